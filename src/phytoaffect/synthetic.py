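"""Synthetic growth-chamber environment and plant-signal generator.

The environment generator reproduces the chamber protocol used as label
ground truth: a heater pad switched on at memoryless random times for
15-45 min episodes, thermostat fans that engage at 36 degC and hold the
chamber above a 35 degC stress floor while an episode persists, a 24 h
fresh-air flush, ~25 degC ambient, a diurnal light waveform with
heater-correlated and independent components, and humidity anti-coupled
to temperature.

The plant generator is a statistical stand-in, not a physiological
model: it couples internal channels to the *true* environmental affect
drives with an explicit timescale separation — the bioelectric channel
carries a high-passed (fast, seconds-minutes) copy of the arousal drive,
while the gas channels (eCO2, TVOC) carry a leaky-integrated (slow, tens
of minutes) copy of the valence drive — plus white noise and slow sensor
drift.  Because the drives are computed from the true chamber variables,
downstream label estimation remains an honest, separate step.

All randomness flows from a single seeded generator per trace; identical
(config, seed) gives bitwise-identical traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import labels as _labels
from .errors import ConfigError, DataError

__all__ = [
    "ChamberConfig",
    "CouplingConfig",
    "EnvironmentTrace",
    "PlantTrace",
    "simulate_environment",
    "simulate_plant",
]

# Thermal response constants (seconds).  These set how fast the chamber
# heats, how aggressively the fans cool, and how it relaxes unforced;
# the heater/fan interplay yields a ~1-2 min thermostat oscillation
# between the 35 degC floor and 36 degC trigger during episodes.
_TAU_HEAT = 300.0
_TAU_FAN = 150.0
_TAU_PASSIVE = 300.0
_HEAT_TARGET = 55.0
_FAN_TARGET = 28.0
_TEMP_NOISE = 0.01  # degC / sqrt(s), sensor + micro-draft jitter


@dataclass(frozen=True)
class ChamberConfig:
    """Chamber protocol parameters.

    duration: hours of simulated recording.
    env_rate: environmental sampling rate, samples/s.
    ambient_temp: unforced chamber temperature, degC.
    fan_trigger_temp / fan_floor_temp: thermostat hysteresis band, degC;
        fans engage at the trigger and disengage at the floor so heat
        episodes stay stressful (>= floor) but bounded.
    heater_min / heater_max: episode duration bounds, minutes.
    heater_rate: expected heater onsets per day (memoryless process,
        refractory while an episode is active).
    flush_period: hours between fresh-air fan flushes.
    flush_duration: minutes each flush lasts.
    diurnal_period: hours per light cycle.
    light_peak: midday clear-sky light level, sensor units.
    humidity_base: %RH at ambient temperature.
    humidity_temp_gain: %RH per degC above ambient (negative: hot air in
        a closed chamber reads drier).
    """

    duration: float = 72.0
    env_rate: float = 0.5
    ambient_temp: float = 25.0
    fan_trigger_temp: float = 36.0
    fan_floor_temp: float = 35.0
    heater_min: float = 15.0
    heater_max: float = 45.0
    heater_rate: float = 24.0
    flush_period: float = 24.0
    flush_duration: float = 5.0
    diurnal_period: float = 24.0
    light_peak: float = 400.0
    humidity_base: float = 55.0
    humidity_temp_gain: float = -1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be positive (hours)")
        if self.env_rate <= 0:
            raise ConfigError("env_rate must be positive (samples/s)")
        if self.heater_rate < 0:
            raise ConfigError("heater_rate must be >= 0 (onsets/day)")
        if self.heater_min > self.heater_max:
            raise ConfigError("heater_min must be <= heater_max")
        if self.fan_floor_temp >= self.fan_trigger_temp:
            raise ConfigError("fan_floor_temp must be below fan_trigger_temp")
        if self.flush_period <= 0 or self.diurnal_period <= 0:
            raise ConfigError("flush_period and diurnal_period must be positive")


@dataclass(frozen=True)
class CouplingConfig:
    """Plant-channel coupling parameters.

    fast_gain: bioelectric response per z-unit of high-passed arousal
        drive (mV-scale units per z-unit).
    slow_gain: gas response per z-unit of leaky-integrated valence drive
        (ppm-scale units per z-unit; TVOC uses half this scale).
    tau_fast: adaptation corner of the bioelectric high-pass, seconds —
        the channel passes fluctuations faster than this and adapts away
        sustained levels, so it carries seconds-to-minutes content only.
    tau_slow: gas integration time constant, minutes; the gas channels
        track the valence drive smoothed over this horizon (strictly
        slower than tau_fast).
    noise_sd_bio / noise_sd_gas: white measurement noise, channel units
        (metal-oxide gas sensors are noisy at the sample level).
    drift_sd: random-walk sensor drift accumulated per hour (gas
        channels; metal-oxide sensors drift on baseline).
    """

    fast_gain: float = 2.0
    slow_gain: float = 40.0
    tau_fast: float = 1800.0
    tau_slow: float = 90.0
    noise_sd_bio: float = 0.3
    noise_sd_gas: float = 25.0
    drift_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_fast >= self.tau_slow * 60.0:
            raise ConfigError("tau_fast (s) must be below tau_slow (min)")
        if min(self.noise_sd_bio, self.noise_sd_gas, self.drift_sd) < 0:
            raise ConfigError("noise terms must be >= 0")


@dataclass
class EnvironmentTrace:
    """Uniformly sampled chamber channels plus actuator event states."""

    timestamps: np.ndarray
    temperature: np.ndarray
    humidity: np.ndarray
    light: np.ndarray
    infrared: np.ndarray
    heater_state: np.ndarray
    fan_state: np.ndarray
    config: ChamberConfig | None = None
    #: (onset_s, duration_s) of every heater episode, for diagnostics.
    heater_episodes: list[tuple[float, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def period(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "temperature": self.temperature,
                "humidity": self.humidity,
                "light": self.light,
                "infrared": self.infrared,
                "heater": self.heater_state,
                "fan": self.fan_state,
            }
        )


@dataclass
class PlantTrace:
    """Internal plant channels on the environmental timebase."""

    timestamps: np.ndarray
    bioelectric: np.ndarray
    eco2: np.ndarray
    tvoc: np.ndarray
    config: CouplingConfig | None = None

    #: channel names in feature order
    CHANNELS = ("bioelectric", "eco2", "tvoc")

    def __len__(self) -> int:
        return len(self.timestamps)

    def channel_matrix(self) -> np.ndarray:
        return np.column_stack([self.bioelectric, self.eco2, self.tvoc])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "bioelectric": self.bioelectric,
                "eco2": self.eco2,
                "tvoc": self.tvoc,
            }
        )


def _ou(rng: np.random.Generator, n: int, dt: float, tau: float, sd: float) -> np.ndarray:
    """Stationary-sd Ornstein-Uhlenbeck noise via a one-pole IIR filter."""
    if sd == 0:
        return np.zeros(n)
    a = dt / tau
    eps = rng.standard_normal(n)
    # y[k] = (1-a) y[k-1] + eps[k]; rescale to the requested stationary sd
    y = lfilter([1.0], [1.0, -(1.0 - a)], eps)
    stat = np.sqrt(1.0 / (1.0 - (1.0 - a) ** 2))
    return sd * y / stat


def _leaky_lowpass(x: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """y[k] = y[k-1] + (dt/tau) (x[k] - y[k-1]), started at x[0]."""
    a = dt / tau
    if a >= 1.0:
        return np.asarray(x, dtype=float).copy()
    y = lfilter([a], [1.0, -(1.0 - a)], x)
    # correct the zero initial condition to start at x[0]
    y += x[0] * (1.0 - a) ** np.arange(1, len(x) + 1)
    return y


def simulate_environment(config: ChamberConfig) -> EnvironmentTrace:
    """Generate one chamber recording under the stated protocol.

    Temperature follows first-order relaxation toward ambient, driven up
    during heater episodes and down while fans run; the fan latches on
    when temperature reaches the trigger and releases at the floor.
    Episodes start as a memoryless (Poisson) process at ``heater_rate``
    onsets/day, refractory while one is active, with durations uniform
    in [heater_min, heater_max] minutes.  Fans additionally run for a
    fixed flush window every ``flush_period`` hours.
    """
    dt = 1.0 / config.env_rate
    n = int(round(config.duration * 3600.0 * config.env_rate))
    if n < 2:
        raise ConfigError("duration too short for the sampling rate")
    rng = np.random.default_rng(config.seed)
    t = np.arange(n) * dt

    # --- thermostat / heater state machine (sequential by nature) ---
    p_onset = config.heater_rate / 86400.0 * dt
    onset_u = rng.random(n)
    temp_eps = rng.standard_normal(n) * _TEMP_NOISE * np.sqrt(dt)

    flush_s = config.flush_duration * 60.0
    period_s = config.flush_period * 3600.0

    T = np.empty(n)
    heater = np.zeros(n, dtype=np.int8)
    fan = np.zeros(n, dtype=np.int8)
    T[0] = config.ambient_temp
    episodes: list[tuple[float, float]] = []
    in_episode = False
    ep_end = 0.0
    fan_latched = False
    for i in range(1, n):
        Tp = T[i - 1]
        dTdt = (config.ambient_temp - Tp) / _TAU_PASSIVE
        if heater[i - 1]:
            dTdt += (_HEAT_TARGET - Tp) / _TAU_HEAT
        if fan[i - 1]:
            dTdt += (_FAN_TARGET - Tp) / _TAU_FAN
        T[i] = Tp + dt * dTdt + temp_eps[i]

        ti = t[i]
        if in_episode and ti >= ep_end:
            in_episode = False
        if not in_episode and onset_u[i] < p_onset:
            dur = rng.uniform(config.heater_min, config.heater_max) * 60.0
            in_episode = True
            ep_end = ti + dur
            episodes.append((ti, dur))
        heater[i] = in_episode

        if T[i] >= config.fan_trigger_temp:
            fan_latched = True
        elif T[i] <= config.fan_floor_temp:
            fan_latched = False
        flush_on = ti >= period_s and (ti % period_s) < flush_s
        fan[i] = 1 if (fan_latched or flush_on) else 0

    # --- light: diurnal half-rectified sinusoid x cloud factor,
    #     plus a heater-correlated component and sensor noise ---
    day_s = config.diurnal_period * 3600.0
    phase = 2.0 * np.pi * (t - day_s / 4.0) / day_s
    diurnal = np.maximum(0.0, np.sin(phase)) * config.light_peak
    # slow cloud cover plus fast flicker (foliage shadows, short-lived
    # haze); both scale with the instantaneous irradiance
    clouds = np.clip(1.0 + _ou(rng, n, dt, 1800.0, 0.15), 0.3, 1.3)
    flicker = np.clip(1.0 + _ou(rng, n, dt, 90.0, 0.10), 0.5, 1.5)
    heater_lp = _leaky_lowpass(heater.astype(float), dt, 120.0)
    light = diurnal * clouds * flicker + 0.08 * config.light_peak * heater_lp
    light = np.maximum(0.0, light + rng.standard_normal(n) * 1.0)

    # Infrared: warm-body channel, correlated with light and the heater
    # pad; its baseline keeps ordinary night readings above the validity
    # floor used downstream.
    infrared = np.maximum(
        0.0,
        4.0 + 0.03 * light + 2.0 * heater_lp + _ou(rng, n, dt, 600.0, 0.3),
    )

    humidity = np.clip(
        config.humidity_base
        + config.humidity_temp_gain * (T - config.ambient_temp)
        + _ou(rng, n, dt, 1200.0, 2.0),
        0.0,
        100.0,
    )

    return EnvironmentTrace(
        timestamps=t,
        temperature=T,
        humidity=humidity,
        light=light,
        infrared=infrared,
        heater_state=heater,
        fan_state=fan,
        config=config,
        heater_episodes=episodes,
    )


def true_affect_drives(env: EnvironmentTrace) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (V, A) drives from the true chamber variables.

    Same construction as the labelling step (z-score, residual-light
    regression, fixed linear combinations) but applied to the generator's
    own variables, so the downstream labelling remains an estimation step
    rather than a shared computation.
    """
    T = _labels.zscore(env.temperature)
    H = _labels.zscore(env.humidity)
    L = _labels.zscore(env.light)
    _, L_res = _labels.fit_residual_light(L, T, H)
    return _labels.valence_arousal(L_res, T, H)


def simulate_plant(env: EnvironmentTrace, coupling: CouplingConfig) -> PlantTrace:
    """Generate internal plant channels coupled to the environment.

    bioelectric = fast_gain * highpass(A, tau_fast) + white noise
    eco2/tvoc   = baseline + slow_gain * lowpass(V, tau_slow)
                  + random-walk drift + white noise

    The high-pass keeps only the fast component of the arousal drive
    (heater onsets, thermostat oscillation); the low-pass integrates the
    valence drive over tens of minutes.  This encodes the hypothesis that
    arousal-related internal dynamics live on faster timescales than
    valence-related ones.
    """
    if len(env) < 2:
        raise DataError("environment trace too short")
    dt = env.period
    n = len(env)
    rng = np.random.default_rng(coupling.seed)

    V, A = true_affect_drives(env)
    hp_A = A - _leaky_lowpass(A, dt, coupling.tau_fast)
    lp_V = _leaky_lowpass(V, dt, coupling.tau_slow * 60.0)

    bio = coupling.fast_gain * hp_A + rng.standard_normal(n) * coupling.noise_sd_bio

    step_sd = coupling.drift_sd * np.sqrt(dt / 3600.0)
    drift_e = np.cumsum(rng.standard_normal(n)) * step_sd
    drift_t = np.cumsum(rng.standard_normal(n)) * step_sd
    eco2 = (
        400.0
        + coupling.slow_gain * lp_V
        + drift_e
        + rng.standard_normal(n) * coupling.noise_sd_gas
    )
    tvoc = (
        50.0
        + 0.5 * coupling.slow_gain * lp_V
        + drift_t
        + rng.standard_normal(n) * coupling.noise_sd_gas
    )

    return PlantTrace(
        timestamps=env.timestamps.copy(),
        bioelectric=bio,
        eco2=eco2,
        tvoc=tvoc,
        config=coupling,
    )
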