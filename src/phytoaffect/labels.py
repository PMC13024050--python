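"""Environmentally defined valence-arousal labels.

Valence and arousal are operationalised purely from chamber variables:
light is regressed on temperature and humidity (all z-scored) and the
residual light ``L_res`` — the component of light statistically
independent of T and H — enters two fixed linear combinations,

    V = L_res - T + H        (favourability of the regime)
    A = L_res + T - H        (physiological activation demanded)

so that valence rises with residual light and humidity and falls with
temperature, while arousal does the reverse for T and H.  Continuous
coordinates are median-smoothed, binarised by sign, and combined into a
four-way quadrant code ``q = 2v + a``.  A dead-zone around the origin and
an infrared validity floor mask ambiguous or sensor-failure samples.

Labels are a pure function of the environment trace: plant signals never
enter label construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, DegenerateAnalysisError

__all__ = [
    "LabelConfig",
    "ResidualLightModel",
    "AffectLabels",
    "zscore",
    "fit_residual_light",
    "valence_arousal",
    "smooth",
    "binarize",
    "quadrant_code",
    "ir_filter",
    "build_labels",
]

#: Quadrant semantics, indexed by q = 2v + a: (valence sign, arousal sign).
QUADRANT_SIGNS = {0: ("-", "-"), 1: ("-", "+"), 2: ("+", "-"), 3: ("+", "+")}


@dataclass(frozen=True)
class LabelConfig:
    """Tunables for label construction.

    median_window
        Rolling-median width in minutes applied to V and A; suppresses
        transients on the scale of chamber interventions (lid removal,
        fan bursts).  The window is forced to an odd sample count and is
        centered, shrinking at the edges.
    deadzone_halfwidth
        Half-width (z-units) of the band around V=0 / A=0 whose samples
        are excluded from classification.
    ir_min
        Infrared validity floor in sensor units; samples below it are
        treated as sensor write failures and masked.
    """

    median_window: float = 15.0
    deadzone_halfwidth: float = 0.1
    ir_min: float = 1.0

    def __post_init__(self) -> None:
        if self.median_window <= 0:
            raise ConfigError("median_window must be positive (minutes)")
        if self.deadzone_halfwidth < 0:
            raise ConfigError("deadzone_halfwidth must be >= 0")


@dataclass(frozen=True)
class ResidualLightModel:
    """OLS fit of (z-scored) light on temperature and humidity."""

    beta0: float
    betaT: float
    betaH: float
    r_squared: float


@dataclass
class AffectLabels:
    """Per-sample affect labels derived from an environment trace."""

    timestamps: np.ndarray
    L_res: np.ndarray
    V: np.ndarray
    A: np.ndarray
    V_smooth: np.ndarray
    A_smooth: np.ndarray
    v: np.ndarray
    a: np.ndarray
    q: np.ndarray
    valid: np.ndarray
    model: ResidualLightModel | None = None
    config: LabelConfig = field(default_factory=LabelConfig)

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "L_res": self.L_res,
                "V": self.V,
                "A": self.A,
                "V_smooth": self.V_smooth,
                "A_smooth": self.A_smooth,
                "v": self.v,
                "a": self.a,
                "q": self.q,
                "valid": self.valid,
            }
        )


def zscore(
    x: np.ndarray,
    mean: float | None = None,
    sd: float | None = None,
) -> np.ndarray:
    """Standardise a series to mean 0, sd 1 (population convention).

    When ``mean``/``sd`` are supplied they are used as-is, so a series can
    be expressed in the statistics of another (e.g. train-fold) segment.
    """
    x = np.asarray(x, dtype=float)
    if mean is None or sd is None:
        if x.size < 2:
            raise DegenerateAnalysisError("need at least 2 samples to z-score")
        mean = float(np.mean(x))
        sd = float(np.std(x))  # ddof=0: population convention
    if sd <= 0:
        raise DegenerateAnalysisError("cannot z-score a zero-variance series")
    return (x - mean) / sd


def fit_residual_light(
    L: np.ndarray, T: np.ndarray, H: np.ndarray
) -> tuple[ResidualLightModel, np.ndarray]:
    """Regress light on temperature and humidity; return model + residual.

    Ordinary least squares with intercept on already z-scored inputs.
    The residual has zero mean (intercept) and zero sample correlation
    with both regressors (normal equations), which is what makes it usable
    as a light coordinate independent of T and H.
    """
    L, T, H = (np.asarray(v, dtype=float) for v in (L, T, H))
    if not (len(L) == len(T) == len(H)):
        raise DataError("L, T, H must have equal lengths")
    if len(L) < 3:
        raise DataError("need at least 3 samples to fit the light model")
    X = np.column_stack([np.ones_like(T), T, H])
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateAnalysisError(
            "collinear design: [1, T, H] is rank-deficient "
            "(temperature/humidity carry no independent variation)"
        )
    beta, *_ = np.linalg.lstsq(X, L, rcond=None)
    fitted = X @ beta
    resid = L - fitted
    ss_tot = float(np.sum((L - L.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    model = ResidualLightModel(
        beta0=float(beta[0]), betaT=float(beta[1]), betaH=float(beta[2]), r_squared=r2
    )
    return model, resid


def valence_arousal(
    L_res: np.ndarray, T: np.ndarray, H: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """V = L_res - T + H and A = L_res + T - H, elementwise.

    Two exact identities follow and are used as test anchors:
    V + A = 2 L_res and V - A = 2 (H - T).
    """
    L_res, T, H = (np.asarray(v, dtype=float) for v in (L_res, T, H))
    if not (len(L_res) == len(T) == len(H)):
        raise DataError("L_res, T, H must have equal lengths")
    V = L_res - T + H
    A = L_res + T - H
    return V, A


def smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling median with shrinking windows at the edges."""
    x = np.asarray(x, dtype=float)
    if window < 1:
        raise ConfigError("median window must be >= 1 sample")
    if window > len(x):
        raise DataError(
            f"median window ({window}) longer than series ({len(x)})"
        )
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def binarize(
    V_smooth: np.ndarray,
    A_smooth: np.ndarray,
    deadzone_halfwidth: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sign-binarise smoothed coordinates; mask the dead-zone.

    v = 1[V > 0], a = 1[A > 0] (strict inequality: exact zeros fall to
    class 0).  Samples with |V| or |A| within the dead-zone half-width
    carry no class and are flagged invalid.
    """
    V_smooth = np.asarray(V_smooth, dtype=float)
    A_smooth = np.asarray(A_smooth, dtype=float)
    v = (V_smooth > 0).astype(np.int8)
    a = (A_smooth > 0).astype(np.int8)
    valid = (np.abs(V_smooth) > deadzone_halfwidth) & (
        np.abs(A_smooth) > deadzone_halfwidth
    )
    return v, a, valid


def quadrant_code(v: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Combine binary valence/arousal into q = 2v + a (0:--, 1:-+, 2:+-, 3:++)."""
    v = np.asarray(v)
    a = np.asarray(a)
    if not (np.isin(v, (0, 1)).all() and np.isin(a, (0, 1)).all()):
        raise DataError("quadrant inputs must be binary 0/1")
    return (2 * v + a).astype(np.int8)


def ir_filter(infrared: np.ndarray, ir_min: float = 1.0) -> np.ndarray:
    """Validity mask: True where the infrared reading is >= ir_min.

    Sub-threshold IR marks intervals where the light sensor failed to
    record; the floor does not exclude ordinary night-time readings.
    """
    return np.asarray(infrared, dtype=float) >= ir_min


def build_labels(env, config: LabelConfig | None = None) -> AffectLabels:
    """Full label construction from an environment trace.

    Z-scores T, H, L over the whole trace (labels are external ground
    truth, so full-trace statistics are not feature leakage), fits the
    residual-light regression, forms V/A, median-smooths them, binarises
    with the dead-zone, and intersects with the IR validity mask.
    """
    config = config or LabelConfig()
    T = zscore(env.temperature)
    H = zscore(env.humidity)
    L = zscore(env.light)
    model, L_res = fit_residual_light(L, T, H)
    V, A = valence_arousal(L_res, T, H)

    period = float(env.timestamps[1] - env.timestamps[0])
    win = max(1, int(round(config.median_window * 60.0 / period)))
    if win % 2 == 0:
        win += 1
    V_s = smooth(V, win)
    A_s = smooth(A, win)

    v, a, valid = binarize(V_s, A_s, config.deadzone_halfwidth)
    valid = valid & ir_filter(env.infrared, config.ir_min)
    if not valid.any():
        raise DegenerateAnalysisError(
            "empty analysis set: every sample is dead-zoned or IR-filtered"
        )
    q = quadrant_code(v, a)
    return AffectLabels(
        timestamps=np.asarray(env.timestamps, dtype=float),
        L_res=L_res,
        V=V,
        A=A,
        V_smooth=V_s,
        A_smooth=A_s,
        v=v,
        a=a,
        q=q,
        valid=valid,
        model=model,
        config=config,
    )
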