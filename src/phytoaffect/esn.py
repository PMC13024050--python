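"""Echo State Network: fixed random leaky reservoir + ridge readout.

The reservoir state update is

    x(t+1) = (1 - alpha) x(t) + alpha tanh(W_in u(t) + W x(t))

with leak rate alpha, dense random input weights W_in (scaled by
input_scaling) and a sparse random recurrent matrix W rescaled to a
target spectral radius below 1, which gives fading memory.  The
reservoir is never trained; only the linear readout

    y(t) = W_out [x(t); 1]

is fit, by closed-form ridge regression on post-washout states with
targets encoded +/-1 and the bias column unpenalised.  Binary classes
come from the ridge score through a logistic sigmoid thresholded at 0.5
(equivalently: score > 0); quadrants combine two independent binary
readouts as q = 2v + a.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError, DegenerateAnalysisError
from .labels import quadrant_code

__all__ = [
    "ReservoirConfig",
    "Reservoir",
    "ReadoutModel",
    "init_reservoir",
    "run_reservoir",
    "ridge_fit",
    "fit_readout",
    "predict_binary",
    "combine_quadrant",
]


@dataclass(frozen=True)
class ReservoirConfig:
    """Reservoir hyperparameters.

    Defaults follow common reservoir-computing practice for slow
    biosignals: 300 units, spectral radius 0.9 (fading memory), leak
    rate 0.2 (slow state integration), input scaling 0.5, 50-step
    washout, ridge penalty 1.0.  Note the leak rate and the ridge
    penalty are distinct parameters even though both are often written
    as alpha.
    """

    n_units: int = 300
    spectral_radius: float = 0.9
    leak: float = 0.2
    input_scaling: float = 0.5
    washout: int = 50
    ridge_penalty: float = 1.0
    density: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units <= 0:
            raise ConfigError("n_units must be positive")
        if not 0 < self.leak <= 1:
            raise ConfigError("leak must be in (0, 1]")
        if self.spectral_radius <= 0:
            raise ConfigError("spectral_radius must be positive")
        if self.washout < 0 or self.ridge_penalty < 0:
            raise ConfigError("washout and ridge_penalty must be >= 0")
        if not 0 < self.density <= 1:
            raise ConfigError("density must be in (0, 1]")


@dataclass
class Reservoir:
    """Fixed random recurrent system; reproducible from (config, n_inputs)."""

    W: np.ndarray
    W_in: np.ndarray
    config: ReservoirConfig

    @property
    def n_inputs(self) -> int:
        return self.W_in.shape[1]


@dataclass
class ReadoutModel:
    """Trained linear readout: weights over [state; 1]."""

    W_out: np.ndarray  # [n_units + 1], bias last
    trained_on: str = ""


def init_reservoir(config: ReservoirConfig, n_inputs: int) -> Reservoir:
    """Draw and scale the fixed random weights.

    W entries are Uniform(-1, 1), sparsified to ``density``, then
    rescaled so the largest absolute eigenvalue equals
    ``spectral_radius`` exactly.  W_in is dense Uniform(-1, 1) times
    ``input_scaling``.
    """
    if n_inputs <= 0:
        raise ConfigError("n_inputs must be positive")
    rng = np.random.default_rng(config.seed)
    n = config.n_units
    W = rng.uniform(-1.0, 1.0, size=(n, n))
    mask = rng.random((n, n)) < config.density
    W = W * mask
    radius = float(np.max(np.abs(np.linalg.eigvals(W))))
    if radius <= 0:
        raise DegenerateAnalysisError(
            "sparsified recurrent matrix has spectral radius 0; "
            "increase density or n_units, or change the seed"
        )
    W *= config.spectral_radius / radius
    W_in = rng.uniform(-1.0, 1.0, size=(n, n_inputs)) * config.input_scaling
    return Reservoir(W=W, W_in=W_in, config=config)


def run_reservoir(
    res: Reservoir, U: np.ndarray, x0: np.ndarray | None = None
) -> np.ndarray:
    """Iterate the leaky-tanh state update over an input sequence.

    Returns the state after each input step, shape [T, n_units].  With
    x0 in [-1, 1]^n every state stays in [-1, 1]^n (each update is a
    convex combination of the previous state and a tanh image).
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if U.shape[1] != res.n_inputs:
        raise DataError(
            f"input has {U.shape[1]} columns, reservoir expects {res.n_inputs}"
        )
    bad = np.flatnonzero(~np.isfinite(U).all(axis=1))
    if bad.size:
        raise DataError(f"non-finite input at step {bad[0]}")
    alpha = res.config.leak
    x = np.zeros(res.config.n_units) if x0 is None else np.asarray(x0, dtype=float)
    X = np.empty((len(U), res.config.n_units))
    for t in range(len(U)):
        x = (1.0 - alpha) * x + alpha * np.tanh(res.W_in @ U[t] + res.W @ x)
        X[t] = x
    return X


def ridge_fit(X: np.ndarray, y: np.ndarray, penalty: float) -> np.ndarray:
    """Closed-form ridge on [X; 1] with the bias column unpenalised.

    Solves (G'G + penalty * D) w = G'y with G = [X, 1] and
    D = diag(1, ..., 1, 0); returns w with the bias last.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    G = np.column_stack([X, np.ones(len(X))])
    D = np.eye(G.shape[1])
    D[-1, -1] = 0.0
    A = G.T @ G + penalty * D
    b = G.T @ y
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def fit_readout(
    X: np.ndarray,
    targets: np.ndarray,
    config: ReservoirConfig,
    trained_on: str = "",
) -> ReadoutModel:
    """Ridge-train the readout on post-washout states.

    Binary 0/1 targets are encoded -1/+1.  A training fold whose
    post-washout targets contain a single class is degenerate and
    refused (such folds are discarded upstream).
    """
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets)
    if len(X) != len(targets):
        raise DataError("states and targets differ in length")
    w = config.washout
    if len(X) - w < 2:
        raise DegenerateAnalysisError(
            f"only {max(0, len(X) - w)} post-washout samples; need >= 2"
        )
    Xw, yw = X[w:], targets[w:]
    if np.unique(yw).size < 2:
        raise DegenerateAnalysisError(
            "single-class training targets after washout; fold discarded"
        )
    y_pm = np.where(yw > 0, 1.0, -1.0)
    W_out = ridge_fit(Xw, y_pm, config.ridge_penalty)
    if not np.isfinite(W_out).all():
        raise DegenerateAnalysisError("non-finite readout weights")
    return ReadoutModel(W_out=W_out, trained_on=trained_on)


def predict_binary(
    model: ReadoutModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Score, sigmoid probability and hard class for each state.

    class = 1[p > 0.5] which is identical to 1[score > 0]; a score of
    exactly zero falls to class 0.
    """
    X = np.asarray(X, dtype=float)
    scores = X @ model.W_out[:-1] + model.W_out[-1]
    probs = 1.0 / (1.0 + np.exp(-scores))
    classes = (scores > 0).astype(np.int8)
    return scores, probs, classes


def combine_quadrant(v_pred: np.ndarray, a_pred: np.ndarray) -> np.ndarray:
    """q = 2v + a from independent binary predictions."""
    v_pred, a_pred = np.asarray(v_pred), np.asarray(a_pred)
    if len(v_pred) != len(a_pred):
        raise DataError("valence/arousal prediction lengths differ")
    return quadrant_code(v_pred, a_pred)


def save_reservoir_model(
    path: str | Path,
    config: ReservoirConfig,
    n_inputs: int,
    readouts: dict[str, ReadoutModel],
) -> None:
    """Portable JSON archive: config + seed + readout weights.

    W and W_in are regenerable from (config, n_inputs), so only the
    trained readouts are stored.
    """
    payload = {
        "config": asdict(config),
        "n_inputs": n_inputs,
        "readouts": {
            k: {"W_out": m.W_out.tolist(), "trained_on": m.trained_on}
            for k, m in readouts.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_reservoir_model(
    path: str | Path,
) -> tuple[Reservoir, dict[str, ReadoutModel]]:
    payload = json.loads(Path(path).read_text())
    config = ReservoirConfig(**payload["config"])
    res = init_reservoir(config, payload["n_inputs"])
    readouts = {
        k: ReadoutModel(W_out=np.asarray(d["W_out"]), trained_on=d["trained_on"])
        for k, d in payload["readouts"].items()
    }
    return res, readouts
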