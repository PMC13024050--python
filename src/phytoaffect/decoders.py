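"""Fold-level decoders over window features.

Both decoders share the same readout: closed-form ridge to +/-1 targets,
sigmoid-squashed score thresholded at 0.5.  The linear decoder applies
it directly to the standardized window features; the ESN decoder first
expands the feature sequence through a fixed random reservoir (one
reservoir step per window, states carried causally from the training
segment into the test segment).  The two paths therefore differ only by
the reservoir expansion.

Targets are passed as an [n, k] binary matrix — one column per affect
dimension — and each column gets its own readout, so a quadrant decoder
is just the k=2 case with q = 2v + a recombined downstream.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateAnalysisError
from .esn import (
    ReadoutModel,
    Reservoir,
    ReservoirConfig,
    init_reservoir,
    predict_binary,
    ridge_fit,
    run_reservoir,
)

__all__ = ["RidgeWindowDecoder", "ESNWindowDecoder"]


def _check_two_classes(Y: np.ndarray) -> None:
    for j in range(Y.shape[1]):
        if np.unique(Y[:, j]).size < 2:
            raise DegenerateAnalysisError(
                f"single-class training targets in column {j}; fold discarded"
            )


class RidgeWindowDecoder:
    """Ridge-score + sigmoid readout applied directly to window features."""

    def __init__(self, ridge_penalty: float = 1.0):
        self.ridge_penalty = ridge_penalty
        self.readouts: list[ReadoutModel] | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "RidgeWindowDecoder":
        X = np.asarray(X, dtype=float)
        Y = np.atleast_2d(np.asarray(Y).T).T  # ensure [n, k]
        _check_two_classes(Y)
        self.readouts = [
            ReadoutModel(
                W_out=ridge_fit(
                    X, np.where(Y[:, j] > 0, 1.0, -1.0), self.ridge_penalty
                )
            )
            for j in range(Y.shape[1])
        ]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        assert self.readouts is not None, "fit before predict"
        cols = [predict_binary(m, X)[2] for m in self.readouts]
        return np.column_stack(cols)


class ESNWindowDecoder:
    """Reservoir expansion of the window sequence + ridge readout.

    The reservoir consumes one standardized feature vector per window in
    time order.  ``fit`` starts from the zero state, discards the
    washout, and trains one readout per target column; ``predict``
    continues the state from the end of the training segment, so test
    states depend causally on the training history but never the
    reverse.
    """

    def __init__(
        self,
        config: ReservoirConfig | None = None,
        reservoir: Reservoir | None = None,
        n_inputs: int | None = None,
    ):
        self.config = config or ReservoirConfig()
        self._reservoir = reservoir
        self._n_inputs = n_inputs
        self.readouts: list[ReadoutModel] | None = None
        self._state: np.ndarray | None = None

    def _ensure_reservoir(self, n_inputs: int) -> Reservoir:
        if self._reservoir is None:
            self._reservoir = init_reservoir(self.config, n_inputs)
        return self._reservoir

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "ESNWindowDecoder":
        X = np.asarray(X, dtype=float)
        Y = np.atleast_2d(np.asarray(Y).T).T
        res = self._ensure_reservoir(X.shape[1])
        states = run_reservoir(res, X)
        self._state = states[-1].copy()
        w = self.config.washout
        if len(states) - w < 2:
            raise DegenerateAnalysisError(
                f"only {max(0, len(states) - w)} post-washout windows; need >= 2"
            )
        _check_two_classes(Y[w:])
        self.readouts = [
            ReadoutModel(
                W_out=ridge_fit(
                    states[w:],
                    np.where(Y[w:, j] > 0, 1.0, -1.0),
                    self.config.ridge_penalty,
                )
            )
            for j in range(Y.shape[1])
        ]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        assert self.readouts is not None and self._reservoir is not None
        states = run_reservoir(self._reservoir, np.asarray(X, dtype=float), self._state)
        self._state = states[-1].copy()
        cols = [predict_binary(m, states)[2] for m in self.readouts]
        return np.column_stack(cols)
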