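"""Sliding-window feature extraction and label aggregation.

Decoding never sees raw samples: each (possibly overlapping) time window
is summarised by the mean and standard deviation of every internal plant
channel, and carries one aggregated binary valence label, one arousal
label and the combined quadrant.  Masked samples (dead-zone, IR filter)
are excluded from both the summaries and the label vote; windows with
too few valid samples, or with a tied label vote, are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, DegenerateAnalysisError
from .labels import AffectLabels, quadrant_code
from .synthetic import PlantTrace

__all__ = ["WindowSpec", "WindowTable", "make_windows"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry and label-aggregation rule.

    window_len, stride: minutes; stride <= window_len gives overlap.
    min_valid_fraction: minimum fraction of in-window samples that must
        be unmasked for the window to be kept.
    label_rule: 'majority' votes over per-sample binary labels (exact
        ties drop the window); 'mean-sign' takes the sign of the mean
        smoothed coordinate over unmasked samples.
    """

    window_len: float
    stride: float
    min_valid_fraction: float = 0.5
    label_rule: str = "majority"

    def __post_init__(self) -> None:
        if self.window_len <= 0:
            raise ConfigError("window_len must be positive (minutes)")
        if not 0 < self.stride <= self.window_len:
            raise ConfigError("stride must satisfy 0 < stride <= window_len")
        if not 0 < self.min_valid_fraction <= 1:
            raise ConfigError("min_valid_fraction must be in (0, 1]")
        if self.label_rule not in ("majority", "mean-sign"):
            raise ConfigError("label_rule must be 'majority' or 'mean-sign'")


@dataclass
class WindowTable:
    """Aligned per-window features and labels, time-ordered."""

    window_start: np.ndarray  # seconds
    window_end: np.ndarray  # seconds, half-open [start, end)
    features: np.ndarray  # [n_windows, 2 * n_channels]
    feature_names: list[str]
    label_v: np.ndarray
    label_a: np.ndarray
    label_q: np.ndarray
    n_samples: np.ndarray  # unmasked samples per window
    stride_seconds: float

    def __len__(self) -> int:
        return len(self.window_start)

    def with_labels(
        self, v: np.ndarray, a: np.ndarray
    ) -> "WindowTable":
        """Copy of the table with replaced binary labels (q recombined)."""
        return WindowTable(
            window_start=self.window_start,
            window_end=self.window_end,
            features=self.features,
            feature_names=self.feature_names,
            label_v=np.asarray(v, dtype=np.int8),
            label_a=np.asarray(a, dtype=np.int8),
            label_q=quadrant_code(v, a),
            n_samples=self.n_samples,
            stride_seconds=self.stride_seconds,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df.insert(0, "window_end", self.window_end)
        df.insert(0, "window_start", self.window_start)
        df["label_v"] = self.label_v
        df["label_a"] = self.label_a
        df["label_q"] = self.label_q
        df["n_samples"] = self.n_samples
        return df


def window_starts(n: int, wlen: int, stride: int) -> np.ndarray:
    """Start indices tiling [0, n): regular stride plus an end-anchored
    window when the last regular window stops short of the end."""
    starts = list(range(0, n - wlen + 1, stride))
    if not starts:
        return np.array([], dtype=int)
    if starts[-1] != n - wlen:
        starts.append(n - wlen)
    return np.asarray(starts, dtype=int)


def _window_sums(x: np.ndarray, starts: np.ndarray, wlen: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(x)])
    return c[starts + wlen] - c[starts]


def make_windows(
    plant: PlantTrace, labels: AffectLabels, spec: WindowSpec
) -> WindowTable:
    """Segment aligned plant/label traces into a feature-and-label table.

    Features are per-channel mean and population sd over the unmasked
    samples of each window.  Binary labels aggregate per the spec's rule;
    the quadrant label recombines the aggregated binaries (q = 2v + a).
    """
    ts = np.asarray(plant.timestamps, dtype=float)
    if len(ts) != len(labels) or not np.allclose(ts, labels.timestamps):
        raise DataError("plant trace and labels are not on a common timebase")
    if len(ts) < 2:
        raise DataError("trace too short to window")
    period = float(ts[1] - ts[0])

    wlen_f = spec.window_len * 60.0 / period
    stride_f = spec.stride * 60.0 / period
    wlen, stride = int(round(wlen_f)), int(round(stride_f))
    if abs(wlen_f - wlen) > 1e-9 or abs(stride_f - stride) > 1e-9:
        log.warning(
            "window/stride (%.3g/%.3g min) are not multiples of the sample "
            "period (%.3g s); rounded to %d/%d samples",
            spec.window_len, spec.stride, period, wlen, stride,
        )
    if wlen < 1 or stride < 1:
        raise ConfigError("window/stride shorter than one sample period")
    if wlen > len(ts):
        raise DataError("window longer than the trace")

    starts = window_starts(len(ts), wlen, stride)
    valid = labels.valid.astype(float)
    n_valid = _window_sums(valid, starts, wlen)

    keep = n_valid >= spec.min_valid_fraction * wlen
    # need at least one valid sample even if min_valid_fraction * wlen < 1
    keep &= n_valid > 0

    channels = plant.channel_matrix()
    feats = np.empty((len(starts), 2 * channels.shape[1]))
    names: list[str] = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for j, name in enumerate(PlantTrace.CHANNELS):
            s1 = _window_sums(channels[:, j] * valid, starts, wlen)
            s2 = _window_sums(channels[:, j] ** 2 * valid, starts, wlen)
            mean = s1 / n_valid
            var = np.maximum(0.0, s2 / n_valid - mean**2)
            feats[:, 2 * j] = mean
            feats[:, 2 * j + 1] = np.sqrt(var)
            names += [f"mean_{name}", f"sd_{name}"]

    if spec.label_rule == "majority":
        votes_v = _window_sums(labels.v * valid, starts, wlen)
        votes_a = _window_sums(labels.a * valid, starts, wlen)
        tie = np.isclose(votes_v, n_valid / 2.0) | np.isclose(votes_a, n_valid / 2.0)
        keep &= ~tie
        with np.errstate(invalid="ignore"):
            lv = (votes_v > n_valid / 2.0).astype(np.int8)
            la = (votes_a > n_valid / 2.0).astype(np.int8)
    else:  # mean-sign
        mv = _window_sums(labels.V_smooth * valid, starts, wlen)
        ma = _window_sums(labels.A_smooth * valid, starts, wlen)
        keep &= (mv != 0) & (ma != 0)
        lv = (mv > 0).astype(np.int8)
        la = (ma > 0).astype(np.int8)

    if not keep.any():
        raise DegenerateAnalysisError(
            "no window satisfied the validity/label requirements"
        )
    starts = starts[keep]
    return WindowTable(
        window_start=ts[0] + starts * period,
        window_end=ts[0] + (starts + wlen) * period,
        features=feats[keep],
        feature_names=names,
        label_v=lv[keep],
        label_a=la[keep],
        label_q=quadrant_code(lv[keep], la[keep]),
        n_samples=n_valid[keep].astype(int),
        stride_seconds=stride * period,
    )
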