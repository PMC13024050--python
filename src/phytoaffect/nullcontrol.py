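"""Circular time-shift permutation null.

To rule out decoding driven by chamber routine or diurnal structure,
labels are rotated in time relative to the plant signals by at least a
minimum lag, and the identical fold plan, standardisation and decoder
are re-run on the shifted labels.  Rotation preserves the marginal label
structure (class counts, run lengths) while destroying alignment, so a
genuine coupling collapses toward chance while routine-driven artefacts
would survive.

Shifts are applied at the window level (units of window strides): the
feature set is then exactly identical between the real and null runs,
isolating label alignment as the only difference.  Shifts that produce
a single-class training fold are discarded and resampled, mirroring the
discard rule used for degenerate folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ConfigError, DataError, DegenerateAnalysisError
from .evaluation import FoldPlan, MetricsReport, evaluate_pipeline
from .features import WindowTable

__all__ = ["NullSpec", "NullResult", "circular_shift", "sample_shifts", "run_null"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullSpec:
    """Null-analysis parameters.

    min_shift: minimum label rotation in minutes (both directions under
        circularity); chosen per dimension — e.g. >=60/>=360 min for
        arousal, >=360/>=720 min for valence.
    n_permutations: shifts drawn per run.
    scope: which target the null is computed for ('v', 'a' or 'q').
    """

    min_shift: float = 360.0
    n_permutations: int = 50
    seed: int = 0
    scope: str = "v"

    def __post_init__(self) -> None:
        if self.min_shift <= 0:
            raise ConfigError("min_shift must be positive (minutes)")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.scope not in ("v", "a", "q"):
            raise ConfigError("scope must be 'v', 'a' or 'q'")


@dataclass
class NullResult:
    """Null distribution of balanced accuracy vs the unshifted value."""

    scope: str
    min_shift: float
    shifts: list[int]
    null_balanced_accuracies: list[float]
    unshifted: MetricsReport
    discarded_shifts: list[dict] = field(default_factory=list)
    per_shift_reports: list[MetricsReport] = field(default_factory=list)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_balanced_accuracies))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_balanced_accuracies))

    @property
    def unshifted_balanced_accuracy(self) -> float:
        return self.unshifted.mean_balanced_accuracy

    @property
    def exceedance_fraction(self) -> float:
        """Fraction of null runs at or above the unshifted value."""
        null = np.asarray(self.null_balanced_accuracies)
        return float((null >= self.unshifted_balanced_accuracy).mean())

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "min_shift_minutes": self.min_shift,
            "n_shifts_used": len(self.shifts),
            "n_shifts_discarded": len(self.discarded_shifts),
            "shifts_samples": self.shifts,
            "null_mean_balanced_accuracy": round(self.null_mean, 3),
            "null_sd_balanced_accuracy": round(self.null_sd, 3),
            "unshifted_balanced_accuracy": round(
                self.unshifted_balanced_accuracy, 3
            ),
            "exceedance_fraction": round(self.exceedance_fraction, 3),
            "discarded_shifts": self.discarded_shifts,
        }


def circular_shift(labels: np.ndarray, shift: int) -> np.ndarray:
    """Rotate a label sequence: output[i] = input[(i - shift) mod n].

    Length and class counts are preserved exactly; shift 0 is the
    identity and shifts compose modulo the length.
    """
    labels = np.asarray(labels)
    if not 0 <= shift < len(labels):
        raise DataError(
            f"shift {shift} outside [0, {len(labels)}) for this sequence"
        )
    return np.roll(labels, shift)


def sample_shifts(
    spec: NullSpec, length: int, sample_period: float, n: int | None = None
) -> np.ndarray:
    """Draw shifts (in samples) honouring the minimum lag circularly.

    Valid shifts s satisfy s * period >= min_shift and
    (length - s) * period >= min_shift, so the rotation is at least the
    minimum lag in both directions around the circle.
    """
    period_min = sample_period / 60.0
    lo = int(np.ceil(spec.min_shift / period_min))
    hi = length - lo
    if lo > hi:
        raise DegenerateAnalysisError(
            f"no valid circular shifts: series spans "
            f"{length * period_min:.0f} min but min_shift is "
            f"{spec.min_shift:.0f} min each way"
        )
    rng = np.random.default_rng(spec.seed)
    return rng.integers(lo, hi + 1, size=n or spec.n_permutations)


def run_null(
    table: WindowTable,
    decoder_factory: Callable[[], object],
    spec: NullSpec,
    fold_plan: FoldPlan | None = None,
    n_splits: int = 5,
    max_retries: int | None = None,
    keep_reports: bool = False,
) -> NullResult:
    """Baseline evaluation plus the shifted-label null distribution.

    Every permutation re-runs the full per-fold pipeline with labels
    rotated by a freshly drawn shift; shifts whose training folds are
    single-class are discarded and resampled within a bounded retry
    budget (a warning is logged if the budget runs out and fewer
    permutations are returned).
    """
    from .evaluation import forward_chain_splits

    plan = fold_plan or forward_chain_splits(len(table), n_splits)
    unshifted = evaluate_pipeline(
        table, decoder_factory, target=spec.scope, fold_plan=plan
    )
    budget = max_retries if max_retries is not None else 4 * spec.n_permutations
    rng_offset = 0
    result = NullResult(
        scope=spec.scope,
        min_shift=spec.min_shift,
        shifts=[],
        null_balanced_accuracies=[],
        unshifted=unshifted,
    )
    period = table.stride_seconds
    while len(result.shifts) < spec.n_permutations and budget > 0:
        want = spec.n_permutations - len(result.shifts)
        draw_spec = NullSpec(
            min_shift=spec.min_shift,
            n_permutations=want,
            seed=spec.seed + rng_offset,
            scope=spec.scope,
        )
        rng_offset += 1
        for s in sample_shifts(draw_spec, len(table), period):
            budget -= 1
            shifted = table.with_labels(
                circular_shift(table.label_v, int(s)),
                circular_shift(table.label_a, int(s)),
            )
            try:
                rep = evaluate_pipeline(
                    shifted, decoder_factory, target=spec.scope, fold_plan=plan
                )
            except DegenerateAnalysisError as exc:
                result.discarded_shifts.append({"shift": int(s), "reason": str(exc)})
                continue
            if rep.skipped_folds:
                # the paper-style discard rule: any single-class training
                # fold invalidates the whole shift
                result.discarded_shifts.append(
                    {"shift": int(s), "reason": "single-class training fold"}
                )
                continue
            result.shifts.append(int(s))
            result.null_balanced_accuracies.append(rep.mean_balanced_accuracy)
            if keep_reports:
                result.per_shift_reports.append(rep)
            if len(result.shifts) >= spec.n_permutations or budget <= 0:
                break
    if len(result.shifts) < spec.n_permutations:
        log.warning(
            "retry budget exhausted: %d/%d permutations completed",
            len(result.shifts),
            spec.n_permutations,
        )
    if not result.shifts:
        raise DegenerateAnalysisError("every sampled shift was discarded")
    return result
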