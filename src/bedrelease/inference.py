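"""Patient-level bootstrap for the change-in-LOS estimand.

Uncertainty is quantified by resampling patients with replacement (the
sampling unit is the whole event history, never a single transition),
re-running the multistate estimator on each replicate, and taking percentile
intervals from the replicate distribution.  Replicates on which the estimand
is undefined — a resample may contain no intermediate events — are dropped
and counted, not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InferenceFailureError, InvalidParameterError
from .multistate import ClosResult, _clos_from_table, _table_from_arrays
from .exceptions import EstimandUndefinedError
from .records import PatientRecord, cohort_arrays, validate_records, CohortArrays

__all__ = ["BootstrapResult", "bootstrap_clos", "histogram_bed_days"]


@dataclass
class BootstrapResult:
    """Replicate estimates of the change in LOS and their percentile CI.

    ``replicates`` holds the signed delta estimates (days) from the
    successful resamples; ``bed_days_released`` is the elementwise negation.
    """

    replicates: np.ndarray
    ci_low: float
    ci_high: float
    level: float
    B: int
    seed: Optional[int]
    n_failed: int
    point_estimate: Optional[float] = None

    @property
    def bed_days_released(self) -> np.ndarray:
        return -self.replicates

    @property
    def n_successful(self) -> int:
        return len(self.replicates)

    def conf_int(self, level: Optional[float] = None) -> tuple[float, float]:
        """Percentile interval at ``level`` (defaults to the fitted level)."""
        if level is None:
            return self.ci_low, self.ci_high
        return _percentile_ci(self.replicates, level)

    def summary(self) -> dict:
        return {
            "B": self.B,
            "n_failed": self.n_failed,
            "level": self.level,
            "delta_mean": float(np.mean(self.replicates)),
            "delta_ci": [float(self.ci_low), float(self.ci_high)],
            "bed_days_released_mean": float(np.mean(self.bed_days_released)),
            "bed_days_released_ci": [float(-self.ci_high), float(-self.ci_low)],
            "seed": self.seed,
        }


def _percentile_ci(values: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def bootstrap_clos(
    records: Sequence[PatientRecord],
    B: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
    stratify_by_cohort: bool = False,
    point_estimate: Optional[ClosResult] = None,
) -> BootstrapResult:
    """Nonparametric bootstrap of :func:`~bedrelease.multistate.estimate_clos`.

    Each replicate resamples the n patients with replacement from the pooled
    sample (or within cohort strata when ``stratify_by_cohort``), rebuilds
    the transition table and recomputes delta.  Deterministic given ``seed``.

    Raises :class:`InferenceFailureError` when more than half the replicates
    leave the estimand undefined — the cohort is too small or intermediate
    events too rare for resampling-based inference.
    """
    if B < 1:
        raise InvalidParameterError("B must be >= 1")
    if not (0.0 < level < 1.0):
        raise InvalidParameterError("level must be in (0, 1)")
    records = list(records)
    validate_records(records)
    arrays = cohort_arrays(records)
    n = arrays.n
    if n == 0:
        raise InvalidParameterError("no records to resample")

    rng = np.random.default_rng(seed)
    if stratify_by_cohort and arrays.cohort is not None:
        strata = [np.flatnonzero(arrays.cohort == c) for c in np.unique(arrays.cohort)]
    else:
        strata = [np.arange(n)]

    reps: list[float] = []
    n_failed = 0
    for _ in range(B):
        idx = np.concatenate(
            [s[rng.integers(0, len(s), len(s))] for s in strata]
        )
        try:
            res = _clos_from_table(_table_from_arrays(arrays.take(idx)))
            reps.append(res.delta)
        except EstimandUndefinedError:
            n_failed += 1
    if n_failed > B / 2:
        raise InferenceFailureError(
            f"{n_failed}/{B} bootstrap replicates had an undefined estimand; "
            "the cohort is too small for resampling inference — collect more "
            "patients or more intermediate events"
        )
    replicates = np.asarray(reps)
    ci_low, ci_high = _percentile_ci(replicates, level)
    return BootstrapResult(
        replicates=replicates,
        ci_low=ci_low,
        ci_high=ci_high,
        level=level,
        B=B,
        seed=seed,
        n_failed=n_failed,
        point_estimate=None if point_estimate is None else point_estimate.delta,
    )


def histogram_bed_days(result: BootstrapResult, bin_width: float = 5.0) -> pd.DataFrame:
    """Bin the bed-days-released replicates on a uniform grid.

    Returns a frame with ``bin_left``, ``bin_right`` and ``count`` columns;
    counts sum to the number of successful replicates.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")
    values = result.bed_days_released
    if len(values) == 0:
        raise InvalidParameterError("no successful replicates to histogram")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
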