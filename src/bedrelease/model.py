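"""Model/Results interface over the estimation pipeline.

`ChangeInLOSModel` is constructed from patient event histories (records, a
DataFrame in the canonical schema, or a CSV path) and its :meth:`fit`
returns a :class:`ChangeInLOSResults` carrying the point estimate, its
per-time decomposition, and a :meth:`~ChangeInLOSResults.bootstrap` method
for percentile confidence intervals.  :class:`EconModel` turns the bootstrap
bed-day draws into the Monte Carlo economic evaluation.

Example
-------
>>> from bedrelease import ChangeInLOSModel, EconModel
>>> from bedrelease.simulate import PaperLikeScenario, simulate_paper_like
>>> records = simulate_paper_like(PaperLikeScenario(seed=42))
>>> res = ChangeInLOSModel(records).fit()
>>> boot = res.bootstrap(B=1000, seed=42)
>>> econ = EconModel(boot.bed_days_released).run()
>>> econ.p_meets_wtp  # doctest: +SKIP
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .cohort import compare_cohorts
from .econ import EconConfig, EconSimResult, run_monte_carlo
from .inference import BootstrapResult, bootstrap_clos
from .multistate import (
    ClosResult,
    TransitionTable,
    aalen_johansen,
    build_transition_table,
    estimate_clos,
)
from .records import PatientRecord

__all__ = ["ChangeInLOSModel", "ChangeInLOSResults", "EconModel"]


class ChangeInLOSModel:
    """Three-state change-in-LOS model for a patient cohort.

    Parameters
    ----------
    records : sequence of PatientRecord
        The pooled cohort; control patients contribute only direct
        discharges to the risk sets.
    cohort : str, optional
        Restrict estimation to one cohort label instead of pooling.
    """

    def __init__(self, records: Sequence[PatientRecord], cohort: Optional[str] = None):
        self.records = list(records)
        self.cohort = cohort

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cohort: Optional[str] = None):
        return cls(_io.records_from_dataframe(df), cohort=cohort)

    @classmethod
    def from_csv(cls, path, cohort: Optional[str] = None):
        return cls(_io.read_patients(path), cohort=cohort)

    def transition_table(self) -> TransitionTable:
        records = self.records
        if self.cohort is not None:
            records = [r for r in records if r.cohort == self.cohort]
        return build_transition_table(records)

    def transition_probabilities(self, s: float = 0.0):
        """Aalen-Johansen matrices P(s, .) on the event grid."""
        return aalen_johansen(self.transition_table(), s)

    def fit(self) -> "ChangeInLOSResults":
        result = estimate_clos(self.records, cohort=self.cohort)
        return ChangeInLOSResults(self, result)


class ChangeInLOSResults:
    """Fitted change-in-LOS estimate with its decomposition.

    Attributes
    ----------
    delta : float
        Signed change in expected LOS (days); negative = shorter stays.
    bed_days_released : float
        ``-delta``: capacity freed per patient managed.
    phi_curve, weights, s_times : ndarray
        Per-intervention-time differences, their weights, and the times.
    """

    def __init__(self, model: ChangeInLOSModel, result: ClosResult):
        self.model = model
        self._result = result

    # pass-through surface
    @property
    def delta(self) -> float:
        return self._result.delta

    @property
    def bed_days_released(self) -> float:
        return self._result.bed_days_released

    @property
    def phi_curve(self) -> np.ndarray:
        return self._result.phi

    @property
    def weights(self) -> np.ndarray:
        return self._result.weights

    @property
    def s_times(self) -> np.ndarray:
        return self._result.s_times

    @property
    def tau(self) -> float:
        return self._result.tau

    @property
    def n_patients(self) -> int:
        return self._result.n_patients

    @property
    def clos_result(self) -> ClosResult:
        return self._result

    def bootstrap(
        self,
        B: int = 1000,
        level: float = 0.95,
        seed: Optional[int] = None,
        stratify_by_cohort: bool = False,
    ) -> BootstrapResult:
        """Patient-level percentile bootstrap of the estimate."""
        records = self.model.records
        if self.model.cohort is not None:
            records = [r for r in records if r.cohort == self.model.cohort]
        return bootstrap_clos(
            records,
            B=B,
            level=level,
            seed=seed,
            stratify_by_cohort=stratify_by_cohort,
            point_estimate=self._result,
        )

    def cohort_comparison(self, level: float = 0.95) -> dict:
        """Baseline Table-1-style comparison of the two cohorts."""
        return compare_cohorts(self.model.records, level=level)

    def summary(self) -> str:
        r = self._result
        lines = [
            "Change in expected length of stay (three-state model)",
            "=" * 56,
            f"n patients                 {r.n_patients}",
            f"integration horizon tau    {r.tau:.1f} days",
            f"intervention times used    {len(r.s_times)}",
            f"delta (change in LOS)      {r.delta:.2f} days",
            f"bed days released/patient  {r.bed_days_released:.2f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return self._result.to_dict()


class EconModel:
    """Monte Carlo economic model over bed-days-released draws.

    ``draws`` is typically ``BootstrapResult.bed_days_released``; ``config``
    holds costs, caseload bounds, simulation count and WTP threshold.
    """

    def __init__(self, draws, config: EconConfig = EconConfig()):
        self.draws = np.asarray(draws, dtype=float)
        self.config = config

    def run(self, seed: Optional[int] = None) -> EconSimResult:
        config = self.config
        if seed is not None:
            from dataclasses import replace

            config = replace(config, seed=seed)
        return run_monte_carlo(self.draws, config)
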