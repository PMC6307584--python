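"""Patient event histories.

A :class:`PatientRecord` is one subject's stay: the time from admission to
receipt of the intervention (if any), the time from admission to discharge or
censoring, an event indicator, and basic demographics.  Admission is the time
origin (day 0) for every record; times are durations in days and may be
fractional.

The three-state process behind a record is

    0  in hospital, pre-intervention
    1  in hospital, post-intervention (the intermediate state)
    2  discharged (absorbing)

A control-cohort patient never enters state 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .exceptions import ValidationError

COHORT_CONTROL = "control"
COHORT_INTERVENTION = "intervention_era"
COHORTS = (COHORT_CONTROL, COHORT_INTERVENTION)

SEX_FEMALE = "female"
SEX_MALE = "male"


@dataclass(frozen=True)
class PatientRecord:
    """One subject's event history plus demographics.

    Parameters
    ----------
    patient_id : str
        Opaque identifier.
    cohort : str
        ``"control"`` or ``"intervention_era"``.
    t_intervention : float or None
        Days from admission to entering the intermediate state; ``None`` if
        the patient never receives the intervention.  Must satisfy
        ``0 < t_intervention <= t_end`` when present.  Control records never
        carry it.
    t_end : float
        Days from admission to discharge or censoring; strictly positive.
    discharged : bool
        True if ``t_end`` is a discharge, False if censored.
    age : float, optional
        Age in years at admission.
    sex : str, optional
        ``"female"`` or ``"male"``.
    """

    patient_id: str
    cohort: str
    t_intervention: Optional[float]
    t_end: float
    discharged: bool
    age: Optional[float] = None
    sex: Optional[str] = None

    def errors(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        out = []
        pid = self.patient_id
        if self.cohort not in COHORTS:
            out.append(f"{pid}: unknown cohort {self.cohort!r}")
        if not (isinstance(self.t_end, (int, float)) and math.isfinite(self.t_end)):
            out.append(f"{pid}: t_end is not a finite number")
        elif self.t_end <= 0:
            out.append(f"{pid}: t_end must be > 0, got {self.t_end}")
        ti = self.t_intervention
        if ti is not None:
            if self.cohort == COHORT_CONTROL:
                out.append(f"{pid}: control record has t_intervention set")
            if not (isinstance(ti, (int, float)) and math.isfinite(ti)):
                out.append(f"{pid}: t_intervention is not a finite number")
            elif ti <= 0:
                out.append(f"{pid}: t_intervention must be > 0, got {ti}")
            elif isinstance(self.t_end, (int, float)) and ti > self.t_end:
                out.append(
                    f"{pid}: t_intervention ({ti}) exceeds t_end ({self.t_end})"
                )
        if self.sex is not None and self.sex not in (SEX_FEMALE, SEX_MALE):
            out.append(f"{pid}: unknown sex {self.sex!r}")
        return out

    def validate(self) -> "PatientRecord":
        errs = self.errors()
        if errs:
            raise ValidationError(errs)
        return self


def validate_records(records: Sequence[PatientRecord]) -> None:
    """Validate a cohort, collecting every violation into one error."""
    msgs: list[str] = []
    for rec in records:
        msgs.extend(rec.errors())
    if msgs:
        raise ValidationError(msgs)


@dataclass
class CohortArrays:
    """Columnar view of a cohort used by the estimators.

    ``t_intervention`` is NaN where the record has no intermediate event.
    """

    t_intervention: np.ndarray
    t_end: np.ndarray
    discharged: np.ndarray
    cohort: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n(self) -> int:
        return self.t_end.shape[0]

    def take(self, idx: np.ndarray) -> "CohortArrays":
        return CohortArrays(
            self.t_intervention[idx],
            self.t_end[idx],
            self.discharged[idx],
            None if self.cohort is None else self.cohort[idx],
        )


def cohort_arrays(records: Iterable[PatientRecord]) -> CohortArrays:
    """Convert records to the columnar form, NaN-coding absent interventions."""
    recs = list(records)
    ti = np.array(
        [np.nan if r.t_intervention is None else float(r.t_intervention) for r in recs]
    )
    te = np.array([float(r.t_end) for r in recs])
    dis = np.array([bool(r.discharged) for r in recs])
    coh = np.array([r.cohort for r in recs])
    return CohortArrays(ti, te, dis, coh)
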