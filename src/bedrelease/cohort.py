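"""Baseline cohort comparison (Table-1-style).

Group summaries per cohort, a Welch-type comparison of mean age (unpooled
variances and Welch-Satterthwaite degrees of freedom by default, pooled as
an option), and a chi-squared test of the sex split with Yates continuity
correction by default (the uncorrected statistic is exposed too).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidParameterError
from .records import (
    COHORT_CONTROL,
    COHORT_INTERVENTION,
    SEX_FEMALE,
    SEX_MALE,
    PatientRecord,
)

__all__ = [
    "GroupSummary",
    "group_summaries",
    "welch_mean_difference",
    "yates_chisq",
    "compare_cohorts",
]


@dataclass(frozen=True)
class GroupSummary:
    cohort: str
    n: int
    mean_age: float
    sd_age: float
    female: int
    male: int


class MeanDifference(NamedTuple):
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float


def welch_mean_difference(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    level: float = 0.95,
    pooled: bool = False,
) -> MeanDifference:
    """Two-sample mean difference (group 2 minus group 1) with CI and p.

    Welch's unpooled-variance version by default; ``pooled=True`` uses the
    classic equal-variance t test.  Works from summary statistics, so it can
    reproduce published comparisons without patient-level data.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidParameterError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise InvalidParameterError("standard deviations must be positive")
    if not (0.0 < level < 1.0):
        raise InvalidParameterError("level must be in (0, 1)")
    diff = mean2 - mean1
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if pooled:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = float(np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
        df = float(n1 + n2 - 2)
    else:
        se = float(np.sqrt(v1 + v2))
        df = float((v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)))
    tcrit = float(stats.t.ppf(1.0 - (1.0 - level) / 2.0, df))
    tstat = diff / se
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    return MeanDifference(diff, diff - tcrit * se, diff + tcrit * se, p, df)


def yates_chisq(table, correction: bool = True) -> tuple[float, float]:
    """Chi-squared test of independence on a 2x2 table, 1 df.

    Yates continuity correction is applied by default (``correction=False``
    gives the uncorrected Pearson statistic).  Delegates to
    :func:`scipy.stats.chi2_contingency`.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise InvalidParameterError("table must be 2x2")
    if np.any(arr < 0):
        raise InvalidParameterError("cell counts must be >= 0")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise InvalidParameterError("both margins must be positive")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue)


def group_summaries(records: Sequence[PatientRecord]) -> list[GroupSummary]:
    """Per-cohort n, age mean/SD and sex counts (records missing age or sex
    are excluded from the corresponding summary)."""
    out = []
    for cohort in (COHORT_CONTROL, COHORT_INTERVENTION):
        recs = [r for r in records if r.cohort == cohort]
        if not recs:
            continue
        ages = np.array([r.age for r in recs if r.age is not None], dtype=float)
        female = sum(1 for r in recs if r.sex == SEX_FEMALE)
        male = sum(1 for r in recs if r.sex == SEX_MALE)
        out.append(
            GroupSummary(
                cohort=cohort,
                n=len(recs),
                mean_age=float(np.mean(ages)) if len(ages) else float("nan"),
                sd_age=float(np.std(ages, ddof=1)) if len(ages) > 1 else float("nan"),
                female=female,
                male=male,
            )
        )
    return out


def compare_cohorts(
    records: Sequence[PatientRecord],
    level: float = 0.95,
    pooled_t: bool = False,
    continuity_correction: bool = True,
) -> dict:
    """Table-1-style comparison of the two cohorts.

    Returns group summaries, the mean-age difference (intervention minus
    control) with its CI and p value, and the chi-squared test of the sex
    split.
    """
    summaries = {s.cohort: s for s in group_summaries(records)}
    if COHORT_CONTROL not in summaries or COHORT_INTERVENTION not in summaries:
        raise InvalidParameterError("both cohorts must be present to compare")
    ctrl, intv = summaries[COHORT_CONTROL], summaries[COHORT_INTERVENTION]
    age = welch_mean_difference(
        ctrl.mean_age, ctrl.sd_age, ctrl.n,
        intv.mean_age, intv.sd_age, intv.n,
        level=level, pooled=pooled_t,
    )
    sex_table = [[ctrl.female, intv.female], [ctrl.male, intv.male]]
    chi2, chi2_p = yates_chisq(sex_table, correction=continuity_correction)
    return {
        "groups": pd.DataFrame(
            [
                {
                    "cohort": s.cohort,
                    "n": s.n,
                    "age_mean": s.mean_age,
                    "age_sd": s.sd_age,
                    "female": s.female,
                    "male": s.male,
                }
                for s in (ctrl, intv)
            ]
        ),
        "age_difference": age._asdict(),
        "sex_chi2": {"statistic": chi2, "p_value": chi2_p, "table": sex_table},
        "level": level,
    }
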