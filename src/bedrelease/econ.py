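"""Monte Carlo economic model for bed days released.

Converts a distribution of bed-days-released-per-patient (typically the
bootstrap replicates of the multistate estimate) into annual bed days
released, cost per bed day, and the probability that the cost per bed day
falls below a decision maker's willingness to pay (WTP), generalised over a
WTP grid as a cost-effectiveness acceptability curve (CEAC).

Each simulation draws the per-patient bed days ``b`` from the supplied
distribution and the monthly caseload ``m`` from a uniform distribution,
then

    annual bed days = b * m * months
    cost per bed day = total annual cost / annual bed days.

Costs are treated as known with certainty and are not discounted (the
horizon is a single year).  Simulations with ``b <= 0`` release no bed days,
so their cost per day is undefined: they are excluded from the cost
summaries, counted, and treated as *not* meeting the WTP criterion — the
conservative choice for decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import EconEvaluationUndefinedError, InvalidParameterError

__all__ = ["EconConfig", "EconSimResult", "run_monte_carlo", "summarize", "ceac"]

#: Default annual staffing costs (2017 AUD): one full-time specialist social
#: worker and one social work assistant.
DEFAULT_COST_COMPONENTS = (
    ("specialist social worker", 158_000.0),
    ("social work assistant", 71_000.0),
)


@dataclass(frozen=True)
class EconConfig:
    """Inputs of the economic simulation.

    ``total_cost_override`` defaults to 228 876 AUD — the study-style exact
    annual running cost — while the component sum (229 000 to the nearest
    thousand) remains available via :attr:`component_cost`; set the override
    to ``None`` to use the component sum.  ``patients_per_month`` is uniform
    on [low, high], continuous by default with a discrete option.
    """

    cost_components: tuple = DEFAULT_COST_COMPONENTS
    total_cost_override: Optional[float] = 228_876.0
    months: int = 12
    patients_per_month_low: float = 20.0
    patients_per_month_high: float = 30.0
    n_sims: int = 1000
    wtp: float = 216.0
    seed: Optional[int] = None
    discrete_caseload: bool = False
    paired: bool = False  # one-to-one pass over the draws when sizes match

    def validate(self) -> "EconConfig":
        if any(c < 0 for _, c in self.cost_components):
            raise InvalidParameterError("cost components must be >= 0")
        if self.total_cost_override is not None and self.total_cost_override < 0:
            raise InvalidParameterError("total cost must be >= 0")
        if self.patients_per_month_low > self.patients_per_month_high:
            raise InvalidParameterError("caseload low bound exceeds high bound")
        if self.n_sims < 1:
            raise InvalidParameterError("n_sims must be >= 1")
        if self.months < 1:
            raise InvalidParameterError("months must be >= 1")
        return self

    @property
    def component_cost(self) -> float:
        return float(sum(c for _, c in self.cost_components))

    @property
    def total_cost(self) -> float:
        if self.total_cost_override is not None:
            return float(self.total_cost_override)
        return self.component_cost


_ROW_LABELS = {
    "bed_days_per_patient": "Total bed days released per patient managed",
    "patients_per_month": "Average number of patients managed per month",
    "annual_bed_days": "Total bed days released per year",
    "cost_per_bed_day": "Average cost to save 1 bed day",
}


@dataclass
class EconSimResult:
    """Per-simulation draws and decision summaries.

    The four vectors are aligned and restricted to the usable simulations
    (those with positive bed days released); ``n_nonpositive`` counts the
    excluded ones, so ``n_sims = len(b) + n_nonpositive``.
    """

    b: np.ndarray
    m: np.ndarray
    annual_bed_days: np.ndarray
    cost_per_bed_day: np.ndarray
    n_sims: int
    n_nonpositive: int
    total_cost: float
    wtp: float
    p_meets_wtp: float
    config: EconConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def summary(self, rounded: bool = False) -> pd.DataFrame:
        return summarize(self, rounded=rounded)

    def ceac_curve(self, wtp_grid: Sequence[float]) -> pd.DataFrame:
        return ceac(self, wtp_grid)


def run_monte_carlo(
    bed_day_draws: Sequence[float], config: EconConfig = EconConfig()
) -> EconSimResult:
    """Run the Monte Carlo economic simulation.

    ``bed_day_draws`` is any non-empty collection of bed-days-released
    values (e.g. ``BootstrapResult.bed_days_released``); each simulation
    samples one with replacement, independently of the caseload draw.  With
    ``config.paired`` and ``n_sims`` equal to the number of draws, the draws
    are passed over one-to-one instead.  Deterministic given ``config.seed``.
    """
    config.validate()
    draws = np.asarray(bed_day_draws, dtype=float)
    if draws.size == 0:
        raise InvalidParameterError("bed_day_draws must be non-empty")
    if not np.any(draws > 0):
        raise EconEvaluationUndefinedError(
            "all bed-day draws are non-positive; cost per bed day released "
            "is undefined"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_sims
    if config.paired and draws.size == n:
        b = draws.copy()
    else:
        b = rng.choice(draws, size=n, replace=True)
    if config.discrete_caseload:
        m = rng.integers(
            int(config.patients_per_month_low),
            int(config.patients_per_month_high) + 1,
            size=n,
        ).astype(float)
    else:
        m = rng.uniform(
            config.patients_per_month_low, config.patients_per_month_high, size=n
        )

    usable = b > 0
    n_nonpositive = int(np.count_nonzero(~usable))
    b_u, m_u = b[usable], m[usable]
    annual = b_u * m_u * config.months
    total = config.total_cost
    cost_per = total / annual
    # non-positive simulations count against the criterion, never for it
    p_meets = float(np.count_nonzero(cost_per < config.wtp) / n)
    return EconSimResult(
        b=b_u,
        m=m_u,
        annual_bed_days=annual,
        cost_per_bed_day=cost_per,
        n_sims=n,
        n_nonpositive=n_nonpositive,
        total_cost=total,
        wtp=config.wtp,
        p_meets_wtp=p_meets,
        config=config,
    )


def summarize(result: EconSimResult, rounded: bool = False) -> pd.DataFrame:
    """Mean/SD/min/max table over the usable simulations.

    With ``rounded=True`` the rendering mirrors reporting practice: bed days
    and caseloads to whole numbers, costs to whole dollars.
    """
    rows = {}
    for key, vec in (
        ("bed_days_per_patient", result.b),
        ("patients_per_month", result.m),
        ("annual_bed_days", result.annual_bed_days),
        ("cost_per_bed_day", result.cost_per_bed_day),
    ):
        rows[_ROW_LABELS[key]] = [
            float(np.mean(vec)),
            float(np.std(vec, ddof=1)) if len(vec) > 1 else 0.0,
            float(np.min(vec)),
            float(np.max(vec)),
        ]
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean", "sd", "min", "max"]
    )
    if rounded:
        df = df.round(0).astype(int)
    return df


def ceac(result: EconSimResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid.

    For each threshold, the probability (over all ``n_sims`` simulations,
    non-positive ones counting as failures) that the cost per bed day
    released falls below it.  Non-decreasing in WTP by construction.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise InvalidParameterError("wtp_grid must be non-empty")
    costs = np.sort(result.cost_per_bed_day)
    prob = np.searchsorted(costs, grid, side="left") / result.n_sims
    return pd.DataFrame({"wtp": grid, "probability": prob})
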