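"""Aalen-Johansen machinery for the three-state length-of-stay model.

States: 0 = in hospital pre-intervention, 1 = in hospital post-intervention,
2 = discharged (absorbing); no backward transitions.  The quantity of
interest is the change in expected length of stay attributable to the
intermediate event,

    delta = sum_s phi(s) w(s),
    phi(s) = e_1(s) - e_0(s),

where ``e_j(s)`` is the expected LOS given occupancy of state j at time s
(computed from the Aalen-Johansen transition matrices ``P(s, t)``) and the
weights ``w(s)`` are the normalised increments of the cumulative probability
``F_1`` of experiencing the intermediate event.  Negative delta means the
intervention is associated with shorter stays; bed days released per patient
is ``-delta``.

Tie conventions (day-granular data makes ties common): at an equal time,
0->1 entries are processed before 1->2 exits, and transitions before
censorings; a patient with ``t_intervention == t_end`` gets an infinitesimal
state-1 sojourn.  The integration horizon is the largest observed event time
(truncated estimator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EstimandUndefinedError,
    InvalidParameterError,
    InvalidStateError,
    ValidationError,
)
from .records import CohortArrays, PatientRecord, cohort_arrays, validate_records

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionTable",
    "TransitionProbabilities",
    "ClosResult",
    "build_transition_table",
    "aalen_johansen",
    "expected_los_given_state",
    "estimate_clos",
]


@dataclass
class TransitionTable:
    """Counts and risk sets at each distinct event time.

    ``times`` is strictly increasing.  At each time u: ``d01``, ``d02``,
    ``d12`` are transition counts, ``c0``/``c1`` censoring counts by state,
    ``y0`` the number at risk in state 0 just before u, and ``y1`` the
    number at risk in state 1 at u *after* processing the 0->1 entries at u
    (so same-time entrants are at risk for the 1->2 exit, per the tie
    convention).
    """

    times: np.ndarray
    d01: np.ndarray
    d02: np.ndarray
    d12: np.ndarray
    c0: np.ndarray
    c1: np.ndarray
    y0: np.ndarray
    y1: np.ndarray
    n_patients: int

    @property
    def n_times(self) -> int:
        return len(self.times)

    def hazard_increments(self):
        """Nelson-Aalen increments dA01, dA02, dA12 (0 where risk set empty)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            a01 = np.where(self.y0 > 0, self.d01 / self.y0, 0.0)
            a02 = np.where(self.y0 > 0, self.d02 / self.y0, 0.0)
            a12 = np.where(self.y1 > 0, self.d12 / self.y1, 0.0)
        return a01, a02, a12

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "d01": self.d01,
                "d02": self.d02,
                "d12": self.d12,
                "censored_state0": self.c0,
                "censored_state1": self.c1,
                "Y0": self.y0,
                "Y1": self.y1,
            }
        )


def _table_from_arrays(arr: CohortArrays) -> TransitionTable:
    ti, te, dis = arr.t_intervention, arr.t_end, arr.discharged
    has_i = ~np.isnan(ti)
    exit0 = np.where(has_i, ti, te)  # time of leaving state 0, whatever the route

    times = np.unique(np.concatenate([exit0, te]))
    K = len(times)

    def counts(values) -> np.ndarray:
        pos = np.searchsorted(times, values)
        return np.bincount(pos, minlength=K)

    d01 = counts(ti[has_i])
    d02 = counts(te[~has_i & dis])
    d12 = counts(te[has_i & dis])
    c0 = counts(te[~has_i & ~dis])
    c1 = counts(te[has_i & ~dis])

    exit0_sorted = np.sort(exit0)
    y0 = arr.n - np.searchsorted(exit0_sorted, times, side="left")
    ti_sorted = np.sort(ti[has_i])
    te1_sorted = np.sort(te[has_i])
    y1 = np.searchsorted(ti_sorted, times, side="right") - np.searchsorted(
        te1_sorted, times, side="left"
    )
    return TransitionTable(times, d01, d02, d12, c0, c1, y0, y1, arr.n)


def build_transition_table(records: Sequence[PatientRecord]) -> TransitionTable:
    """Tabulate counts and risk sets from validated patient records.

    Raises :class:`ValidationError` (naming the offending patient ids) on
    invalid records, and on an empty record list.
    """
    records = list(records)
    if not records:
        raise ValidationError("empty record list")
    validate_records(records)
    return _table_from_arrays(cohort_arrays(records))


@dataclass
class TransitionProbabilities:
    """Aalen-Johansen transition matrices from origin ``s``.

    ``times[0] == s`` with the identity matrix; subsequent entries are the
    event times after ``s`` with the right-continuous products
    ``P(s, t) = prod_{u in (s, t]} (I + dA(u))``.
    """

    s: float
    times: np.ndarray
    matrices: np.ndarray  # shape (len(times), 3, 3)

    def at(self, t: float) -> np.ndarray:
        """P(s, t) for any t >= s (step-constant between event times)."""
        if t < self.s:
            raise InvalidParameterError("t must be >= origin s")
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.matrices[max(idx, 0)]

    def in_hospital(self, j: int) -> np.ndarray:
        """P_j0(s, t) + P_j1(s, t) on the grid."""
        return self.matrices[:, j, 0] + self.matrices[:, j, 1]


def aalen_johansen(table: TransitionTable, s: float = 0.0) -> TransitionProbabilities:
    """Aalen-Johansen estimate of P(s, t) on the event-time grid after s.

    Each increment matrix is I + dA(u) with dA01 = d01/Y0, dA02 = d02/Y0,
    dA12 = d12/Y1 and diagonal entries making every row sum to one;
    increments with an empty risk set contribute the identity.
    """
    if s < 0:
        raise InvalidParameterError("origin s must be >= 0")
    a01, a02, a12 = table.hazard_increments()
    after = table.times > s
    if not np.any(after):
        logger.info("origin s=%s is beyond the last event time; returning identity", s)
        return TransitionProbabilities(
            s=float(s), times=np.array([float(s)]), matrices=np.eye(3)[None, :, :]
        )
    idx = np.flatnonzero(after)
    K = len(idx)
    mats = np.empty((K + 1, 3, 3))
    mats[0] = np.eye(3)
    P = np.eye(3)
    for out, k in enumerate(idx, start=1):
        M = np.array(
            [
                [1.0 - a01[k] - a02[k], a01[k], a02[k]],
                [0.0, 1.0 - a12[k], a12[k]],
                [0.0, 0.0, 1.0],
            ]
        )
        P = P @ M
        mats[out] = P
    times = np.concatenate([[float(s)], table.times[idx]])
    return TransitionProbabilities(s=float(s), times=times, matrices=mats)


def expected_los_given_state(
    P: TransitionProbabilities, s: float, j: int, tau: float
) -> float:
    """Expected length of stay given occupancy of state ``j`` at time ``s``.

    Integrates the in-hospital probability ``P_j0(s, .) + P_j1(s, .)`` as a
    right-continuous step function over ``[s, tau)``:

        e_j(s) = s + sum_k (u_{k+1} - u_k) [P_j0(s, u_k) + P_j1(s, u_k)]

    with the grid clipped at ``tau`` (beyond which the in-hospital
    probability is treated as zero — truncated estimator).
    """
    if j == 2:
        raise InvalidStateError(
            "expected LOS conditional on the discharged state is not defined"
        )
    if j not in (0, 1):
        raise InvalidStateError(f"state must be 0 or 1, got {j}")
    if abs(s - P.s) > 1e-12:
        raise InvalidParameterError(
            f"s={s} does not match the origin of the supplied matrices (P.s={P.s})"
        )
    if tau < s:
        raise InvalidParameterError("tau must be >= s")
    inside = P.times < tau
    ts = P.times[inside]
    if len(ts) == 0:
        return float(s)
    vals = P.in_hospital(j)[inside]
    edges = np.append(ts, tau)
    return float(s + np.sum(np.diff(edges) * vals))


@dataclass
class ClosResult:
    """Estimated change in expected LOS and its decomposition over time.

    ``delta`` (days, signed; negative = intervention associated with shorter
    stay) is the weighted average of ``phi(s) = e_1(s) - e_0(s)`` over the
    observed 0->1 transition times ``s_times``, with weights proportional to
    the increments of the cumulative intermediate-event probability F_1.
    """

    delta: float
    s_times: np.ndarray
    phi: np.ndarray
    weights: np.ndarray
    tau: float
    n_patients: int

    @property
    def bed_days_released(self) -> float:
        """Bed days released per patient managed (positive is a saving)."""
        return -self.delta

    def to_dict(self) -> dict:
        return {
            "delta_days": float(self.delta),
            "bed_days_released_per_patient": float(self.bed_days_released),
            "s_times": [float(x) for x in self.s_times],
            "phi": [float(x) for x in self.phi],
            "weights": [float(x) for x in self.weights],
            "tau": float(self.tau),
            "n_patients": int(self.n_patients),
        }


def _backward_scan(d: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Solve x[k] = d[k] + g[k] * x[k+1] backwards with x[n] = 0, vectorised.

    Propagation stops at exact zeros of ``g``, so the arrays are split into
    segments at those positions and each segment is solved with prefix
    products and suffix sums (O(n) overall).
    """
    n = len(d)
    x = np.empty(n)
    if n == 0:
        return x
    zero = np.flatnonzero(g == 0.0)
    starts = np.concatenate(([0], zero + 1))
    ends = np.concatenate((zero, [n - 1]))
    for a, b in zip(starts, ends):
        if a > b:
            continue
        seg_g = g[a:b + 1]
        G = np.empty(b - a + 1)
        G[0] = 1.0
        if b > a:
            G[1:] = np.cumprod(seg_g[:-1])
        terms = d[a:b + 1] * G
        suffix = np.cumsum(terms[::-1])[::-1]
        x[a:b + 1] = suffix / G
    return x


def _clos_from_table(table: TransitionTable) -> ClosResult:
    if int(table.d01.sum()) == 0:
        raise EstimandUndefinedError(
            "no transitions into the intermediate state were observed"
        )
    if int(table.d02.sum() + table.d12.sum()) == 0:
        raise EstimandUndefinedError("no discharges were observed")

    s_idx = np.flatnonzero(table.d01 > 0)
    if (
        len(s_idx) == 1
        and s_idx[0] == 0
        and table.d01[0] == table.y0[0] == table.n_patients
    ):
        raise EstimandUndefinedError(
            "every patient enters the intermediate state at the first event "
            "time; no one is ever at risk in the initial state afterwards, so "
            "the weighting over intervention times has no support"
        )

    a01, a02, a12 = table.hazard_increments()
    t = table.times
    K = len(t)
    dt = np.diff(t)

    # e_1(t_k) - t_k: backward recursion for the integrated P_11
    Eg = np.zeros(K)
    if K > 1:
        Eg[:-1] = _backward_scan(dt, (1.0 - a12)[1:])

    # e_0(t_k) - t_k: same recursion with the 0->1 inflow feeding into Eg
    W = np.zeros(K)
    if K > 1:
        d_in = dt + a01[1:] * Eg[1:]
        W[:-1] = _backward_scan(d_in, (1.0 - a01 - a02)[1:])

    phi_full = Eg - W

    # weights: increments of F_1(s) = sum_{u <= s} P_00(0, u-) dA01(u)
    c0v = 1.0 - a01 - a02
    H0 = np.empty(K)
    H0[0] = 1.0
    if K > 1:
        H0[1:] = np.cumprod(c0v[:-1])
    dF1 = H0 * a01
    F1_tau = float(dF1.sum())
    if F1_tau <= 0.0:
        raise EstimandUndefinedError(
            "cumulative intermediate-event probability is zero at the horizon"
        )

    weights = dF1[s_idx] / F1_tau
    phi = phi_full[s_idx]
    delta = float(np.sum(phi * weights))
    return ClosResult(
        delta=delta,
        s_times=t[s_idx].copy(),
        phi=phi,
        weights=weights,
        tau=float(t[-1]),
        n_patients=int(table.n_patients),
    )


def estimate_clos(
    records: Optional[Sequence[PatientRecord]] = None,
    *,
    arrays: Optional[CohortArrays] = None,
    cohort: Optional[str] = None,
) -> ClosResult:
    """Estimate the change in expected LOS attributable to the intervention.

    By default the full pooled sample forms one risk set (controls contribute
    only direct-discharge transitions); ``cohort`` restricts the analysis to
    one cohort label.  ``arrays`` offers a pre-columnised fast path used by
    the bootstrap.

    Raises :class:`EstimandUndefinedError` when there are no intermediate
    events (or the weighting degenerates), per the estimand's definition.
    """
    if arrays is None:
        if records is None:
            raise InvalidParameterError("provide records or arrays")
        records = list(records)
        if cohort is not None:
            records = [r for r in records if r.cohort == cohort]
        if not records:
            raise ValidationError("empty record list")
        validate_records(records)
        arrays = cohort_arrays(records)
    elif cohort is not None and arrays.cohort is not None:
        arrays = arrays.take(np.flatnonzero(arrays.cohort == cohort))
    return _clos_from_table(_table_from_arrays(arrays))
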