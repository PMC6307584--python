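# Methods

## The estimand

Let `X_t ∈ {0, 1, 2}` be a patient's state at time `t` from admission:
in hospital pre-intervention (0), in hospital post-intervention (1),
discharged (2, absorbing; no backward transitions).  For an origin `s` and
state `j ∈ {0, 1}` define the expected length of stay

    e_j(s) = s + ∫_s^τ [P_j0(s, u) + P_j1(s, u)] du ,

with `P(s, t)` the transition-probability matrix and `τ` the largest
observed event time.  The change in expected LOS attributable to the
intermediate event is the weighted average

    delta = Σ_s phi(s) w(s),   phi(s) = e_1(s) − e_0(s),
    w(s) ∝ ΔF_1(s),            F_1(s) = Σ_{u ≤ s} P_00(0, u−) dA_01(u),

where `F_1` is the cumulative probability of experiencing the intermediate
event and the sum runs over observed 0→1 transition times.  Conditioning on
the state occupied at `s` is what protects the comparison from
time-dependent bias: patients must remain in hospital to become treated, so
comparing raw cohort means conflates treatment with survival in state 0.
The weighting by `ΔF_1` is the standard population-averaging choice for
this family of estimators; it is the one methodological reconstruction in
the package (the weighting is rarely restated in applied reports), and it
is exposed through `ClosResult.phi`/`weights` so any other weighting can be
recomputed from the decomposition.

## Estimation

`P(s, t)` is the Aalen–Johansen estimator: the product over event times
`u ∈ (s, t]` of `I + dA(u)` with `dA_01 = d_01/Y_0`, `dA_02 = d_02/Y_0`,
`dA_12 = d_12/Y_1`, diagonal entries completing each row to 1, and identity
increments where a risk set is empty.  With no 0→1 transitions the 0→2
entry collapses to the Kaplan–Meier estimator exactly (bit-identical; this
is a regression test).

Conventions:

- **Ties** (common in day-granular data): at an equal time, 0→1 entries are
  processed before 1→2 exits, and transitions before censorings.  A patient
  with `t_intervention == t_end` receives an infinitesimal state-1 sojourn:
  they count in `d_01`, in the state-1 risk set at that time, and in
  `d_12`.
- **Horizon**: `τ` = largest observed event time; the in-hospital
  probability beyond `τ` is treated as zero (truncated estimator).  With
  heavy censoring near `τ` both `e_0` and `e_1` are truncated alike, so
  `phi` is attenuated rather than directionally biased.
- **Support**: `phi(s)` is evaluated only at times with `d_01(s) > 0`;
  other times carry zero weight through `ΔF_1`.  If every patient enters
  state 1 at the first event time, no one is ever at risk in state 0
  afterwards and the estimand is reported as undefined rather than silently
  degrading to a difference of means.
- **Pooling**: both cohorts share one risk set (controls contribute only
  0→2 transitions), with a cohort filter available.  Time origin is
  admission for both cohorts; no left truncation.
- **Censoring**: censored patients contribute to risk sets up to their
  censoring time; nothing is imputed beyond the product-limit machinery.

Internally `e_0(s)` and `e_1(s)` for *all* origins are computed in one
O(K) backward pass (K = number of event times) via the linear recurrences

    E_1(u_k) = Δ_k + (1 − dA_12(u_{k+1})) E_1(u_{k+1})
    E_0(u_k) = Δ_k + (1 − dA_01 − dA_02)(u_{k+1}) E_0(u_{k+1})
                   + dA_01(u_{k+1}) E_1(u_{k+1})

solved with a segment-safe vectorised scan (segments split at exact zeros
of the multipliers, so an exhausted risk set never produces a 0/0).  The
equivalence of this fast path with the direct route — a full `P(s, ·)`
product followed by step-function integration — is property-tested on
small tied and censored cohorts to 1e−9.

## Inference

Percentile bootstrap over whole patients: `B` resamples (default 1000) of
`n` patients with replacement from the pooled sample (stratified-by-cohort
optional; unstratified is the default because the estimand is defined on
the pooled risk set), re-estimating delta on each.  Replicates with an
undefined estimand are dropped and counted; more than 50% failures abort
with advice to collect more data.  Percentile rather than BCa intervals:
the replicate distribution is reported directly (histogram export), and no
analytic variance is attempted.

## Economic model

Per simulation: bed days released per patient `b` is drawn with replacement
from the supplied distribution (one-to-one pairing optional when the draw
count matches), monthly caseload `m` ~ Uniform(20, 30) — read as
continuous, with a discrete option — and

    annual bed days = b · m · months,
    cost per bed day = total cost / annual bed days.

Costs default to the two staffing components ($158 000 + $71 000 a year)
with a total-cost override of $228 876 as the default effective total (the
override keeps the summary arithmetic internally consistent with the
component sum shown separately as $229 000 at the nearest thousand); they
are treated as known and undiscounted over the one-year horizon.
Simulations with `b ≤ 0` have no defined cost per day: they are excluded
from cost summaries, counted, and treated as failing the WTP criterion —
conservative for the decision.  The CEAC reports, for each threshold on a
WTP grid, the fraction of *all* simulations whose cost per bed day falls
strictly below it; at the default $216 threshold it equals `p_meets_wtp`.
This is a decision-probability analysis, not a full cost-effectiveness
analysis: health outcomes are not valued.

## Cohort comparison

Welch's unpooled-variance t machinery (difference, Welch–Satterthwaite df,
CI, p) computed from summary statistics so published comparisons can be
reproduced without patient data; a pooled-variance option exists.  The sex
split uses the chi-squared test with Yates continuity correction by
default — on small 2×2 tables the corrected p (≈0.66 on the 23/37 vs 23/29
split) differs noticeably from the uncorrected one (≈0.53) — with the
uncorrected statistic exposed.

## Synthetic data

**Markov oracle scenario.**  Competing exponential clocks: 0→1 at `α01`
(≥ 0; zero disables the intervention), 0→2 at `α02`, then 1→2 at `α12`,
optional administrative censoring, iid draws.  Under homogeneity the
estimand is constant in `s` and equals

    phi = 1/α12 − [ 1/(α01+α02) + α01 / ((α01+α02)·α12) ] ,

implemented as `closed_form_clos` and used as the recovery oracle
(−26.67 days at α = (0.02, 0.01, 0.05)) together with the analytic
state-occupation curves.  This scenario stays strictly iid because the
bootstrap-coverage and Monte Carlo-error arguments in the tests assume it.

**Study-like scenario.**  52 intervention-era patients following the
three-state process and 60 controls discharged at a single exponential
rate; ages N(69, 18²) (control) and N(74, 14²) (intervention) clipped to
[18, 105]; female counts 23/60 and 23/52.  Hazards were calibrated by a
coarse grid over exponential rates: the competing-exponential identity
makes the observed time-to-intervention Exp(α01+α02), so `α01+α02 =
ln 2 / 25` pins its median at 25 days (implied IQR 10.4–50 days); a 9:1
split sends ~90% of the cohort through the intermediate state; `α12 =
0.0566` and a control rate of 1/85 give cohort mean stays of ≈52 and ≈85
days, pooling to ≈70 at 52/60 weights, with a sample range of roughly 0.3
to 400+ days.  The generator's contract is to *emulate published marginal
summaries within tolerances*; at n = 112 an iid exponential sample's
pooled mean has an SE of ~7 days, so the clocks are drawn by stratified
inverse-CDF sampling (one draw per quantile stratum, shuffled), which
preserves each marginal's shape while pinning the sample moments.  A
calibration check compares the *analytic* moments implied by the hazards
(at the default 52/60 weights) with the configured targets
(mean LOS 70 ± 15, median time-to-intervention 25 ± 10 days) and fails
naming the violated summary; sample-level summaries are asserted in the
test suite.

What the generator does **not** emulate: the selection of historical
controls on an already-met long-stay definition (a bias the study design
carries), the 11 psychosocial risk factors and referral process, covariate
dependence of the hazards, and any LOS–age or LOS–sex association.
Passing tests therefore demonstrate estimator correctness under the stated
sampling model, not robustness to those real-data features.  With both
cohorts pooled, the scenario's implied estimand reflects the gap between
the post-intervention discharge rate and the *pooled* pre-intervention
rate (the slow controls included), which is why end-to-end demo runs show
a larger bed-day effect (≈56 days) than a single-cohort analysis would.

## Problem sizes and numerical choices

Oracle recovery, null invariance and coverage checks run at n = 5000
patients; the coverage study uses 50 experiments at B = 200 replicates;
large-sample simulator checks at n = 100 000.  Tolerances are stated in
Monte Carlo standard errors (3 SEs) wherever a quantity is stochastic;
exact assertions (Kaplan–Meier reduction, weight normalisation, matrix row
sums) use equality or 1e−9.  Quantiles are NumPy's default (linear
interpolation).  Rounded administrative times are supported and
deliberately exercised in tests via the generators' `round_days` mode.

## Known limitations

- No covariate adjustment or Cox-type transition intensities; the
  estimator is fully nonparametric and marginal.
- The truncation at `τ` underestimates both conditional expectations when
  follow-up is short; use longer follow-up or report `τ` alongside delta
  (the results object always carries it).
- Percentile intervals can undercover at small n with skewed replicate
  distributions; the coverage test documents behaviour at n = 5000, not at
  study-sized n = 112.
- The economic layer treats costs as certain and ignores downstream health
  outcomes by design.
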