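# Methods

This note records the models implemented in `hospvol`, the parameter
defaults and why they were chosen, the numerical design, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Volume–outcome curve and performance coefficients

The volume–outcome association is treated as a deterministic relation: a
monotone decreasing curve `m(x)` maps a hospital's annual volume to its
30-day risk-adjusted mortality rate. The empirical curves published for
specific procedures are not available in parametric form, so the package
ships two qualitative stand-ins that reproduce the documented shape (steep
decline at low volume, plateau at high volume):

* `exponential`: `m(x) = m_floor + m_scale·exp(−decay·x)`;
* `power`: `m(x) = m_floor + m_scale·(x+1)^(−decay)` (heavier tail).

Defaults (`m_floor = 0.02`, `m_scale = 0.08`, `decay = 0.02`, exponential)
put mortality at 10% for a zero-volume ward, ≈ 4.9% at the colon-surgery
guideline threshold of 50 interventions/year, and 2% asymptotically —
plausible magnitudes for major abdominal surgery. Rates are clamped to
[0, 1]; fractional volumes are accepted throughout because operational
solutions are probability sums.

The deviation band is proportional, `dev(x) = γ·m(x)` with `γ = 0.3` by
default. A proportional band is a single interpretable knob and guarantees
`m − v·dev ≥ 0` for any admissible performance coefficient, so expected
deaths can never go negative. The performance coefficient itself is the
clamped on-curve residual of last year's outcome,
`v = clamp((observed − m(x_prev)) / dev(x_prev), −1, +1)`, zero when no
history exists, saturating to ±1 when the band is degenerate. This is our
concretization of "compare the real outcome with the curve's prediction";
only its sign/scale convention (negative = better than predicted) matters
downstream.

## Strategic allocation

Decision variables are open flags and integer volumes; the objective
`Σ x·m(x) + x·v·dev(x)` is nonlinear but separable per hospital, and each
hospital's volume lives on the small integer domain `{0} ∪ [lower, cap]`.
The solver therefore tabulates per-hospital cost curves exactly and never
approximates:

* **Province decomposition** (all hospitality thresholds zero, no budget):
  dynamic programming over hospitals × cumulative volume, O(J·I·levels) per
  province. Exact, and fast enough for hundreds of patients per province.
* **Coupled model** (cross-province flows or a budget): each hospital picks
  one volume level via binary indicators with precomputed costs — an exact
  linearization — solved by HiGHS with `mip_rel_gap = 0`.

The provincial-demand constraint is implemented exactly as specified, with
the lower side `I_n − Σ_{n'≠n} δ_{n'}·I_{n'} ≤ Σ_j x_{j_n}`. Note the
asymmetry: the subtracted term aggregates *other* provinces' hospitality
allowances rather than province n's own outflow cap. We implement the stated
inequality verbatim rather than guessing an intent; with all `δ = 0` (the
case every default configuration uses) the two readings coincide.

Case-study planning flags are available on `PlanningFlags`: capacity equal
to twice last year's volume (strategic-level elasticity), the open-volume
lower bound halved outside the capital province, and forced opening of
hospitals that met the threshold last year ("close the inexperienced, not
the compliant"). Hospitals whose capacity cannot reach their applicable
lower bound are excluded before solving. Infeasibility is reported with the
first violated constraint family, never silently repaired.

Ties between equal-objective optima are resolved deterministically: DP
backtracking prefers the smallest admissible volume from the last hospital
backwards, so demand concentrates on the earliest hospital ids. The
convention is arbitrary but fixed; tests that compare solvers compare
objectives.

`brute_force_allocate` enumerates all feasible integer volume vectors
(province by province, with a node-count guard) and exists purely as an
independent optimality oracle for the test suite and the acceptance script.

## Patient choice model

Utilities are linear in distance and in last year's volume, each interacted
with K = 5 patient characteristics (standardized age; binary sex, rurality,
urgent admission, comorbidity — the encoding is ours). Quality always enters
with a one-year lag: patients act on what was observable. The probability
form as sometimes written, `p = U / Σ U`, is ill-defined when utilities are
negative (distance terms always are), and the underlying model is McFadden's
conditional logit; the default is therefore the softmax form with
log-sum-exp stabilization. A `literal-ratio` mode computes the raw ratio and
refuses non-positive utilities, for users who want the printed form on
suitably shifted utilities. Reported probabilities are real numbers in
[0, 1], not binary indicators.

Estimation maximizes the conditional-logit log-likelihood over the
12-parameter vector `(β_d, β_q, α_d, α_q)`. The negative log-likelihood is
convex; we run a Newton trust-region from a zero start with analytic
gradient and Hessian (gradient tolerance 1e-8) and take standard errors from
the inverse observed information. Degenerate inputs — all-singleton choice
sets, perfect separation, non-identified interactions — are flagged as
non-converged rather than raising. No alternative-specific constants or
province fixed effects are included: nothing in the data model identifies
them separately from the volume regressor, and the upstream estimation they
would mimic is not specified.

The implementation is cross-checked in the test suite against an
independent conditional-likelihood fitter (R's `survival::clogit`) on a
deterministic dataset: coefficients, standard errors and the log-likelihood
agree to ~1e-6.

## Integrated three-phase algorithm

* **Phase 1.** Eligibility defaults to `capacity ≥ T`. (The alternative
  reading — last year's volume ≥ T — is selectable via
  `eligibility="prev_volume"`; the capacity reading is the default because
  it is the one consistent with counting eligible hospitals by capacity.)
  `r̃_n` is the shortest prefix of descending eligible capacities covering
  the provincial demand, floored at 1 (with zero hospitality thresholds at
  least one facility per province must stay open). Provincial subsets of
  sizes `r̃_n..H_n` are filtered by capacity ≥ demand; the regional cross
  product is streamed lazily in lexicographic order, with an eager
  materialization guard.
* **Phase 2.** Each admissible set is evaluated by predicting volumes with
  lagged quality and pricing them on the mortality curve *including* the
  performance coefficients `v` — consistent with the premise that surviving
  hospitals were themselves selected on past performance. Mortalities are
  grouped by rounding to the nearest integer; the lowest group is always
  kept, the second and third iff within `θ%` of the lowest. Predicted
  volumes below `T` at an open hospital are reported as threshold
  violations; `strict_threshold=True` disqualifies such sets instead
  (the default reports only, since the disqualification reading cannot be
  pinned down).
* **Phase 3.** `structural` re-solves the strategic model on each
  candidate's choice set (openings pinned) and picks the candidate whose
  operational volumes are L1-closest to that strategic solution. `utility`
  picks the candidate minimizing `Σ_j |g_j(x_prev) − g_j(x_pred)|`, the
  summed per-hospital gap between past and predicted expected deaths — our
  proxy for the past-vs-actual performance discrepancy that patients would
  experience; no formula for this criterion exists upstream. A third,
  workforce-based criterion is qualitative only and out of scope. Ties are
  lexicographic everywhere.

`run_integrated` additionally computes the pure strategic solution, the
patient response to the strategic choice set (the *operational* solution)
and the actual baseline mortality, yielding the four-way comparison. The
θ-rule guarantees the integrated mortality lies within `(1+θ/100)` of the
minimum admissible operational mortality (the bound is exercised on integer
mortality groups; for mortalities near zero the rounding could in principle
loosen it, which never arises at realistic scales of tens of deaths). The
qualitative ordering strategic ≤ integrated ≤ operational is *typical*, not
guaranteed: free patients cross provincial borders that bind the strategic
model, so on some synthetic regions the operational mortality dips below the
strategic optimum. The package reports the ordering rather than asserting
it.

## Synthetic regions

The generator emulates the structural facts of the motivating territory —
about eight provinces, ~53 hospitals, ~1405 annual patients, threshold
T = 50 — with a fully seeded generative model:

* **Volumes** are two-tier: a hub tier of ≈ 30% of each province's
  hospitals (`frac_high = 0.30`) shares 80% of the provincial volume
  (`high_share = 0.80`, lognormal jitter σ = 0.25), the rest scatter over
  small performers (lognormal σ = 1.1). A single lognormal cannot reproduce
  the documented pattern of "~30% of hospitals above 50/year" given
  realistic province sizes — extreme skew just produces one dominant
  hospital per province — whereas the two-tier shape matches how real
  hub-and-spoke territories look.
* **Capacities** are a modest multiple (uniform 1.3–2.2×) of the volume,
  with the largest provincial hospital sized up to cover the whole
  provincial demand (the hub). Genuinely impossible configurations —
  a positive provincial demand below the applicable lower bound, or a
  threshold above every capacity — raise at generation time.
* **Outcomes** scatter uniformly inside ±0.95·dev(x) around the curve, so
  generated performance coefficients span (−1, 1) without clipping
  pile-ups.
* **Geography** is planar: provincial cluster centers in a 200 km box,
  hospitals and patients scattered around them, Euclidean distances. Road
  networks, travel times and borders are not modeled.
* **Patients** have standardized-normal age and Bernoulli binaries
  (sex 0.5, rurality 0.3, urgent admission 0.35, comorbidity 0.4).
* **Default choice coefficients** (`β_d = −0.10` per km, `β_q = +0.01` per
  intervention, `α_d[age] = −0.02`, other interactions zero) make a
  100-intervention quality gap worth about 10 km of travel, with older
  patients more distance-averse — magnitudes in line with the discrete-
  choice literature on hospital choice.

The fixed territory (`piedmont_like_fixture`) hard-codes eligible
capacities so that, at T = 50, the per-province eligible counts are
H = (5, 1, 1, 5, 2, 8, 2, 2) — 26 of 53 hospitals — and the minimum-open
numbers are r̃ = (2, 1, 1, 2, 2, 4, 1, 1). The 1405 patients are split
proportionally to provincial hospital counts (largest-remainder rounding:
239, 79, 79, 239, 133, 424, 106, 106); true per-province patient counts
are not public, so this split is an invention constrained only by the
total. With these (H, r̃) the closed-form pre-filter count is 991,692
choice sets; applying the capacity filter on the fixture's invented
capacities leaves 128,384 admissible sets. (Counts computed on real
capacities would differ; those capacities are not public.)

What passing tests on these regions shows: the algorithms are exact,
deterministic, conserving and internally consistent at realistic scale.
What it does not show: calibration of any specific real territory — the
curve, the coefficients and the geography are plausible stand-ins, not
estimates.

## Problem sizes and numerics

The test suite and the acceptance script run the full integrated pipeline on
a reduced region (3 provinces, 6 hospitals, 300 patients split 140/100/60,
T = 20, θ = 10%) — the provinces are deliberately unequal because a
perfectly symmetric region makes the two information regimes coincide by
softmax translation invariance. Estimation checks use 5,000 simulated
decisions (500 patients × 10 years, 9 hospitals). Solver-oracle sweeps use
two-province instances with ≤ 3 hospitals each and demand ≤ 30, where
exhaustive enumeration is cheap. On the fixed 53-hospital territory the
package runs Phase 1 and the strategic/operational solutions; evaluating all
~1.3·10⁵ admissible choice sets through the patient model is possible but
pointless for verification, so the integrated run is demonstrated at
reduced scale.

Numerical conventions: probabilities normalize to 1 within 1e-12 and
predicted volumes conserve patients within 1e-9 (both tested); solver
optimality is asserted to 1e-9 against enumeration; MIP relative gap is
zero; report round-trips reproduce stored mortalities to 1e-9. All
randomness flows through explicit `numpy` generators seeded by the caller;
no global state.

## Known limitations

* Single procedure; no multi-procedure capacity coupling.
* The volume–outcome relation is deterministic; real curves carry
  volume-dependent uncertainty, largest at low volume.
* Unit costs are synthetic and the budget constraint, though implemented
  and tested, is unused by the default configurations.
* The choice model uses administrative regressors only (distance, lagged
  volume, five characteristics); no waiting times, reputation or survey
  data, and no nested/mixed logit.
* Patient demand is exogenous: closing hospitals never changes who needs
  surgery, only where it happens.
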