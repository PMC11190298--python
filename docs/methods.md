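# Methods

This note documents the models implemented in `ducem`, the conventions they
pin down, and the reasoning behind the choices that were genuinely open.

## Decision problem

Anaprazole (20 mg once daily) and ilaprazole (2 × 5 mg once daily) are
proton-pump inhibitors used for a 4-week course in duodenal ulcer. No
head-to-head trial exists: anaprazole was compared with rabeprazole in one
randomized trial (n = 220 in the anaprazole arm) and ilaprazole with
rabeprazole in another (n = 129). The package (i) compares efficacy and
safety across the two trials through an anchored matching-adjusted indirect
comparison, (ii) projects 48-week costs and QALYs per patient with a cohort
Markov model and judges cost-effectiveness against a willingness-to-pay
(WTP) threshold of 1× China's 2022 per-capita GDP (85,698 ¥/QALY), and
(iii) projects the 3-year budget impact of national listing.

## Synthetic patient-level data

Patient-level data from the anaprazole trial are not deposited, so the
`synthetic` module generates stand-in IPD from the published arm margins:

* age ~ normal truncated to (18, 75) years; the location parameter is
  re-solved (Brent's method) so the *truncated* mean equals the published
  mean — without this, truncation biases the mean upward by ≈0.5 years;
* binary covariates (male sex, stage A1, H. pylori positive, single ulcer)
  are independent Bernoulli draws at the published proportions. Only
  margins are published, so no correlation structure is imposed; this is a
  simplification, and any analysis that depends on covariate correlations
  (e.g. joint balance of interactions) is outside what the synthetic data
  can support;
* outcomes (healing at week 4, any adverse drug reaction) follow a logistic
  model in the five covariates (age standardized). Default coefficients are
  zero — no covariate–outcome association strengths are published — and the
  intercept is calibrated by bisection (tolerance 1e-6) so the expected
  marginal rate equals the published rate exactly.

Consequently, passing tests demonstrate that the *pipeline machinery* is
correct under the published margins; they cannot validate covariate–outcome
structure against the real trials.

## Anchored MAIC

Weights use the method-of-moments MAIC estimator: with covariates centred
at the target aggregate moments, minimizing `Σ exp(αᵀx_centred)` (convex;
we minimize its logarithm, a numerically stable log-sum-exp with softmax
gradient) yields weights `w_i = exp(αᵀx_centred,i)` whose first moments
match the target exactly at the optimum. Matched moments are the five
published baseline covariates (age mean and four proportions); the age SD
is not matched. The published "matched N = 179" is treated as a rounded
weighted pseudo-count: weights are rescaled to sum to 179 for presentation
only, never for variance computation, which uses the Kish effective sample
size ESS = (Σw)²/Σw².

Outcome contrasts are odds ratios. The weighted arm's log-odds variance
uses the ESS as its binomial denominator; aggregate arms use their actual
n. Any zero cell receives the Haldane–Anscombe correction (+0.5 on all four
cells). Trial-level effects are combined across the common rabeprazole
anchor by Bucher's method (log-odds subtraction, variance addition), with
Wald 95% CIs (z = 1.96) and two-sided normal p-values.

The anchor-arm rates of both trials are unpublished; the shipped
`comparison` block contains synthetic placeholder values, so the indirect
comparison supports qualitative checks only (efficacy OR near 1 with
p > 0.05; safety OR with a CI spanning 1). The published point estimates
(OR 1.05 and 0.63) are not reproducible without the component ORs. The
published efficacy CI (0.94–1.01 around an OR of 1.05) is internally
inconsistent; the package reports internally consistent intervals.

Degenerate inputs fail loudly: a matched covariate with no variation raises
a singularity error and a target moment outside the convex hull of the IPD
raises a convergence error, each naming the covariate.

## Markov model

Four states — active (A), healing (H), scar (S), recovery (R) — with
2-week cycles over 24 cycles (48 weeks), the whole cohort starting in A.
Transitions per cycle: A→H 0.9253 and H→S 0.9661 for anaprazole (from
trial IPD), 0.8957 and 0.9344 for ilaprazole (from the literature); R→A
recurrence 0.0013. A→S and A→R are structural zeros (an ulcer must pass
through the healing phase), and no death state is modelled over the short
horizon. Two quantities the sources leave unstated are pinned as
conventions:

* **S→R = 1.0 per cycle** — scar is a transient confirmation state;
* **recovery utility = 1.0** — required for the published QALY totals to be
  attainable with the published A/H/S utilities (0.7030 / 0.7790 / 0.8420).

**QALY accrual.** Each cycle contributes occupancy-weighted utility with
weight 1/24, so a cohort at utility u all horizon accrues exactly u QALYs.
Per-annum weighting over 48 weeks would cap totals at ≈0.92, below the
published 0.9803, so the 1/n-cycles convention is the one consistent with
the published table. No half-cycle correction (2-week cycles make it
negligible) and no discounting (horizon < 1 year).

**Cost pathway.** Published unit costs cover the two drugs (¥27.25 per
20 mg anaprazole tablet; ¥13.06 per 5 mg ilaprazole tablet; ¥381.50 vs
¥365.68 per 14-day cycle), an examination panel (¥467.7675) and a
gastroscopy (¥606.5550). The published per-arm totals (≈¥5,423 per
patient), however, also include registration fees, laboratory tests and
adverse-reaction expenses that were never itemized, so the pathway between
unit costs and totals is under-determined. The package's convention:

* an examination + gastroscopy panel at entry (diagnosis) and at the end of
  the initial course (week-4 endoscopic assessment), billed to the whole
  cohort;
* drug cost billed per cycle to *active-state* occupancy (treatment targets
  the active ulcer; with retreatment on — the default — this runs over the
  whole horizon, so persistent and recurrent disease is retreated, and the
  expected drug outlay is ≈1.11 cycles ≈ ¥423 per anaprazole patient);
* a follow-up/registration fee per cycle while not recovered
  (¥25.805917); and
* a fixed residual programme cost (¥2,769.724868) per patient.

The last two values are **calibrated**, once, so that the base case
reproduces the published per-arm totals and headline ICUR; they are model
inputs like any other and are varied or held fixed as documented below.
This is the package's own accounting, not a published schedule; the
base-case report prints residuals against the published table so the
calibration is auditable. Billing drug to active-state occupancy (rather
than, say, 3+ cycles of unhealed occupancy) is also what keeps every ±10%
drug-price excursion below the WTP threshold: conventions that front-load
≥2 full cycles of drug cost per patient make the +10% anaprazole-price
bound exceed 1× GDP per QALY, contradicting the robustness the base case
is known to have.

## Cost-utility analysis

ICUR = (Cost₁ − Cost₂)/(QALY₁ − QALY₂) at full internal precision. (At
4-decimal rounding of its inputs the published table implies ≈2,700
¥/QALY against a printed 2,995.41 — the published analysis evidently used
unrounded internals, as does `ducem`.) Cheaper-and-more-effective is
dominant, costlier-and-less-effective dominated, zero QALY difference
undefined (the cost difference is still reported). The decision rule is
strict: cost-effective iff dominant or ICUR < WTP.

## Sensitivity analysis

**Deterministic.** Each of the seven published parameters (four costs,
three utilities) moves one-at-a-time to the bounds of its ±10% range
(the published low/high bounds are exactly ±10% of base, and the published
SEs equal range width / (2 × 1.96)). Shared parameters move in both arms
simultaneously; drug prices are arm-specific. Results are a tornado table
sorted by |ICUR swing|; a bound where the intervention dominates is shown
without a ratio and counted as cost-effective. Because the scheduled
panels are identical across arms, examination and gastroscopy costs cancel
in the increment and show zero swing; drug prices dominate the tornado,
matching the published finding.

**Probabilistic.** 1,000 second-order Monte Carlo draws (seeded,
reproducible). Costs are Gamma, utilities Beta, both fitted by the method
of moments to the published mean and SE (fits are moment-exact); utilities
are sampled once per draw and shared across arms (they are properties of
health states, not treatments), independently across states. The four
arm-specific transition probabilities are *also* sampled by default, from
Beta distributions with binomial SEs at the arm's effective sample size
(179 matched / 129 enrolled). This choice matters: with cost and utility
uncertainty alone the incremental NMB at any plausible threshold is
positive in ≈98–100% of draws, because utilities shared across arms cancel
almost completely in the increment — acceptability near 85% at 2× GDP, as
published, arises only when trial-level uncertainty in the transition
probabilities is propagated. A config switch
(`uncertainty.sample_transitions`) disables it. The calibrated follow-up
fee and programme cost are held fixed (no published uncertainty). The CEAC
reports, on a 0–3×GDP grid (500 points), the fraction of draws with
positive incremental NMB.

## Budget impact

Annual payer expenditure = eligible patients × consultation rate ×
reimbursement rate × Σ_d share_d × course-cost_d, per scenario (with /
without the new drug listed); in the "without" scenario the new drug's
share is reallocated to incumbents proportionally to their shares. Flows
are undiscounted nominal ¥ over 3 years. None of the published inputs
(epidemiology, market shares, prices, fund budget) were disclosed, so the
shipped block is an **illustrative synthetic fixture** chosen to land at
the published order of magnitude (incremental share ≈10⁻³ percent of the
fund budget); the published ¥ totals are context, not targets.

## Numerical choices

* MAIC solver: BFGS on the log-sum-exp objective, gradient tolerance
  1e-10; post-hoc balance check at 1e-6 with a named-covariate error on
  failure. Covariates are standardized internally for conditioning;
  weights are invariant to affine recentring of covariates (tested).
* Logistic intercept calibration: bisection on [−40, 40], tolerance 1e-6.
* Transition matrices validated row-stochastic at 1e-12; traces at 1e-9.
* Continuity correction: +0.5 on all four cells only when a cell is zero.
* Seeds: a single integer drives IPD generation and the PSA
  (`numpy.random.default_rng`); identical config + seed gives
  byte-identical pipeline outputs.

## Problem sizes

The shipped analysis uses the study-scale sizes throughout: n = 220
synthetic IPD, 24-cycle traces, 1,000 PSA draws, 500-point CEAC grid — the
whole pipeline runs in a few seconds. Convergence checks in the test suite
use n up to 50,000 where the law of large numbers is the oracle.

## Known limitations

* The cost pathway beyond the published unit costs is calibrated, not
  observed; only its total and increment are anchored to published values.
* The indirect comparison's anchor inputs are synthetic; its numeric ORs
  are illustrative.
* Independent sampling of state utilities permits ordering violations in
  PSA draws (e.g. a sampled active-state utility above the healing-state
  one); no rank correlation is published that would justify more.
* The cohort model is scale-free and per-patient; it does not model the
  (internally inconsistent) published entry counts, mortality, or
  time-varying transition probabilities.
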