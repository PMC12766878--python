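# Methods

## Setting and notation

A test-set subject under periodic examination carries a *risk interval*
for the primary event (progression): `(T⁻, T⁺]` when a positive
examination followed a negative one (event code δ=1), `(T⁻, ∞)` when
follow-up ended with early treatment at `T_TRT` (δ=2, the competing event,
observed exactly) or right censoring at `T_CEN` (δ=0). Predictions enter
through two conditional curves per subject: the cause-specific cumulative
incidence `Π(s | t0) = Pr{T* ≤ s, T*_prg < T*_trt | event-free at t0}` and
the overall survival `S(s | t0)`. Evaluation is over a half-open window
`[t, t+Δt)`: a time equal to `t` belongs to the window, a time equal to
`t+Δt` does not. The risk set at `t` consists of the `n_t` subjects whose
observed follow-up reaches `t`; subjects whose follow-up ends before `t`
are excluded.

All conditioning is served through the cumulative-incidence identity
`Π(s|t0) = [Π(s|t0') − Π(t0|t0')] / S(t0|t0')` (and `S(s|t0) =
S(s|t0')/S(t0|t0')`) from a single curve origin, so tabulated predictions
need only be supplied once per subject, anchored at or before the earliest
time they will be conditioned on (in practice the earliest `T⁻` in the
risk set).

## Scenario taxonomy and weights

Relative to the window, a risk interval can start before/inside/after the
window and end inside/after it, giving five groups (1–5) crossed with the
event code (suffix a/b/c). Group 3a subjects are *absolute cases* (the
interval lies inside the window, so progression inside the window is
certain); group 4 subjects are *absolute controls* (the interval starts
after the window end). Every other at-risk subject is a partial case
and/or control.

**Model-based weights.** Each subject's case weight is the predicted
probability of progressing inside the window, conditional on the observed
data: for detected progressions, conditional on the latent time lying in
`(T⁻, T⁺]` (a ratio of CIF increments conditioned on `T⁻`); for treated or
censored subjects, the unconditional CIF increment from `T⁻`. Control
weights mirror this with survival or complementary-CIF forms. For group 2a
(interval starts inside the window, detection after it) case and control
weights are exact complements; the implementation computes the control
weight as `1 − case weight` so the complement holds to the last bit. The
boundary conventions follow the half-open window; weights are clipped into
[0, 1] with tolerance 1e-8, and values outside by more than that raise
(they indicate an invalid risk function). A predictor assigning zero
progression probability to an observed progression interval raises a
"degenerate risk interval" error rather than returning an arbitrary
weight.

**IPCW weights.** Absolute cases are weighted by `1/G(T⁺|t)` and absolute
controls by `1/G(t+Δt|t)`, where `G` is the reverse Kaplan–Meier estimate
of the censoring distribution: censoring times (δ=0) are the "events" and
observed progression/treatment times are censored observations, so a
subject observed with an event at time `u` remains in the risk set for a
censoring at `u` (the standard tie rule under role reversal; the
estimation is delegated to `lifelines`). The control weights are uniform
and cancel from the specificity ratio, which therefore equals the
unweighted proportion among absolute controls — an identity the tests
assert at every threshold. Weights are stored unnormalized (≥ 1);
normalization happens inside each metric's ratio.

## Metrics

Sensitivity and specificity at threshold `c` are weighted proportions of
predicted window-end risks `Π_i(t+Δt|t)` among case and control mass. The
ROC is traced on the grid of observed risk values augmented with ±∞
sentinels (sen/spe are step functions changing only there) and integrated
with the trapezoidal rule, which makes the AUC identical to the weighted
pairwise concordance with ties counting one half — verified against a
brute-force pair count to 1e-10.

The Brier score divides the weighted sum `Σ [(1−Π_i)² W_i + Π_i² W'_i]` by
`n_t` without renormalizing by total weight (the per-subject weights need
not sum to one); a weight-normalized variant is available behind a flag
for sensitivity analysis only. The IPCW Brier score runs over the two
known subsets; when a window contains neither absolute cases nor absolute
controls it is 0 by its empty sums and a warning is emitted.

**EPCE.** Each at-risk subject contributes `−log(δ̃₁F1 + δ̃₂F2)` where,
with `T̃₁ = max(T⁻, t)` and `T̃₂` the window-truncated follow-up end,
`F1 = ∫_{T̃₁}^{T̃₂} [Π(s|t) − Π(T̃₁|t)] ds` (composite Gauss–Legendre with
node doubling to 1e-6) and `F2 = S(t+Δt|t)`; `δ̃₁` indicates an open risk
interval intersecting the window, `δ̃₂` a censored subject whose interval
starts at or after the window end. Subjects with no likelihood term —
both indicators zero, or an interval touching the window only at its
boundary (common under biennial schedules when a negative biopsy falls
exactly on the window end) — are skipped with a warning but still count
in `n_t`. A literal doubly-logged summand is retained behind
`literal_double_log=True` purely for audit; it is not a usable estimator
(its argument is a log of a quantity below one).

*Known limitation.* For open-interval subjects the `F1` summand is
monotone increasing in the predicted risk scale, so uniformly inflating
all hazards lowers the estimator; only the `F2` term penalizes
overprediction. The proper-scoring property therefore holds against
symmetric (e.g., per-subject log-normal) distortions of the hazard — which
is how the test suite exercises it — but not against one-sided inflation.

**Reference metrics** use the latent true event times: case iff
progression falls in the window and precedes treatment, control iff
event-free past the window; subjects treated in-window before progressing
are neither, and contribute zero to AUC and Brier. The reference EPCE has
no printed estimator to inherit, and the interval-censored form degenerates
as the risk interval shrinks to a point (F1 → 0), so the package defines it
as the exact-data log score: `−log f(T*|t)` (the predictive progression
density, central difference of the CIF) for in-window cases and
`−log S(t+Δt|t)` for window survivors, with treated-in-window subjects
skipped from the numerator. It is a per-replicate anchor on a density
scale; its absolute level is not comparable to the interval-censored
estimator.

**Naive metrics** treat `T⁺` as the exact progression time (case iff
`t ≤ T⁺ < t+Δt`); treated and censored subjects are handled as
right-censored at their observed times through the same IPCW machinery,
with a censoring distribution estimated treating δ∈{0,2} as censoring
events. How treated subjects should enter a naive analysis is not
prescribed anywhere; this recoding is the package's documented choice.

In the limit of continuous examination with no dropout and no competing
event inside the window, all four approaches coincide exactly — the test
suite asserts this both on constructed degenerate-interval cohorts and on
a simulated near-continuous schedule. With a competing event present, the
naive approach's recoding of treatment as censoring perturbs its weights
by the order of the examination gap, so exact four-way agreement requires
pure interval censoring.

## Simulator

The data-generating process mimics a PSA-based surveillance cohort. The
latent biomarker is `log2(PSA+1)`; its expectation is
`m(t) = β₀ + u₀ + Σₚ (βₚ + uₚ) Bₚ(t) + β₄ (Age − 62)`, with `B` a natural
cubic spline basis (truncated-power form, three columns, normalized to
unit maximum on the follow-up range so coefficients share a scale; linear
beyond the boundary knots so lagged evaluation at `t − 1` is safe), random
effects `u ~ N(0, Ω)` with unstructured 4×4 `Ω`, and t₃ measurement error
(scale 0.18) on biomarker records taken every `visit_spacing` = 0.5 years
until exit. Cause-specific hazards for progression and treatment are
`h_k(t) = exp{ B-spline log-baseline + γ_k · PSAD + α₁ₖ m(t) + α₂ₖ [m(t) −
m(t−1)] }`, with PSA density log-normal at baseline and the log-baseline on
an 11-knot cubic B-spline basis (13 coefficients; the defaults form a
gentle upward ramp).

Latent event times are drawn per cause by inverse transform: the
cumulative hazards are accumulated by the trapezoidal rule on a dense grid
(step 0.005 y) and `Λ_k(T) = −log U` is solved by inverse linear
interpolation — the exact inverse of the piecewise-linear `Λ` being
simulated from, so finer root polishing would add nothing. Right
censoring is independent exponential dropout (rate 0.04/y) plus an
administrative cutoff at 12 years — the simplest mechanism compatible with
the IPCW assumption that examination timing carries no covariate
information. Examinations follow either the PASS schedule (years 1, 2,
then biennially) or i.i.d. uniform gaps; progression is detected at the
first examination at or after the latent time, provided neither treatment
nor censoring intervened, and `T⁻` is the last examination before the
first latent exit time. Every subject draws from an independent substream
keyed by (seed, subject index), so cohorts are reproducible under
subsetting and the replicate studies are order-invariant.

**Default calibration.** The generator's defaults are fixed configuration,
chosen once: the two baseline-hazard intercepts were calibrated so that,
under the PASS schedule, about 22% of subjects are observed with
progression and 9% with early treatment by the administrative horizon, and
the heterogeneity parameters (γ_PRG = 3.5, α₁_PRG = 0.6, PSAD log-sd 0.6,
intercept variance 0.5) were set so the correctly specified predictor
attains a reference AUC around 0.6–0.7 for the window `[1, 4)` — an
informative but far-from-perfect model, as in realistic surveillance data.

**Oracle and misspecified predictors.** The oracle risk integrates each
subject's true hazards: cumulative-Simpson accumulation of `Λ` and of the
cause-specific incidence integrands on a dense grid (vectorized hazards;
closed-form agreement ≲ 1e-8), with all conditioning via the CIF identity.
Two misspecified predictors emulate wrongly specified models at the
risk-function level rather than by refitting (model fitting is out of
scope; the metrics only consume risk curves, so the comparison structure
is preserved): `linear_trajectory` replaces `m(t)` by its least-squares
linear fit on the follow-up range, and `drop_baseline_covariate` removes
the PSAD effect and rescales each baseline hazard by the population mean
of `exp(γ_k · PSAD)` (fixed-seed Monte Carlo), preserving marginal
incidence while discarding between-subject discrimination. Externally
fitted models are evaluated through tabulated risk-curve files instead.

## What the simulator does and does not emulate

It reproduces the structure that the estimators are sensitive to: repeat
biomarker measurements driving two competing hazards, interval-censored
detection under configurable schedules, exact treatment times, and
independent right censoring. It does not emulate imperfect biopsy
sensitivity, informative (covariate-dependent) examination timing or
dropout, measurement-schedule irregularity, or posterior uncertainty from
an estimated prediction model — the "correctly specified" predictor here
is the exact data-generating risk, so reduced-scale RMSEs are smaller than
what refitted models would give, and only orderings and directions across
approaches are asserted. Passing tests therefore show the estimators
behave correctly given honest or systematically distorted risk curves, not
that any particular fitted model is well calibrated on real data.

## Study runner and scales

`run_study` simulates an independent test cohort per replicate, evaluates
the requested predictors under the model-based, IPCW, naive and reference
approaches, and aggregates RMSE against the *same-replicate* reference
(paired). Replicates where an approach is undefined (e.g., no absolute
cases under IPCW in a sparse schedule) are recorded as missing, excluded
pairwise, and counted. The desk-scale defaults used by the acceptance
script and the heavy tests are 50 replicates × 300 subjects for the PASS
misspecification direction and 30 replicates × 300 subjects per schedule
for the examination-frequency comparison; these sizes give stable
orderings (model-based Brier RMSE below IPCW; IPCW AUC RMSE increasing
from Uniform(0.3,1) through Uniform(1,2) to Uniform(0.3,4); model-based
AUC biased upward but less variable) without cluster-scale computation.
The full-scale benchmark RMSE tables shipped in `icmetrics.study` provide
the published reference points for the relative-improvement arithmetic
(`100 × (1 − mean model-based RMSE / mean baseline RMSE)` over a table's
rows).

## Numerical choices and degenerate inputs

- Risk-curve integration: dense-grid cumulative Simpson (step 0.005 y),
  linear interpolation at query time; queries beyond the tabulated horizon
  raise rather than extrapolate.
- Tabulated curves are validated at load (monotone CIF/survival, unit
  endpoints, `Π ≤ 1 − S` within 1e-6) and interpolated linearly, which
  preserves monotonicity; conditioning earlier than the table origin is an
  error.
- ROC threshold grid: observed risk values plus ±∞ sentinels; trapezoidal
  integration makes ties contribute one half, matching the pairwise form.
- EPCE F1 quadrature: Gauss–Legendre, nodes doubled from 16 until
  successive estimates differ by < 1e-6.
- Ties at window boundaries follow the half-open convention throughout;
  empty risk sets, all-zero case or control mass, zero censoring support
  at a needed time, and non-positive likelihood terms raise errors naming
  the subject where applicable.
- Reverse-KM with no censoring events returns `G ≡ 1`, so IPCW weights
  reduce to indicators.

## Known limitations

- The EPCE estimator's one-sided behaviour under uniform risk inflation
  (above).
- The IPCW approach requires the window to be able to contain whole risk
  intervals; under sparse schedules entire replicates can lack absolute
  cases and are reported as missing cells rather than imputed.
- Biopsy sensitivity is assumed perfect: the latent progression time is
  taken to lie strictly inside the reported risk interval.
- The censoring model behind the reverse Kaplan–Meier is marginal;
  covariate-dependent censoring models are out of scope.
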