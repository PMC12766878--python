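# icmetrics

Time-dependent predictive-accuracy metrics — AUC, Brier score, and expected
predictive cross-entropy (EPCE) — for risk-prediction models whose primary
event is **interval-censored** and subject to a **competing risk**.

The motivating setting is active surveillance of low-risk prostate cancer:
progression is only detected at scheduled biopsies, so its time is known
only up to the interval between the last negative and the first positive
biopsy; starting early treatment ends surveillance and competes with
detection; other subjects are right-censored. Standard time-dependent
accuracy metrics need to know who is a *case* (event inside a clinical
window of interest `[t, t+Δt)`) and who is a *control* (event-free past the
window) — under interval censoring, that status is often unknown. The
package is for biostatisticians and modellers who need to evaluate any
dynamic risk model (joint models, machine-learning pipelines, …) in this
setting; predictions enter as per-subject risk curves, so no access to the
fitted model itself is required.

## The estimators

Write `Π_i(s | t0)` for subject *i*'s predicted cumulative incidence of
progression by time `s` (before treatment), conditional on being event-free
at `t0`, and `S_i(s | t0)` for the predicted overall survival. With risk
interval `(T⁻, T⁺]` around the latent progression time, two weighting
approaches resolve the unknown case/control status:

- **Model-based** — every subject at risk at `t` contributes, with case
  weight `W_i` = predicted probability of progressing inside the window
  given what was observed (e.g. `[Π(T⁺|T⁻) − Π(t|T⁻)] / Π(T⁺|T⁻)` when the
  risk interval straddles the window start), and control weight `W'_i`
  analogously. Sensitivity at threshold `c` is
  `Σ 1{Π_i ≥ c} W_i / Σ W_i`, specificity uses `W'_i`, the AUC is
  `∫ sen d(1−spe)`, and the Brier score is
  `n_t⁻¹ Σ [(1−Π_i)² W_i + Π_i² W'_i]`.
- **IPCW** — only subjects whose status is certain enter: *absolute cases*
  (risk interval inside the window) weighted by `1/G(T⁺|t)` and *absolute
  controls* (risk interval after the window) weighted by `1/G(t+Δt|t)`,
  with `G` the reverse Kaplan–Meier estimate of the censoring
  distribution.

The EPCE, `n_t⁻¹ Σ −log p_i` with `p_i` the predicted likelihood of
subject *i*'s observed window outcome, is available for the model-based
approach. *Naive* (treating `T⁺` as the exact event time) and *reference*
(latent true times known — the simulation anchor) comparators are included,
plus a joint longitudinal–survival simulator that generates
interval-censored competing-risk cohorts under configurable biopsy
schedules for method studies.

## Worked example

`examples/evaluate_tabulated_predictions.py` builds a 120-subject
interval-censored test set, tabulates each subject's predicted risk curves
the way an external model would hand them over, and evaluates the window
`[1, 4)`:

```
[model_based]
  subjects at risk at t=1.0: 113
  absolute cases / controls: 13 / 54
  AUC(t=1, dt=3)  = 0.745
  Brier(4 | 1)    = 0.157
  EPCE(4 | 1)     = 0.780
[ipcw]
  subjects at risk at t=1.0: 113
  absolute cases / controls: 13 / 54
  AUC(t=1, dt=3)  = 0.806
  Brier(4 | 1)    = 0.106
```

All 113 at-risk subjects contribute to the model-based numbers with
probability weights; the IPCW numbers rest on the 13 + 54 subjects whose
case/control status is certain, reweighted to represent the rest. The other
examples simulate a surveillance cohort
(`examples/simulate_surveillance_cohort.py`) and run a small
misspecification study (`examples/misspecification_study.py`). A thin CLI
(`icmetrics simulate | evaluate | sim-study | report`) wraps the same
functions for shell use.

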