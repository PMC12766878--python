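"""Evaluate an external model's tabulated risk predictions on a test set.

Builds a small interval-censored test cohort and a per-subject table of
predicted cumulative-incidence / survival curves (the form in which any
external prediction model — joint model, machine-learning pipeline, ... —
hands over its output), then computes the window [1, 4) accuracy metrics
under the model-based and IPCW weighting approaches.
"""

import warnings

import numpy as np

from icmetrics import (
    RiskTable,
    Window,
    ipcw_metrics,
    model_metrics,
    risk_from_table,
)
from icmetrics.data import SubjectOutcome

rng = np.random.default_rng(0)
window = Window(t=1.0, dt=3.0)

# --- a small test cohort -----------------------------------------------------
# Each subject: last negative biopsy, then either a positive biopsy (delta=1),
# early treatment (delta=2), or right censoring (delta=0).
outcomes, tables = [], {}
for i in range(120):
    lam = rng.uniform(0.03, 0.35)          # subject's true progression rate
    t_star = rng.exponential(1.0 / lam)    # latent progression time
    exams = np.arange(1.0, 13.0, 2.0)      # biennial biopsies from year 1
    drop = rng.exponential(20.0)
    sid = f"p{i:03d}"
    pos = exams[(exams >= t_star) & (exams < drop)]
    before = exams[exams < min(t_star, drop)]
    t_neg = float(before[-1]) if len(before) else 0.0
    if len(pos):
        o = SubjectOutcome(sid, t_neg=t_neg, delta=1, t_pos=float(pos[0]))
    else:
        o = SubjectOutcome(sid, t_neg=t_neg, delta=0, t_cen=float(min(drop, 12.0)))
    if o.t2 < window.t:
        continue  # follow-up ended before the window: would be excluded anyway
    outcomes.append(o)

    # the "external model": here, the true exponential curves, tabulated
    grid = np.linspace(0.0, 16.0, 161)
    tables[sid] = RiskTable(
        sid, t0=0.0, grid=grid,
        cif=1 - np.exp(-lam * grid),
        surv=np.exp(-lam * grid),
    )

risks = {sid: risk_from_table(tab) for sid, tab in tables.items()}

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for report in (
        model_metrics(outcomes, window, risks),
        ipcw_metrics(outcomes, window, risks),
    ):
        print(f"[{report.approach}]")
        print(f"  subjects at risk at t={window.t}: {report.n_at_risk}")
        print(f"  absolute cases / controls: "
              f"{report.n_absolute_cases} / {report.n_absolute_controls}")
        print(f"  AUC(t=1, dt=3)  = {report.auc:.3f}")
        print(f"  Brier(4 | 1)    = {report.brier:.3f}")
        if report.epce is not None:
            print(f"  EPCE(4 | 1)     = {report.epce:.3f}")

print(
    "\nAUC ~ probability that a randomly chosen case outranks a control "
    "(0.5 = useless, 1 = perfect); the Brier score is the weighted squared "
    "gap between predicted window risk and case/control status (lower is "
    "better); EPCE is the mean negative log predictive likelihood of the "
    "window outcome (model-based approach only, lower is better)."
)
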