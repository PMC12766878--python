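import numpy as np
import pandas as pd
import pytest

from icmetrics.data import SubjectOutcome, Window
from icmetrics.risk import RiskFunction
from icmetrics.weights import WeightedCohort


def outcome(sid="s", t_neg=0.0, delta=0, time=None, **kw):
    """Shorthand constructor: `time` fills the delta-matching terminal."""
    slot = {1: "t_pos", 2: "t_trt", 0: "t_cen"}[delta]
    kw.setdefault(slot, time)
    return SubjectOutcome(subject_id=sid, t_neg=t_neg, delta=delta, **kw)


def constant_risk(p, t=1.0, end=4.0):
    """RiskFunction whose cif(end, anything) == p, linear in between.

    cif rises linearly from 0 at the origin to p at `end`, then stays;
    surv = 1 - cif.  Conditioning from the origin only (t0_base=0 with
    proportional shrinkage keeps cif(end, t) == p for the default t=1
    choice used throughout the tests: we simply anchor the origin at t.)
    """
    span = end - t

    def cif0(s):
        return p * min(max(s - t, 0.0), span) / span

    return RiskFunction(cif0=cif0, surv0=lambda s: 1.0 - cif0(s), t0_base=t)


def cohort_from_rows(rows, approach="model_based", window=None, n_at_risk=None):
    window = window or Window(1, 3)
    tab = pd.DataFrame(rows, columns=["subject_id", "scenario", "w_case", "w_control", "risk"])
    return WeightedCohort(
        table=tab, approach=approach, window=window,
        n_at_risk=n_at_risk if n_at_risk is not None else len(tab),
    )


def pairwise_auc(risk, w_case, w_control):
    """Brute-force weighted concordance oracle: every case-control pair,
    ties in predicted risk counting one half."""
    risk = np.asarray(risk, float)
    w_case = np.asarray(w_case, float)
    w_control = np.asarray(w_control, float)
    num = 0.0
    for i in range(len(risk)):
        if w_case[i] == 0:
            continue
        for j in range(len(risk)):
            if w_control[j] == 0:
                continue
            if risk[i] > risk[j]:
                conc = 1.0
            elif risk[i] == risk[j]:
                conc = 0.5
            else:
                conc = 0.0
            num += w_case[i] * w_control[j] * conc
    return num / (w_case.sum() * w_control.sum())


@pytest.fixture
def window():
    return Window(t=1.0, dt=3.0)


def exact_exam_cohort(n=60, seed=5, eps=1e-12, lam_scale=1.0):
    """Cohort with examinations exactly at the event times and no right
    censoring within follow-up: every risk interval is degenerate, so
    case/control status is effectively known.  Progression-only (no
    competing event inside the window), true times recorded.

    Returns (outcomes, risks): per-subject constant-hazard predictors with
    subject-specific rates so predicted risks are heterogeneous.
    """
    from icmetrics.risk import exponential_risk

    rng = np.random.default_rng(seed)
    outcomes, risks = [], {}
    tau = 50.0  # administrative horizon, far beyond the window
    i = 0
    while len(outcomes) < n:
        i += 1
        lam = lam_scale * rng.uniform(0.02, 0.4)
        t_star = rng.exponential(1.0 / lam)
        # keep clear of the window boundaries so no risk interval straddles
        if min(abs(t_star - 1.0), abs(t_star - 4.0)) < 0.05:
            continue
        sid = f"x{i:04d}"
        if t_star < 0.9:  # progression before the window: excluded by design
            continue
        if t_star < tau:
            o = SubjectOutcome(sid, t_neg=t_star - eps, delta=1, t_pos=t_star,
                               true_t_prg=t_star, true_t_trt=np.inf)
        else:
            o = SubjectOutcome(sid, t_neg=tau - eps, delta=0, t_cen=tau,
                               true_t_prg=t_star, true_t_trt=np.inf)
        outcomes.append(o)
        risks[sid] = exponential_risk(lam, 0.0)
    return outcomes, risks
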