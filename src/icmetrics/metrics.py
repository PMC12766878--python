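"""Time-dependent predictive-accuracy metrics over a window [t, t+dt).

Implements weighted sensitivity/specificity, the ROC curve and its AUC,
two Brier-score estimators (model-based weights vs. inverse probability
of censoring weighting), the expected predictive cross-entropy (EPCE,
model-based only), the no-censoring *reference* metrics computed from
latent true event times (the simulation anchor), and the *naive*
metrics that treat the detection time as the exact event time.

All estimators consume per-subject predicted risk curves through the
:class:`~icmetrics.risk.RiskFunction` contract, so any external model
whose predictions are tabulated can be evaluated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .data import DataError, SubjectOutcome, Window
from .weights import (
    CensoringSurvival,
    RiskLookup,
    WeightedCohort,
    at_risk,
    ipcw_weights,
    model_weighted_cohort,
    resolve_risk,
)

__all__ = [
    "RocCurve",
    "MetricReport",
    "weighted_sensitivity",
    "weighted_specificity",
    "roc_curve",
    "auc",
    "brier_model",
    "brier_ipcw",
    "epce_model",
    "model_metrics",
    "ipcw_metrics",
    "reference_metrics",
    "naive_metrics",
]


@dataclass
class RocCurve:
    """ROC trace over the threshold grid (thresholds decreasing)."""

    thresholds: np.ndarray
    sens: np.ndarray
    one_minus_spec: np.ndarray


@dataclass
class MetricReport:
    approach: str
    window: Window
    auc: float | None
    brier: float | None
    epce: float | None
    n_at_risk: int
    n_absolute_cases: int | None = None
    n_absolute_controls: int | None = None

    def to_dict(self) -> dict:
        return {
            "approach": self.approach,
            "t": self.window.t,
            "dt": self.window.dt,
            "auc": self.auc,
            "brier": self.brier,
            "epce": self.epce,
            "n_at_risk": self.n_at_risk,
            "n_absolute_cases": self.n_absolute_cases,
            "n_absolute_controls": self.n_absolute_controls,
        }


# ---------------------------------------------------------------------------
# Sensitivity / specificity / AUC on a weighted cohort
# ---------------------------------------------------------------------------


def _masses(cohort: WeightedCohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tab = cohort.table
    return (
        tab["risk"].to_numpy(dtype=float),
        tab["w_case"].to_numpy(dtype=float),
        tab["w_control"].to_numpy(dtype=float),
    )


def weighted_sensitivity(cohort: WeightedCohort, c: float) -> float:
    """Weighted fraction of predicted risks >= c among case mass."""
    r, wc, _ = _masses(cohort)
    total = wc.sum()
    if total <= 0:
        raise DataError("no cases in window: total case weight is zero")
    return float((wc * (r >= c)).sum() / total)


def weighted_specificity(cohort: WeightedCohort, c: float) -> float:
    """Weighted fraction of predicted risks < c among control mass.

    For IPCW cohorts the control weights are uniform, so this equals the
    unweighted proportion among absolute controls.
    """
    r, _, wk = _masses(cohort)
    total = wk.sum()
    if total <= 0:
        raise DataError("no controls in window: total control weight is zero")
    return float((wk * (r < c)).sum() / total)


def roc_curve(cohort: WeightedCohort) -> RocCurve:
    """ROC over the grid of observed predicted risks plus sentinels.

    Sensitivity and specificity are step functions that change only at
    observed risk values, so this grid traces the curve exactly; the
    sentinels pin the endpoints (0,0) and (1,1).
    """
    r, wc, wk = _masses(cohort)
    if wc.sum() <= 0:
        raise DataError("no cases in window: total case weight is zero")
    if wk.sum() <= 0:
        raise DataError("no controls in window: total control weight is zero")
    thr = np.concatenate(([np.inf], np.unique(r)[::-1], [-np.inf]))
    ge = r[None, :] >= thr[:, None]
    sens = (ge * wc).sum(axis=1) / wc.sum()
    oms = (ge * wk).sum(axis=1) / wk.sum()
    return RocCurve(thresholds=thr, sens=sens, one_minus_spec=oms)


def auc(cohort: WeightedCohort) -> float:
    """AUC(t, dt) as the trapezoidal integral of the ROC curve.

    Equals the weighted pairwise concordance over case-control pairs,
    with ties in predicted risk contributing one half.
    """
    curve = roc_curve(cohort)
    return float(np.trapezoid(curve.sens, curve.one_minus_spec))


# ---------------------------------------------------------------------------
# Brier score
# ---------------------------------------------------------------------------


def brier_model(
    outcomes: Sequence[SubjectOutcome],
    window: Window,
    risks: RiskLookup,
    normalize_weights: bool = False,
) -> float:
    """Model-based Brier score: mean over the risk set of
    w_case (1 - pi)^2 + w_control pi^2, divided by n_t (the per-subject
    weights need not sum to one).  ``normalize_weights=True`` divides by
    the total weight mass instead — a sensitivity-analysis variant only.
    """
    cohort = model_weighted_cohort(outcomes, window, risks)
    if cohort.n_at_risk == 0:
        raise DataError("empty risk set at window start")
    r, wc, wk = _masses(cohort)
    denom = (wc + wk).sum() if normalize_weights else cohort.n_at_risk
    return float((wc * (1 - r) ** 2 + wk * r**2).sum() / denom)


def brier_ipcw(
    outcomes: Sequence[SubjectOutcome],
    window: Window,
    risks: RiskLookup,
    G: CensoringSurvival | None = None,
) -> float:
    """IPCW Brier score over the absolute cases and absolute controls."""
    cohort = ipcw_weights(outcomes, window, risks, G=G)
    if cohort.n_at_risk == 0:
        raise DataError("empty risk set at window start")
    r, wc, wk = _masses(cohort)
    if wc.sum() == 0 and wk.sum() == 0:
        warnings.warn(
            "IPCW Brier score: neither absolute cases nor absolute controls "
            "in the window; the estimator is 0 by its empty sums",
            stacklevel=2,
        )
    return float((wc * (1 - r) ** 2 + wk * r**2).sum() / cohort.n_at_risk)


# ---------------------------------------------------------------------------
# EPCE
# ---------------------------------------------------------------------------


def _gauss_legendre(f, a: float, b: float, tol: float = 1e-6) -> float:
    """Gauss-Legendre quadrature with node doubling until stable."""
    if b <= a:
        return 0.0
    prev = None
    n = 16
    for _ in range(8):
        x, w = np.polynomial.legendre.leggauss(n)
        u = 0.5 * (b - a) * x + 0.5 * (b + a)
        val = 0.5 * (b - a) * float(np.sum(w * np.array([f(ui) for ui in u])))
        if prev is not None and abs(val - prev) < tol:
            return val
        prev, n = val, n * 2
    return val


def epce_model(
    outcomes: Sequence[SubjectOutcome],
    window: Window,
    risks: RiskLookup,
    literal_double_log: bool = False,
) -> float:
    """Expected predictive cross-entropy of the window outcome.

    Each at-risk subject contributes -log(d1*F1 + d2*F2) where, writing
    T1 = max(t_neg, t) and T2 = the window-truncated follow-up end,
    F1 = int_{T1}^{T2} [cif(s|t) - cif(T1|t)] ds accumulates the predicted
    progression probability over the subject's remaining risk interval
    within the window, and F2 = surv(t+dt | t) is the predicted overall
    survival for subjects known event-free past the window.  d1 indicates
    an open risk interval intersecting the window (t_neg <= t+dt), d2 a
    censored subject with t_neg >= t+dt.  The mean is over n_t; subjects
    without a likelihood term — both indicators zero, or a risk interval
    touching the window only at its boundary so the F1 range is empty —
    are skipped with a warning (they still count in n_t).

    ``literal_double_log`` retains, for audit, the doubly-logged summand
    -log(log(d1*F1 + d2*F2)).
    """
    t, end = window.t, window.end
    risk_set = [o for o in outcomes if at_risk(o, window)]
    n_t = len(risk_set)
    if n_t == 0:
        raise DataError("empty risk set at window start")
    total = 0.0
    for o in risk_set:
        risk = resolve_risk(risks, o.subject_id)
        d1 = o.t_neg <= end
        d2 = (o.t_neg >= end) and o.delta == 0
        if d1:
            if o.delta == 1:
                t2 = min(o.t_pos, end)
            elif o.delta == 2:
                t2 = min(o.t_trt, end)
            else:
                t2 = end
            t1 = max(o.t_neg, t)
            if t2 <= t1 + 1e-12:
                # empty integration range: the risk interval touches the
                # window only at its closed-end boundary
                d1 = False
        if not (d1 or d2):
            warnings.warn(
                f"subject {o.subject_id}: no likelihood contribution "
                "(risk interval starts after the window and subject is not "
                "censored); skipped from the EPCE numerator",
                stacklevel=2,
            )
            continue
        p = 0.0
        if d1:
            base = risk.cif(t1, t)
            p += _gauss_legendre(lambda s: risk.cif(s, t) - base, t1, t2)
        if d2:
            p += risk.surv(end, t)
        if literal_double_log:
            p = math.log(p) if p > 0 else -1.0
        if p <= 0:
            raise DataError(
                f"subject {o.subject_id}: non-positive EPCE likelihood term ({p})"
            )
        total += -math.log(p)
    return total / n_t


# ---------------------------------------------------------------------------
# Approach-level reports
# ---------------------------------------------------------------------------


def model_metrics(
    outcomes: Sequence[SubjectOutcome],
    window: Window,
    risks: RiskLookup,
    with_epce: bool = True,
) -> MetricReport:
    cohort = model_weighted_cohort(outcomes, window, risks)
    return MetricReport(
        approach="model_based",
        window=window,
        auc=auc(cohort),
        brier=brier_model(outcomes, window, risks),
        epce=epce_model(outcomes, window, risks) if with_epce else None,
        n_at_risk=cohort.n_at_risk,
        n_absolute_cases=cohort.n_absolute_cases,
        n_absolute_controls=cohort.n_absolute_controls,
    )


def ipcw_metrics(
    outcomes: Sequence[SubjectOutcome],
    window: Window,
    risks: RiskLookup,
    G: CensoringSurvival | None = None,
) -> MetricReport:
    cohort = ipcw_weights(outcomes, window, risks, G=G)
    return MetricReport(
        approach="ipcw",
        window=window,
        auc=auc(cohort),
        brier=brier_ipcw(outcomes, window, risks, G=G),
        epce=None,
        n_at_risk=cohort.n_at_risk,
        n_absolute_cases=cohort.n_absolute_cases,
        n_absolute_controls=cohort.n_absolute_controls,
    )


def _true_times(o: SubjectOutcome) -> tuple[float, float]:
    if o.true_t_prg is None or o.true_t_trt is None:
        raise DataError(
            f"subject {o.subject_id}: reference metrics need true event times"
        )
    return o.true_t_prg, o.true_t_trt


def _reference_cohort(
    outcomes: Sequence[SubjectOutcome], window: Window, risks: RiskLookup
) -> WeightedCohort:
    t, end = window.t, window.end
    rows = []
    n_at_risk = 0
    for o in outcomes:
        tp, tt = _true_times(o)
        if min(tp, tt) < t:
            continue
        n_at_risk += 1
        is_case = (t <= tp < end) and (tp < tt)
        is_control = min(tp, tt) >= end
        rows.append(
            {
                "subject_id": o.subject_id,
                "scenario": "case" if is_case else ("control" if is_control else "neither"),
                "w_case": 1.0 if is_case else 0.0,
                "w_control": 1.0 if is_control else 0.0,
                "risk": resolve_risk(risks, o.subject_id).cif(end, t),
            }
        )
    return WeightedCohort(
        table=pd.DataFrame(rows, columns=["subject_id", "scenario", "w_case", "w_control", "risk"]),
        approach="reference",
        window=window,
        n_at_risk=n_at_risk,
    )


def _reference_epce(
    outcomes: Sequence[SubjectOutcome], window: Window, risks: RiskLookup
) -> float:
    """No-censoring EPCE anchor: -log predictive density at the true
    progression time for in-window cases, -log predicted survival for
    window survivors; subjects treated in-window (progression never
    observable) are skipped from the numerator."""
    t, end = window.t, window.end
    risk_set = [o for o in outcomes if min(_true_times(o)) >= t]
    if not risk_set:
        raise DataError("empty reference risk set at window start")
    total = 0.0
    h = 1e-5
    for o in risk_set:
        tp, tt = _true_times(o)
        risk = resolve_risk(risks, o.subject_id)
        if (t <= tp < end) and (tp < tt):
            lo, hi = max(tp - h, t), tp + h
            p = (risk.cif(hi, t) - risk.cif(lo, t)) / (hi - lo)
        elif min(tp, tt) >= end:
            p = risk.surv(end, t)
        else:
            continue
        if p <= 0:
            raise DataError(
                f"subject {o.subject_id}: non-positive reference likelihood term"
            )
        total += -math.log(p)
    return total / len(risk_set)


def reference_metrics(
    outcomes: Sequence[SubjectOutcome],
    window: Window,
    risks: RiskLookup,
    with_epce: bool = True,
) -> MetricReport:
    """Metrics in the ideal no-censoring scenario: case/control status is
    read off the latent true event times (case: progression in-window and
    before treatment; control: event-free past the window), with the same
    predicted risks as the other approaches."""
    cohort = _reference_cohort(outcomes, window, risks)
    if cohort.n_at_risk == 0:
        raise DataError("empty reference risk set at window start")
    r, wc, wk = _masses(cohort)
    brier = float((wc * (1 - r) ** 2 + wk * r**2).sum() / cohort.n_at_risk)
    return MetricReport(
        approach="reference",
        window=window,
        auc=auc(cohort),
        brier=brier,
        epce=_reference_epce(outcomes, window, risks) if with_epce else None,
        n_at_risk=cohort.n_at_risk,
        n_absolute_cases=int(wc.sum()),
        n_absolute_controls=int(wk.sum()),
    )


def _naive_censoring_survival(outcomes: Sequence[SubjectOutcome]) -> CensoringSurvival:
    # in the naive view treatment is recoded as right censoring
    durations = np.array([o.t2 for o in outcomes], dtype=float)
    censored = np.array([o.delta != 1 for o in outcomes], dtype=bool)
    if not censored.any():
        return CensoringSurvival(times=np.array([np.inf]), probs=np.array([1.0]))
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=censored)
    sf = kmf.survival_function_
    return CensoringSurvival(
        times=sf.index.to_numpy(dtype=float), probs=sf.iloc[:, 0].to_numpy(dtype=float)
    )


def naive_metrics(
    outcomes: Sequence[SubjectOutcome], window: Window, risks: RiskLookup
) -> MetricReport:
    """Naive metrics ignoring interval censoring: the detection time t_pos
    is treated as the exact progression time (case iff t <= t_pos < t+dt);
    treated and censored subjects are handled as right-censored at their
    observed times through the IPCW machinery."""
    t, end = window.t, window.end
    G = _naive_censoring_survival(outcomes)
    rows = []
    n_at_risk = 0
    for o in outcomes:
        if o.t2 < t:
            continue
        n_at_risk += 1
        w_case = w_control = 0.0
        label = "neither"
        if o.delta == 1 and t <= o.t2 < end:
            w_case = 1.0 / G.conditional(o.t2, t)
            label = "case"
        elif o.t2 >= end:
            w_control = 1.0 / G.conditional(end, t)
            label = "control"
        rows.append(
            {
                "subject_id": o.subject_id,
                "scenario": label,
                "w_case": w_case,
                "w_control": w_control,
                "risk": resolve_risk(risks, o.subject_id).cif(end, t),
            }
        )
    cohort = WeightedCohort(
        table=pd.DataFrame(rows, columns=["subject_id", "scenario", "w_case", "w_control", "risk"]),
        approach="naive",
        window=window,
        n_at_risk=n_at_risk,
    )
    if cohort.n_at_risk == 0:
        raise DataError("empty risk set at window start")
    r, wc, wk = _masses(cohort)
    brier = float((wc * (1 - r) ** 2 + wk * r**2).sum() / cohort.n_at_risk)
    return MetricReport(
        approach="naive",
        window=window,
        auc=auc(cohort),
        brier=brier,
        epce=None,
        n_at_risk=cohort.n_at_risk,
        n_absolute_cases=int((wc > 0).sum()),
        n_absolute_controls=int((wk > 0).sum()),
    )
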