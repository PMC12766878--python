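"""Scenario classification and case/control weights.

Each at-risk subject's *risk interval* — the interval known to contain
the latent progression time — is positioned relative to the evaluation
window [t, t+dt).  That position determines the subject's scenario code
(groups 1–5, suffix a/b/c for progression-detected / treated / censored)
and, under the model-based approach, the probability weights with which
the subject enters the sensitivity (case weight) and specificity
(control weight) estimators.  Under the IPCW approach only subjects with
*known* status enter — absolute cases (risk interval fully inside the
window, group 3a) and absolute controls (risk interval entirely after
the window, group 4) — reweighted by the inverse of the censoring-free
probability from a reverse Kaplan–Meier estimate.

Boundary convention: the window is half-open, so a time equal to ``t``
belongs to the window and a time equal to ``t+dt`` does not.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .data import DataError, SubjectOutcome, Window
from .risk import RiskFunction

__all__ = [
    "ScenarioCode",
    "classify_scenario",
    "model_case_weight",
    "model_control_weight",
    "CensoringSurvival",
    "reverse_km",
    "WeightedCohort",
    "model_weighted_cohort",
    "ipcw_weights",
    "at_risk",
]

_CLIP_TOL = 1e-8


class ScenarioCode(str, enum.Enum):
    S1A = "1a"; S1B = "1b"; S1C = "1c"
    S2A = "2a"; S2B = "2b"; S2C = "2c"
    S3A = "3a"; S3B = "3b"; S3C = "3c"
    S4A = "4a"; S4B = "4b"; S4C = "4c"
    S5A = "5a"; S5B = "5b"; S5C = "5c"
    EXCLUDED = "EXCLUDED"


_SUFFIX = {1: "a", 2: "b", 0: "c"}


def at_risk(outcome: SubjectOutcome, window: Window) -> bool:
    """A subject is in the risk set at t when follow-up reaches t."""
    return outcome.t2 >= window.t


def classify_scenario(outcome: SubjectOutcome, window: Window) -> ScenarioCode:
    """Deterministic, total map from (outcome, window) to a scenario code.

    Groups: 1 = risk interval straddles the window start; 2 = starts
    inside the window, ends after it; 3 = fully inside the window;
    4 = entirely after the window; 5 = starts before the window, ends
    after it.  Suffix a/b/c by event code.  Subjects whose follow-up
    ends before t are EXCLUDED.
    """
    t, end = window.t, window.end
    if not at_risk(outcome, window):
        return ScenarioCode.EXCLUDED
    suffix = _SUFFIX[outcome.delta]
    terminal = outcome.t2
    if outcome.t_neg >= end:
        group = "4"
    elif outcome.t_neg >= t:
        group = "3" if terminal < end else "2"
    else:
        group = "1" if terminal < end else "5"
    return ScenarioCode(group + suffix)


def _clip01(w: float, what: str, sid: str) -> float:
    if w < -_CLIP_TOL or w > 1 + _CLIP_TOL:
        raise DataError(f"subject {sid}: {what} weight {w} outside [0,1]")
    return min(max(w, 0.0), 1.0)


def _case_denominator(outcome: SubjectOutcome, risk: RiskFunction) -> float:
    denom = risk.cif(outcome.t_pos, outcome.t_neg)
    if denom <= 0:
        raise DataError(
            f"subject {outcome.subject_id}: degenerate risk interval — "
            "predictor assigns zero progression risk to an observed progression"
        )
    return denom


def model_case_weight(
    outcome: SubjectOutcome, window: Window, risk: RiskFunction
) -> float:
    """Model-based probability of being a case for the window.

    The weight is the predicted probability that the latent progression
    time falls in [t, t+dt), conditional on what was observed: for
    detected progressions (suffix a) additionally conditional on the
    progression lying in (t_neg, t_pos].  All curves are conditioned on
    the last negative examination time.
    """
    code = classify_scenario(outcome, window)
    if code is ScenarioCode.EXCLUDED:
        raise DataError(f"subject {outcome.subject_id} is excluded (follow-up ends before t)")
    t, end, tn = window.t, window.end, outcome.t_neg
    cif = lambda s: risk.cif(s, tn)
    g = code.value
    if g in ("4a", "4b", "4c"):
        return 0.0
    if g == "3a":
        return 1.0
    if g == "1a":
        return _clip01((cif(outcome.t_pos) - cif(t)) / _case_denominator(outcome, risk),
                       "case", outcome.subject_id)
    if g == "2a":
        return _clip01(cif(end) / _case_denominator(outcome, risk),
                       "case", outcome.subject_id)
    if g == "5a":
        return _clip01((cif(end) - cif(t)) / _case_denominator(outcome, risk),
                       "case", outcome.subject_id)
    if g == "1b":
        return _clip01(cif(outcome.t_trt) - cif(t), "case", outcome.subject_id)
    if g == "3b":
        return _clip01(cif(outcome.t_trt), "case", outcome.subject_id)
    if g == "1c":
        return _clip01(cif(end) - cif(t), "case", outcome.subject_id)
    if g in ("2b", "2c", "3c"):
        return _clip01(cif(end), "case", outcome.subject_id)
    if g in ("5b", "5c"):
        return _clip01(cif(end) - cif(t), "case", outcome.subject_id)
    raise AssertionError(f"unhandled scenario {g}")  # pragma: no cover


def model_control_weight(
    outcome: SubjectOutcome, window: Window, risk: RiskFunction
) -> float:
    """Model-based probability of being a control (event-free through the
    window); complements :func:`model_case_weight` exactly for group 2a."""
    code = classify_scenario(outcome, window)
    if code is ScenarioCode.EXCLUDED:
        raise DataError(f"subject {outcome.subject_id} is excluded (follow-up ends before t)")
    t, end, tn = window.t, window.end, outcome.t_neg
    cif = lambda s: risk.cif(s, tn)
    g = code.value
    if g in ("4a", "4b", "4c"):
        return 1.0
    if g in ("1a", "1b", "3a", "3b"):
        return 0.0
    if g == "2a":
        # printed ratio [cif(t_pos)-cif(end)]/cif(t_pos); computed as the
        # exact complement so case + control == 1 in floating point
        return 1.0 - model_case_weight(outcome, window, risk)
    if g == "5a":
        return _clip01(
            (risk.cif(outcome.t_pos, tn) - cif(end)) / _case_denominator(outcome, risk),
            "control", outcome.subject_id)
    if g in ("2b", "2c", "5b", "5c"):
        return _clip01(1.0 - cif(end), "control", outcome.subject_id)
    if g in ("1c", "3c"):
        return _clip01(risk.surv(end, tn), "control", outcome.subject_id)
    raise AssertionError(f"unhandled scenario {g}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Censoring distribution (reverse Kaplan-Meier)
# ---------------------------------------------------------------------------


@dataclass
class CensoringSurvival:
    """Right-continuous step estimate G(s) of being censoring-free at s."""

    times: np.ndarray
    probs: np.ndarray

    def g(self, s: float) -> float:
        if s < 0:
            raise DataError("censoring survival queried at negative time")
        idx = np.searchsorted(self.times, s, side="right") - 1
        return 1.0 if idx < 0 else float(self.probs[idx])

    def conditional(self, s: float, t: float) -> float:
        """G(s | t) = G(s) / G(t); requires G(t) > 0."""
        gt = self.g(t)
        if gt <= 0:
            raise DataError(f"no censoring support: G({t}) = 0")
        return self.g(s) / gt


def reverse_km(outcomes: Sequence[SubjectOutcome]) -> CensoringSurvival:
    """Kaplan–Meier estimate of the censoring distribution.

    Roles are reversed: right-censoring (delta=0) is the "event" and
    observed progression/treatment times are censored observations, so a
    subject observed with an event at time u still counts as at risk of
    censoring at u (standard KM tie rule under the reversal).
    """
    if len(outcomes) == 0:
        raise DataError("reverse_km needs at least one subject")
    durations = np.array([o.t2 for o in outcomes], dtype=float)
    censored = np.array([o.delta == 0 for o in outcomes], dtype=bool)
    if not censored.any():
        return CensoringSurvival(times=np.array([np.inf]), probs=np.array([1.0]))
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=censored)
    sf = kmf.survival_function_
    return CensoringSurvival(
        times=sf.index.to_numpy(dtype=float),
        probs=sf.iloc[:, 0].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Weighted cohorts
# ---------------------------------------------------------------------------

RiskLookup = RiskFunction | Mapping[str, RiskFunction] | Callable[[str], RiskFunction]


def resolve_risk(risks: RiskLookup, subject_id: str) -> RiskFunction:
    if isinstance(risks, RiskFunction):
        return risks
    if isinstance(risks, Mapping):
        try:
            return risks[subject_id]
        except KeyError:
            raise DataError(f"no risk function for subject {subject_id}") from None
    return risks(subject_id)


@dataclass
class WeightedCohort:
    """Per-subject scenario codes, case/control weights, and predicted
    window-end risks for one window under one weighting approach.

    Model-based weights lie in [0,1]; IPCW weights are stored
    unnormalized (>= 1) and cancel inside each metric's ratio.
    """

    table: pd.DataFrame
    approach: str
    window: Window
    n_at_risk: int

    @property
    def n_absolute_cases(self) -> int:
        return int((self.table["scenario"] == "3a").sum())

    @property
    def n_absolute_controls(self) -> int:
        return int(self.table["scenario"].isin(["4a", "4b", "4c"]).sum())

    def to_csv(self, path) -> None:
        """Weight audit export for visual inspection."""
        out = self.table.copy()
        out["approach"] = self.approach
        out.to_csv(path, index=False)


def _window_end_risks(
    outcomes: Sequence[SubjectOutcome], window: Window, risks: RiskLookup
) -> list[float]:
    return [
        resolve_risk(risks, o.subject_id).cif(window.end, window.t) for o in outcomes
    ]


def model_weighted_cohort(
    outcomes: Sequence[SubjectOutcome], window: Window, risks: RiskLookup
) -> WeightedCohort:
    """Model-based weights for every subject in the risk set at t."""
    rows = []
    n_at_risk = 0
    for o in outcomes:
        code = classify_scenario(o, window)
        if code is ScenarioCode.EXCLUDED:
            continue
        n_at_risk += 1
        risk = resolve_risk(risks, o.subject_id)
        rows.append(
            {
                "subject_id": o.subject_id,
                "scenario": code.value,
                "w_case": model_case_weight(o, window, risk),
                "w_control": model_control_weight(o, window, risk),
                "risk": risk.cif(window.end, window.t),
            }
        )
    return WeightedCohort(
        table=pd.DataFrame(rows, columns=["subject_id", "scenario", "w_case", "w_control", "risk"]),
        approach="model_based",
        window=window,
        n_at_risk=n_at_risk,
    )


def ipcw_weights(
    outcomes: Sequence[SubjectOutcome],
    window: Window,
    risks: RiskLookup,
    G: CensoringSurvival | None = None,
) -> WeightedCohort:
    """IPCW weights: absolute cases get 1/G(t_pos | t), absolute controls
    1/G(t+dt | t), everyone else zero.  G defaults to the reverse-KM
    estimate on the full outcome collection."""
    if G is None:
        G = reverse_km(outcomes)
    t, end = window.t, window.end
    rows = []
    n_at_risk = 0
    for o in outcomes:
        code = classify_scenario(o, window)
        if code is ScenarioCode.EXCLUDED:
            continue
        n_at_risk += 1
        risk = resolve_risk(risks, o.subject_id)
        w_case = w_control = 0.0
        if code is ScenarioCode.S3A:
            w_case = 1.0 / G.conditional(o.t_pos, t)
        elif code.value in ("4a", "4b", "4c"):
            w_control = 1.0 / G.conditional(end, t)
        rows.append(
            {
                "subject_id": o.subject_id,
                "scenario": code.value,
                "w_case": w_case,
                "w_control": w_control,
                "risk": risk.cif(end, t),
            }
        )
    return WeightedCohort(
        table=pd.DataFrame(rows, columns=["subject_id", "scenario", "w_case", "w_control", "risk"]),
        approach="ipcw",
        window=window,
        n_at_risk=n_at_risk,
    )
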