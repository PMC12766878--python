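import math
import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from icmetrics.data import DataError, SubjectOutcome, Window
from icmetrics.metrics import (
    auc,
    brier_ipcw,
    brier_model,
    epce_model,
    ipcw_metrics,
    model_metrics,
    naive_metrics,
    reference_metrics,
    roc_curve,
    weighted_sensitivity,
    weighted_specificity,
)
from icmetrics.risk import exponential_risk
from icmetrics.weights import CensoringSurvival, ipcw_weights

from conftest import (
    cohort_from_rows,
    constant_risk,
    exact_exam_cohort,
    outcome,
    pairwise_auc,
)

W = Window(1.0, 3.0)


class TestSensitivitySpecificity:
    def test_weighted_sensitivity_hand_ratio(self):
        coh = cohort_from_rows(
            [("a", "3a", 1.0, 0.0, 0.8), ("b", "1a", 0.5, 0.0, 0.2)]
        )
        assert weighted_sensitivity(coh, 0.5) == pytest.approx(2 / 3, abs=1e-15)
        assert weighted_sensitivity(coh, 0.0) == 1.0
        assert weighted_sensitivity(coh, 0.9) == 0.0

    def test_weighted_specificity_hand_ratio(self):
        coh = cohort_from_rows(
            [("a", "4a", 0.0, 1.0, 0.1), ("b", "4b", 0.0, 1.0, 0.9)]
        )
        assert weighted_specificity(coh, 0.5) == 0.5
        assert weighted_specificity(coh, 1.0 + 1e-9) == 1.0

    def test_empty_case_or_control_mass_is_an_error(self):
        coh = cohort_from_rows([("a", "4a", 0.0, 1.0, 0.1)])
        with pytest.raises(DataError, match="no cases"):
            weighted_sensitivity(coh, 0.5)
        coh2 = cohort_from_rows([("a", "3a", 1.0, 0.0, 0.1)])
        with pytest.raises(DataError, match="no controls"):
            weighted_specificity(coh2, 0.5)

    def test_ipcw_specificity_equals_unweighted_proportion(self):
        """The uniform control weights cancel out of the IPCW specificity."""
        rng = np.random.default_rng(3)
        outs, risks = [], {}
        for i in range(60):
            delta = int(rng.integers(0, 3))
            tn = float(rng.uniform(0, 8))
            outs.append(outcome(f"s{i}", t_neg=tn, delta=delta,
                                time=tn + float(rng.uniform(0.1, 5))))
            risks[f"s{i}"] = exponential_risk(float(rng.uniform(0.05, 0.5)), 0.1)
        cohort = ipcw_weights(outs, W, risks)
        tab = cohort.table
        controls = tab[tab["w_control"] > 0]
        if len(controls) == 0:
            pytest.skip("draw produced no absolute controls")
        for c in np.linspace(0, 1, 21):
            weighted = weighted_specificity(cohort, c)
            unweighted = float((controls["risk"] < c).mean())
            assert weighted == pytest.approx(unweighted, abs=1e-12)


class TestAuc:
    def test_perfect_separation(self):
        coh = cohort_from_rows(
            [("a", "3a", 1, 0, 0.9), ("b", "3a", 1, 0, 0.9),
             ("c", "4a", 0, 1, 0.1), ("d", "4a", 0, 1, 0.1)]
        )
        assert auc(coh) == 1.0

    def test_all_tied_risks_give_half(self):
        coh = cohort_from_rows(
            [("a", "3a", 1, 0, 0.4), ("b", "4a", 0, 1, 0.4)]
        )
        assert auc(coh) == pytest.approx(0.5, abs=1e-15)

    def test_threshold_integral_equals_pairwise_concordance(self):
        """Trapezoidal ROC integral == brute-force weighted pair count on
        random cohorts of up to 50 subjects, for both weighting styles."""
        rng = np.random.default_rng(11)
        for trial in range(20):
            n = int(rng.integers(5, 51))
            risk = np.round(rng.uniform(0, 1, n), 2)  # rounding forces ties
            w_case = np.where(rng.uniform(size=n) < 0.5, rng.uniform(0, 1, n), 0.0)
            w_control = np.where(rng.uniform(size=n) < 0.5, rng.uniform(0, 2.5, n), 0.0)
            if w_case.sum() == 0 or w_control.sum() == 0:
                continue
            coh = cohort_from_rows(
                [(f"s{i}", "3a", w_case[i], w_control[i], risk[i]) for i in range(n)]
            )
            assert auc(coh) == pytest.approx(
                pairwise_auc(risk, w_case, w_control), abs=1e-10
            )

    def test_roc_endpoints(self):
        coh = cohort_from_rows(
            [("a", "3a", 1, 0, 0.7), ("b", "4a", 0, 1, 0.3)]
        )
        curve = roc_curve(coh)
        assert (curve.sens[0], curve.one_minus_spec[0]) == (0.0, 0.0)
        assert (curve.sens[-1], curve.one_minus_spec[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.sens) >= 0)
        assert np.all(np.diff(curve.one_minus_spec) >= 0)

    def test_added_noise_never_improves_reference_auc_on_average(self):
        """Perturbing predicted risks with symmetric noise degrades (or at
        best preserves) discrimination, averaged over noise draws."""
        rng = np.random.default_rng(42)
        n = 80
        status = rng.uniform(size=n) < 0.3
        risk = np.clip(0.2 + 0.3 * status + rng.normal(0, 0.1, n), 0, 1)
        rows = [(f"s{i}", "3a" if status[i] else "4a",
                 float(status[i]), float(~status[i]), risk[i]) for i in range(n)]
        clean = auc(cohort_from_rows(rows))
        noisy = []
        for _ in range(200):
            pert = np.clip(risk + rng.normal(0, 0.15, n), 0, 1)
            rows_p = [(f"s{i}", rows[i][1], rows[i][2], rows[i][3], pert[i])
                      for i in range(n)]
            noisy.append(auc(cohort_from_rows(rows_p)))
        assert np.mean(noisy) <= clean + 1e-3


class TestBrier:
    def test_model_based_hand_arithmetic(self):
        outs = [
            outcome("a", t_neg=1.5, delta=1, time=3.5),  # 3a, weight 1
            outcome("b", t_neg=4.5, delta=1, time=5.0),  # 4a, control weight 1
        ]
        risks = {"a": constant_risk(0.8), "b": constant_risk(0.1)}
        assert brier_model(outs, W, risks) == pytest.approx(0.025, abs=1e-12)

    def test_perfect_predictions_score_zero(self):
        outs = [
            outcome("a", t_neg=1.5, delta=1, time=3.5),
            outcome("b", t_neg=4.5, delta=0, time=6.0),
        ]
        risks = {"a": constant_risk(1.0), "b": constant_risk(0.0)}
        assert brier_model(outs, W, risks) == pytest.approx(0.0, abs=1e-12)

    def test_zero_weight_subject_contributes_nothing(self):
        outs = [outcome("a", t_neg=1.5, delta=1, time=3.5)]
        base = brier_model(outs, W, {"a": constant_risk(0.8)})
        # group 2a straddler with case+control not both zero would change it;
        # a subject treated in-window after its own t_neg contributes ~cif mass
        outs2 = outs + [outcome("b", t_neg=4.5, delta=1, time=5.0)]
        risks2 = {"a": constant_risk(0.8), "b": constant_risk(0.0)}
        got = brier_model(outs2, W, risks2)
        assert got == pytest.approx(base / 2, abs=1e-12)  # only n_t changed

    def test_ipcw_single_absolute_case_hand_arithmetic(self):
        G = CensoringSurvival(times=np.array([0.0, 2.0]), probs=np.array([1.0, 0.5]))
        outs = [outcome("a", t_neg=1.2, delta=1, time=3.0)]
        got = brier_ipcw(outs, W, {"a": constant_risk(0.6)}, G=G)
        assert got == pytest.approx(0.32, abs=1e-12)

    def test_ipcw_without_censoring_matches_model_on_degenerate_cohort(self):
        outs, risks = exact_exam_cohort(n=40, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert brier_ipcw(outs, W, risks) == pytest.approx(
                brier_model(outs, W, risks), abs=1e-10
            )

    def test_empty_known_subsets_score_zero_with_warning(self):
        outs = [outcome(f"s{i}", t_neg=2.0, delta=1, time=6.0) for i in range(4)]
        risks = {o.subject_id: exponential_risk(0.2, 0.0) for o in outs}
        with pytest.warns(UserWarning, match="neither absolute cases nor"):
            assert brier_ipcw(outs, W, risks) == 0.0


class TestEpce:
    def test_window_survivor_closed_form(self):
        """Event-free past the window under all-cause rate 0.1:
        the contribution is -log S(4|1) = 0.3."""
        outs = [outcome("a", t_neg=4.5, delta=0, time=5.0)]
        risk = exponential_risk(0.1, 0.0)
        assert epce_model(outs, W, {"a": risk}) == pytest.approx(0.3, abs=1e-9)

    def test_open_interval_quadrature_matches_independent_integral(self):
        lam = 0.25
        outs = [outcome("a", t_neg=2.0, delta=0, time=6.0)]  # 5c-style
        risk = exponential_risk(lam, 0.0)
        got = epce_model(outs, W, {"a": risk})
        # independent oracle: integrate the closed-form CIF difference
        f1, _ = quad(lambda s: (1 - math.exp(-lam * (s - 1))) - (1 - math.exp(-lam)),
                     2.0, 4.0, epsabs=1e-12)
        assert got == pytest.approx(-math.log(f1), abs=1e-6)

    def test_mean_invariance_under_duplication(self):
        outs = [outcome("a", t_neg=4.5, delta=0, time=5.0)]
        risk = exponential_risk(0.1, 0.0)
        single = epce_model(outs, W, {"a": risk})
        double = epce_model(
            outs + [outcome("b", t_neg=4.5, delta=0, time=5.0)],
            W, {"a": risk, "b": risk},
        )
        assert double == pytest.approx(single, abs=1e-14)

    def test_uninformative_subject_skipped_with_warning(self):
        outs = [
            outcome("a", t_neg=4.5, delta=0, time=5.0),
            outcome("b", t_neg=4.5, delta=1, time=5.0),  # both indicators vacuous
        ]
        risk = exponential_risk(0.1, 0.0)
        with pytest.warns(UserWarning, match="no likelihood contribution"):
            got = epce_model(outs, W, {"a": risk, "b": risk})
        assert got == pytest.approx(0.3 / 2, abs=1e-9)  # skipped but in n_t

    def test_literal_double_log_audit_switch(self):
        outs = [outcome("a", t_neg=4.5, delta=0, time=5.0)]
        risk = exponential_risk(0.1, 0.0)  # F2 < 1 so log(F2) < 0
        with pytest.raises(DataError, match="non-positive"):
            epce_model(outs, W, {"a": risk}, literal_double_log=True)

    def test_true_model_beats_perturbed_model_on_average(self):
        """Proper-scoring behaviour: the data-generating risk has lower
        EPCE than a symmetrically perturbed risk (per-subject log-normal
        distortion of the progression hazard), averaged over replicates."""
        from icmetrics.simulate import (
            BiopsySchedule,
            SimulationParams,
            oracle_risk,
            simulate_cohort,
            subject_hazards,
        )
        from icmetrics.risk import HazardSpec, risk_from_hazards

        params = SimulationParams()
        gaps = []
        for seed in (1, 2, 3, 4, 5, 6):
            cohort = simulate_cohort(params, 120, BiopsySchedule(), seed=seed)
            rng = np.random.default_rng(seed + 100)
            true_risks, warped = {}, {}
            for s in cohort.states:
                true_risks[s.subject_id] = oracle_risk(params, s)
                hz = subject_hazards(params, s)
                c = float(np.exp(rng.normal(0.0, 1.5)))
                warped_spec = HazardSpec(
                    h_prg=lambda t, h=hz.h_prg, c=c: c * h(t),
                    h_trt=hz.h_trt,
                )
                warped[s.subject_id] = risk_from_hazards(
                    warped_spec, horizon=params.admin_censor + 4
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gaps.append(
                    epce_model(cohort.outcomes, W, warped)
                    - epce_model(cohort.outcomes, W, true_risks)
                )
        assert np.mean(gaps) > 0


class TestReferenceAndNaive:
    def test_perfect_separation_reference(self):
        outs = [
            outcome("a", t_neg=2.4, delta=1, time=2.5,
                    true_t_prg=2.5, true_t_trt=np.inf),
            outcome("b", t_neg=7.9, delta=0, time=8.0,
                    true_t_prg=np.inf, true_t_trt=np.inf),
        ]
        risks = {"a": constant_risk(0.99), "b": constant_risk(0.01)}
        rep = reference_metrics(outs, W, risks, with_epce=False)
        assert rep.auc == 1.0
        assert rep.brier == pytest.approx((0.01**2 + 0.01**2) / 2, abs=1e-12)

    def test_treated_before_progression_in_window_is_neither(self):
        outs = [
            outcome("a", t_neg=1.9, delta=2, time=2.0,
                    true_t_prg=3.0, true_t_trt=2.0),  # treatment preempts
            outcome("b", t_neg=2.4, delta=1, time=2.5,
                    true_t_prg=2.5, true_t_trt=np.inf),
            outcome("c", t_neg=7.9, delta=0, time=8.0,
                    true_t_prg=np.inf, true_t_trt=np.inf),
        ]
        risks = {k: constant_risk(v) for k, v in
                 [("a", 0.5), ("b", 0.9), ("c", 0.1)]}
        rep = reference_metrics(outs, W, risks, with_epce=False)
        assert rep.n_at_risk == 3
        assert rep.n_absolute_cases == 1  # subject a is neither case nor control
        assert rep.n_absolute_controls == 1

    def test_missing_true_times_rejected(self):
        outs = [outcome("a", t_neg=1.5, delta=1, time=3.5)]
        with pytest.raises(DataError, match="true event times"):
            reference_metrics(outs, W, {"a": constant_risk(0.5)})

    def test_all_approaches_coincide_without_censoring(self):
        """With examinations exactly at the event times and no censoring
        before the horizon, model-based, IPCW, naive and reference AUC and
        Brier scores are identical."""
        outs, risks = exact_exam_cohort(n=60, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reps = [
                model_metrics(outs, W, risks, with_epce=False),
                ipcw_metrics(outs, W, risks),
                naive_metrics(outs, W, risks),
                reference_metrics(outs, W, risks, with_epce=False),
            ]
        aucs = [r.auc for r in reps]
        briers = [r.brier for r in reps]
        assert max(aucs) - min(aucs) < 1e-10
        assert max(briers) - min(briers) < 1e-10

    def test_naive_counts_partial_case_as_full_case(self):
        """A progression detected inside the window but truly occurring
        before it: the naive approach scores a full case, the model-based
        approach only the probability mass inside the window."""
        o = outcome("a", t_neg=0.5, delta=1, time=2.0)  # scenario 1a
        ctrl = outcome("b", t_neg=4.5, delta=0, time=6.0)
        risks = {"a": exponential_risk(0.3, 0.0), "b": exponential_risk(0.05, 0.0)}
        naive_rep = naive_metrics([o, ctrl], W, risks)
        assert naive_rep.n_absolute_cases == 1
        from icmetrics.weights import model_case_weight

        partial = model_case_weight(o, W, risks["a"])
        assert 0 < partial < 1

    def test_naive_empty_case_set_is_an_error(self):
        outs = [outcome("a", t_neg=4.5, delta=0, time=6.0)]
        with pytest.raises(DataError):
            naive_metrics(outs, W, {"a": constant_risk(0.1)})
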