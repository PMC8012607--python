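"""Dose-response AUC, drug filters, log-ratio designs, penalised models."""

import numpy as np
import pandas as pd
import pytest

import cytopheno as cp
from cytopheno import synthetic
from cytopheno.containers import DoseResponsePlate, SurvivalTable
from cytopheno.response import (
    compute_auc,
    compute_response,
    filter_drugs,
    fit_cox_composition,
    fit_lasso_auc,
    logratio_transform,
    quartile_km,
)

DOSES = np.array([0.1, 0.4, 1.6, 6.4])


def plate_from_responses(responses):
    """Plate whose intensities encode the given per-dose percent responses."""
    pos, neg = 100.0, 0.0
    resp = np.atleast_2d(np.asarray(responses, dtype=float)).T
    # response = 100 - 100*(I - neg)/(pos - neg)  =>  I = pos - (pos-neg)*resp/100
    inten = pos - (pos - neg) * resp / 100.0
    return DoseResponsePlate("d", "m", DOSES[: resp.shape[0]], inten, pos, neg)


class TestResponseFormula:
    def test_positive_control_endpoint_zero(self):
        p = DoseResponsePlate("d", "m", DOSES, np.full((4, 1), 100.0), 100.0, 0.0)
        np.testing.assert_allclose(compute_response(p), 0.0)

    def test_negative_control_endpoint_hundred(self):
        p = DoseResponsePlate("d", "m", DOSES, np.full((4, 1), 0.0), 100.0, 0.0)
        np.testing.assert_allclose(compute_response(p), 100.0)

    def test_midpoint_fifty(self):
        p = DoseResponsePlate("d", "m", DOSES, np.full((4, 1), 50.0), 100.0, 0.0)
        np.testing.assert_allclose(compute_response(p), 50.0)

    def test_equal_controls_rejected(self):
        with pytest.raises(ValueError):
            DoseResponsePlate("d", "m", DOSES, np.zeros((4, 1)), 10.0, 10.0)


class TestAUC:
    def test_flat_zero_response(self):
        assert compute_auc(plate_from_responses([0, 0, 0, 0])) == pytest.approx(0.0)

    def test_flat_full_response(self):
        assert compute_auc(plate_from_responses([100, 100, 100, 100])) == pytest.approx(1.0)

    def test_two_dose_step_half(self):
        p = plate_from_responses([0, 100])
        assert compute_auc(p) == pytest.approx(0.5)

    def test_single_dose_rejected(self):
        p = DoseResponsePlate("d", "m", [1.0], [[50.0]], 100.0, 0.0)
        with pytest.raises(ValueError):
            compute_auc(p)

    def test_monotone_in_responses(self, rng):
        # pointwise-larger response curves never yield smaller AUC
        for _ in range(100):
            lo = rng.uniform(0, 80, 4)
            hi = lo + rng.uniform(0, 20, 4)
            assert compute_auc(plate_from_responses(hi)) >= compute_auc(plate_from_responses(lo)) - 1e-12

    def test_isotonic_fit_matches_pav_oracle(self):
        # pool-adjacent-violators on a 4-point toy, checked by hand:
        # responses [60, 20, 40, 80] -> PAV gives [40, 40, 40, 80]
        p = plate_from_responses([60, 20, 40, 80])
        log_dose = np.log10(p.doses)
        expected_fit = np.array([40.0, 40.0, 40.0, 80.0])
        area = np.trapezoid(expected_fit, log_dose) / (100.0 * (log_dose[-1] - log_dose[0]))
        assert compute_auc(p) == pytest.approx(area, abs=1e-12)


class TestDrugFilters:
    def _auc_table(self):
        models = [f"M{i}" for i in range(12)]
        return pd.DataFrame(
            {
                "ok_drug": np.linspace(0.05, 0.8, 12),
                "few_models": [0.1, 0.5] + [np.nan] * 10,
                "no_resistant": np.linspace(0.3, 0.9, 12),
                "no_responder": np.linspace(0.01, 0.15, 12),
            },
            index=models,
        ).T

    def test_rules_and_reasons(self):
        out = filter_drugs(self._auc_table(), min_models=10).set_index("drug")
        assert out.loc["ok_drug", "included"]
        assert "min models" in out.loc["few_models", "reason"]
        assert "no resistant" in out.loc["no_resistant", "reason"]
        assert "no responding" in out.loc["no_responder", "reason"]

    def test_flagged_curve_fraction_rule(self):
        auc = self._auc_table()
        flags = pd.DataFrame(False, index=auc.index, columns=auc.columns)
        flags.loc["ok_drug", flags.columns[:5]] = True  # 5/12 > 33%
        out = filter_drugs(auc, curve_cluster_flags=flags, min_models=10).set_index("drug")
        assert not out.loc["ok_drug", "included"]
        assert "33%" in out.loc["ok_drug", "reason"]


class TestLogRatio:
    def setup_method(self):
        self.comps = pd.DataFrame(
            [[0.5, 0.3, 0.2], [0.2, 0.2, 0.6]], index=["M1", "M2"], columns=list("ABC")
        )

    def test_equal_to_referent_gives_zero(self):
        comps = pd.DataFrame([[0.5, 0.5]], index=["M1"], columns=["A", "B"])
        design = logratio_transform(comps, "B", pseudocount=0.0)
        assert design.matrix.iloc[0, 0] == 0.0

    def test_referent_column_absent_from_design(self):
        design = logratio_transform(self.comps, "C")
        assert list(design.matrix.columns) == ["log(A/C)", "log(B/C)"]

    def test_subset_renormalisation_invariance(self):
        d1 = logratio_transform(self.comps, "C", pseudocount=0.0)
        rescaled = self.comps.div(self.comps.sum(axis=1) * 2.0, axis=0)  # halved scale
        d2 = logratio_transform(rescaled, "C", pseudocount=0.0)
        pd.testing.assert_frame_equal(d1.matrix, d2.matrix)

    def test_zero_prevalence_finite(self):
        comps = pd.DataFrame([[0.0, 1.0]], index=["M1"], columns=["A", "B"])
        design = logratio_transform(comps, "B")
        assert np.isfinite(design.matrix.to_numpy()).all()

    def test_missing_referent_rejected(self):
        with pytest.raises(ValueError, match="referent"):
            logratio_transform(self.comps, "Z")


class TestLassoAUC:
    def _design(self, n=20, p=10, seed=5):
        comps = synthetic.dirichlet_compositions(
            [f"M{i}" for i in range(n)], [f"C{j}" for j in range(p + 1)], 1.0, seed=seed
        )
        return comps, logratio_transform(comps, f"C{p}")

    def test_null_data_mostly_empty_support(self):
        comps, design = self._design()
        rng = np.random.default_rng(0)
        empties, r2s = 0, []
        for s in range(5):
            auc = pd.Series(0.3 + rng.normal(0, 0.03, len(comps)), index=comps.index)
            res = fit_lasso_auc(design, auc, n_folds=10, seed=s)
            empties += len(res.support) == 0
            r2s.append(res.r2)
        assert empties >= 3
        assert np.median(r2s) < 0.1

    def test_huge_penalty_intercept_only(self):
        comps, design = self._design()
        auc, _ = synthetic.simulate_auc_from_composition(
            comps, np.linspace(-0.2, 0.2, design.matrix.shape[1]), design.referent, seed=1
        )
        res = fit_lasso_auc(design, auc, alpha=1e6)
        assert (res.coefficients == 0.0).all()
        np.testing.assert_allclose(res.fitted, np.mean(auc), atol=1e-9)

    def test_zero_penalty_equals_ols(self):
        comps, design = self._design()
        auc, _ = synthetic.simulate_auc_from_composition(
            comps, np.linspace(-0.2, 0.2, design.matrix.shape[1]), design.referent, noise_sd=0.02, seed=2
        )
        res = fit_lasso_auc(design, auc, alpha=0.0)
        X = np.column_stack([np.ones(len(comps)), design.matrix.to_numpy()])
        ols = np.linalg.lstsq(X, np.asarray(auc), rcond=None)[0]
        np.testing.assert_allclose(res.coefficients.to_numpy(), ols[1:], atol=1e-6)

    def test_signal_recovery(self):
        comps, design = self._design(seed=8)
        beta = np.zeros(design.matrix.shape[1])
        beta[[1, 4]] = [0.25, -0.2]
        auc, _ = synthetic.simulate_auc_from_composition(
            comps, beta, design.referent, noise_sd=0.03, seed=8
        )
        res = fit_lasso_auc(design, auc, n_folds=10, seed=8)
        assert set(design.matrix.columns[[1, 4]]) <= set(res.support)
        assert res.r2 > 0.5

    def test_fold_reduction_warns(self):
        comps, design = self._design(n=6, p=3)
        auc = pd.Series(np.linspace(0.2, 0.8, 6), index=comps.index)
        res = fit_lasso_auc(design, auc, n_folds=10, seed=0)
        assert res.cv_folds < 10 and res.warnings


class TestCoxComposition:
    def _cohort(self, gamma, n=300, seed=4, censor=0.2):
        comps = synthetic.dirichlet_compositions(
            [f"P{i}" for i in range(n)], list("ABCD"), 1.0, seed=seed
        )
        surv, truth = synthetic.simulate_survival(comps, gamma, "D", censor_rate=censor, seed=seed)
        return comps, logratio_transform(comps, "D"), surv

    def test_zero_events_rejected(self):
        comps, design, surv = self._cohort([0.0, 0.0, 0.0], n=30)
        surv.data["event"] = 0
        with pytest.raises(ValueError, match="events"):
            fit_cox_composition(design, surv)

    def test_null_near_empty_support(self):
        comps, design, surv = self._cohort([0.0, 0.0, 0.0], n=200, seed=9)
        res = fit_cox_composition(design, surv, n_folds=5, seed=0)
        assert (res.coefficients != 0).sum() <= 1

    def test_strong_effect_sign_recovered(self):
        comps, design, surv = self._cohort([1.5, 0.0, 0.0], n=300, seed=4)
        res = fit_cox_composition(design, surv, n_folds=5, seed=0)
        assert res.coefficients.iloc[0] > 0.0

    def test_ties_documented_breslow(self):
        comps, design, surv = self._cohort([1.0, 0.0, 0.0], n=100, seed=1)
        res = fit_cox_composition(design, surv, n_folds=3, seed=0)
        assert res.ties == "breslow"


class TestQuartileKM:
    def test_degenerate_quartiles_rejected(self):
        comps, design, surv = (None, None, None)
        scores = pd.Series([1.0, 1.0, 1.0], index=["a", "b", "c"])
        table = SurvivalTable(
            pd.DataFrame({"case_id": ["a", "b", "c"], "time": [1.0, 2.0, 3.0], "event": [1, 1, 0]})
        )
        with pytest.raises(ValueError, match="quartiles"):
            quartile_km(scores, table)

    def test_km_without_censoring_is_empirical_survival(self):
        rng = np.random.default_rng(2)
        n = 40
        times = rng.exponential(10, n) + 0.1
        ids = [f"c{i}" for i in range(n)]
        table = SurvivalTable(pd.DataFrame({"case_id": ids, "time": times, "event": 1}))
        scores = pd.Series(np.arange(n, dtype=float), index=ids)
        curves, stat, p = quartile_km(scores, table)
        q1_ids = np.array(ids)[np.arange(n) <= np.quantile(np.arange(n), 0.25)]
        t_q1 = times[: len(q1_ids)]
        kmf = curves["Q1"]
        for t in np.quantile(t_q1, [0.3, 0.6, 0.9]):
            emp = (t_q1 > t).mean()
            assert float(kmf.survival_function_at_times(t).iloc[0]) == pytest.approx(emp, abs=1e-9)

    def test_strong_effect_monotone_and_significant(self):
        comps = synthetic.dirichlet_compositions(
            [f"P{i}" for i in range(400)], list("ABCD"), 1.0, seed=6
        )
        surv, _ = synthetic.simulate_survival(comps, [2.0, 0.0, 0.0], "D", censor_rate=0.1, seed=6)
        design = logratio_transform(comps, "D")
        scores = pd.Series(design.matrix.iloc[:, 0].to_numpy() * 2.0, index=comps.index)
        curves, stat, p = quartile_km(scores, surv)
        medians = [curves[f"Q{g}"].median_survival_time_ for g in (1, 2, 3, 4)]
        assert all(np.diff(medians) < 0)  # higher risk -> shorter survival
        assert p < 0.001
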