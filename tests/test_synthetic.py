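"""Generator correctness: determinism, separation, variance hierarchy,
composition handling, spatial point processes, plates, survival."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, kendalltau

import cytopheno as cp
from cytopheno import synthetic
from cytopheno.synthetic import (
    make_templates,
    simulate_cell_table,
    simulate_spatial_catalog,
    simulate_dose_response_plate,
    simulate_auc_from_composition,
    simulate_survival,
    simulate_alterations,
    dirichlet_compositions,
)


class TestTemplates:
    def test_seed_determinism(self):
        a = make_templates(3, separation=4, seed=1)
        b = make_templates(3, separation=4, seed=1)
        for ta, tb in zip(a, b):
            pd.testing.assert_series_equal(ta.marker_means, tb.marker_means)
            pd.testing.assert_series_equal(ta.marker_sds, tb.marker_sds)

    def test_htc_separation_guarantee(self):
        tpl = make_templates(3, separation=4, seed=1, include_stroma=False)
        htc = [m for m, s in tpl[0].subpanel_map.items() if s == "HTC"]
        sd = tpl[0].marker_sds[htc[0]]
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.linalg.norm(tpl[i].marker_means[htc] - tpl[j].marker_means[htc])
                assert d >= 4 * sd - 1e-9

    def test_within_phenotype_sd_hierarchy(self):
        tpl = make_templates(4, seed=0)[0]
        by_sp = {
            sp: np.mean([tpl.marker_sds[m] for m, s in tpl.subpanel_map.items() if s == sp])
            for sp in ("HTC", "OSA", "CCA")
        }
        assert by_sp["CCA"] > by_sp["OSA"] > by_sp["HTC"]

    @pytest.mark.parametrize("bad", [0, 1])
    def test_too_few_phenotypes_rejected(self, bad):
        with pytest.raises(ValueError):
            make_templates(bad)

    def test_nonpositive_marker_counts_rejected(self):
        with pytest.raises(ValueError):
            make_templates(3, n_markers_per_subpanel={"HTC": 0, "MSC": 2, "OSA": 2, "CCA": 2})

    def test_default_preset_cv_ordering(self):
        # 1000 cells/phenotype across models: per-model mean CV must come
        # out CCA > OSA > HTC, the subpanel variance hierarchy
        templates, comps = synthetic.well_separated_preset(5, 4, seed=3)
        table, _ = simulate_cell_table(templates, comps, cells_per_model=1000, seed=3)
        cv, _ = cp.subpanel_cv(table)
        means = cv.mean()
        assert means["CCA"] > means["OSA"] > means["HTC"]


class TestCellTable:
    def test_full_scale_row_count(self):
        templates, _ = synthetic.well_separated_preset(49, 4, seed=0)
        comps = dirichlet_compositions(
            [f"M{i}" for i in range(49)], [t.phenotype_id for t in templates], 1.0, seed=0
        )
        table, _ = simulate_cell_table(templates, comps, cells_per_model=1600, seed=0)
        assert table.n_cells == 78400

    def test_degenerate_composition_single_label(self):
        tpl = make_templates(3, seed=1, include_stroma=False)
        comps = pd.DataFrame([[1.0, 0.0, 0.0]], index=["M1"], columns=[t.phenotype_id for t in tpl])
        _, truth = simulate_cell_table(tpl, comps, cells_per_model=200, seed=1)
        assert set(truth.labels) == {"C1"}

    def test_multinomial_concentration(self):
        tpl = make_templates(3, seed=1, include_stroma=False)
        comps = pd.DataFrame(
            [[0.5, 0.3, 0.2]], index=["M1"], columns=[t.phenotype_id for t in tpl]
        )
        _, truth = simulate_cell_table(tpl, comps, cells_per_model=100_000, seed=1)
        frac = pd.Series(truth.labels).value_counts(normalize=True)
        for p, expected in zip(("C1", "C2", "C3"), (0.5, 0.3, 0.2)):
            assert abs(frac[p] - expected) < 0.01

    def test_negative_composition_rejected(self):
        tpl = make_templates(2, seed=1, include_stroma=False)
        comps = pd.DataFrame([[1.2, -0.2]], index=["M1"], columns=["C1", "C2"])
        with pytest.raises(ValueError):
            simulate_cell_table(tpl, comps, cells_per_model=10, seed=1)

    def test_bit_identical_under_seed(self):
        tpl = make_templates(3, seed=5)
        comps = dirichlet_compositions(["A", "B"], [t.phenotype_id for t in tpl], 1.0, seed=5)
        t1, _ = simulate_cell_table(tpl, comps, cells_per_model=50, seed=9)
        t2, _ = simulate_cell_table(tpl, comps, cells_per_model=50, seed=9)
        np.testing.assert_array_equal(t1.X, t2.X)

    def test_intensities_nonnegative(self, preset_small):
        _, _, table, _ = preset_small
        assert (table.X >= 0).all()

    def test_bayes_error_below_one_percent(self, preset_small):
        # Monte-Carlo Bayes-optimal classification on the HTC markers
        # against the known Gaussians of the well-separated preset
        templates, _, _, _ = preset_small
        htc = [m for m, s in templates[0].subpanel_map.items() if s == "HTC"]
        rng = np.random.default_rng(123)
        errs = 0
        n = 4000
        means = np.array([t.marker_means[htc].to_numpy() for t in templates])
        sds = np.array([t.marker_sds[htc].to_numpy() for t in templates])
        per = n // len(templates)
        for ti in range(len(templates)):
            x = rng.normal(means[ti], sds[ti], size=(per, len(htc)))
            ll = np.stack(
                [
                    -0.5 * (((x - means[k]) / sds[k]) ** 2).sum(1) - np.log(sds[k]).sum()
                    for k in range(len(templates))
                ]
            )
            errs += int((ll.argmax(axis=0) != ti).sum())
        assert errs / (per * len(templates)) < 0.01


class TestCompositions:
    def test_rows_sum_to_one(self):
        comps = dirichlet_compositions([f"M{i}" for i in range(30)], list("abcd"), 0.7, seed=4)
        np.testing.assert_allclose(comps.sum(axis=1), 1.0, atol=1e-9)


class TestSpatialCatalog:
    def test_seed_determinism(self):
        tpl = make_templates(2, seed=0, spatial_mode="clustered")
        comp = pd.Series({"C1": 0.6, "S1": 0.4})
        c1, _ = simulate_spatial_catalog(tpl, comp, 300, seed=7)
        c2, _ = simulate_spatial_catalog(tpl, comp, 300, seed=7)
        pd.testing.assert_frame_equal(c1.cells, c2.cells)

    def test_points_inside_field(self):
        tpl = make_templates(2, seed=0, spatial_mode="clustered", cluster_scale=40.0)
        comp = pd.Series({"C1": 0.5, "S1": 0.5})
        cat, _ = simulate_spatial_catalog(tpl, comp, 500, field=(0, 0, 200, 100), seed=1)
        assert cat.cells["x_um"].between(0, 200).all()
        assert cat.cells["y_um"].between(0, 100).all()

    def test_empty_catalogue_not_error(self):
        tpl = make_templates(2, seed=0)
        cat, _ = simulate_spatial_catalog(tpl, pd.Series({"C1": 1.0, "S1": 0.0}), 0, seed=1)
        assert len(cat.cells) == 0

    def test_zero_area_field_rejected(self):
        tpl = make_templates(2, seed=0)
        with pytest.raises(ValueError):
            simulate_spatial_catalog(tpl, pd.Series({"C1": 1.0, "S1": 0.0}), 10, field=(0, 0, 0, 100))

    def test_clustered_phenotype_has_excess_close_pairs(self):
        # naive pair counting: a Thomas process at scale 20um must show
        # more close pairs than the CSR expectation
        tpl = make_templates(2, seed=3, include_stroma=False, spatial_mode="clustered")
        tpl[1].spatial_mode = "random"
        comp = pd.Series({"C1": 0.5, "C2": 0.5})
        cat, _ = simulate_spatial_catalog(tpl, comp, 1200, field=(0, 0, 600, 600), seed=3)
        for label, expect_excess in (("C1", True), ("C2", False)):
            pts = cat.image_points("img1", label=label)
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            n = len(pts)
            close = (d[np.triu_indices(n, 1)] < 20).sum()
            # CSR expectation: C(n,2) * pi r^2 / area
            expected = n * (n - 1) / 2 * np.pi * 400 / 360000
            if expect_excess:
                assert close > 3 * expected
            else:
                assert close < 3 * expected

    def test_csr_subregion_counts_uniform(self):
        # chi-square goodness of fit over a 3x3 grid, 100 seeded runs
        tpl = make_templates(2, seed=0, include_stroma=False)
        comp = pd.Series({"C1": 1.0, "C2": 0.0})
        fails = 0
        for s in range(100):
            cat, _ = simulate_spatial_catalog(tpl, comp, 450, field=(0, 0, 300, 300), seed=s)
            gx = np.minimum((cat.cells["x_um"] // 100).astype(int), 2)
            gy = np.minimum((cat.cells["y_um"] // 100).astype(int), 2)
            counts = np.bincount(gx * 3 + gy, minlength=9)
            _, p = chisquare(counts)
            fails += p < 0.01
        assert fails <= 5


class TestDoseResponsePlates:
    DOSES = [0.1, 0.4, 1.6, 6.4, 25.6]

    def test_nonresponder_flat_at_positive_control(self):
        plate = simulate_dose_response_plate(0.0, self.DOSES, noise_sd=0.0, seed=1)
        np.testing.assert_allclose(plate.intensities, plate.pos_control)
        assert cp.compute_auc(plate) == pytest.approx(0.0, abs=1e-9)

    def test_saturating_responder_auc_near_one(self):
        plate = simulate_dose_response_plate(1.0, self.DOSES, noise_sd=0.0, ec50=0.001, seed=1)
        assert cp.compute_auc(plate) > 0.9

    def test_seeded_plates_identical(self):
        p1 = simulate_dose_response_plate(0.5, self.DOSES, noise_sd=50.0, seed=3)
        p2 = simulate_dose_response_plate(0.5, self.DOSES, noise_sd=50.0, seed=3)
        np.testing.assert_array_equal(p1.intensities, p2.intensities)

    def test_equal_controls_rejected(self):
        with pytest.raises(ValueError):
            simulate_dose_response_plate(0.5, self.DOSES, controls=(100.0, 100.0))


class TestAUCForwardModel:
    def setup_method(self):
        self.comps = dirichlet_compositions([f"M{i}" for i in range(8)], list("ABCD"), 1.0, seed=6)

    def test_zero_beta_gives_intercept(self):
        auc, _ = simulate_auc_from_composition(
            self.comps, np.zeros(3), "D", noise_sd=0.0, intercept=0.4, seed=0
        )
        np.testing.assert_allclose(auc, 0.4)

    def test_difference_equals_beta_times_delta_logratio(self):
        comps = pd.DataFrame(
            [[0.5, 0.3, 0.2], [0.25, 0.55, 0.2]], index=["M1", "M2"], columns=list("ABC")
        )
        beta = np.array([0.1, 0.0])
        auc, _ = simulate_auc_from_composition(
            comps, beta, "C", noise_sd=0.0, intercept=0.4, pseudocount=0.0, seed=0
        )
        delta = 0.1 * (np.log(0.5 / 0.2) - np.log(0.25 / 0.2))
        assert auc["M1"] - auc["M2"] == pytest.approx(delta, abs=1e-12)

    def test_beta_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            simulate_auc_from_composition(self.comps, np.zeros(5), "D")

    def test_seeded_noise_reproducible(self):
        a1, _ = simulate_auc_from_composition(self.comps, np.zeros(3), "D", noise_sd=0.1, seed=2)
        a2, _ = simulate_auc_from_composition(self.comps, np.zeros(3), "D", noise_sd=0.1, seed=2)
        pd.testing.assert_series_equal(a1, a2)


class TestSurvivalGenerator:
    def setup_method(self):
        self.comps = dirichlet_compositions(
            [f"P{i}" for i in range(300)], list("ABCD"), 1.0, seed=3
        )

    def test_no_censoring_all_events(self):
        surv, _ = simulate_survival(self.comps, np.zeros(3), "D", censor_rate=0.0, seed=1)
        assert (surv.data["event"] == 1).all()

    def test_strong_effect_shortens_times(self):
        surv, _ = simulate_survival(self.comps, [2.0, 0.0, 0.0], "D", censor_rate=0.0, seed=1)
        lr = cp.logratio_transform(self.comps, "D").matrix.iloc[:, 0]
        tau, p = kendalltau(lr, surv.data["time"])
        assert tau < -0.3 and p < 1e-6

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError):
            simulate_survival(self.comps, np.zeros(3), "D", baseline=(-1.0, 10.0))


class TestAlterations:
    def test_seeded_reproducibility(self):
        comps = dirichlet_compositions(["M1", "M2", "M3"], list("AB"), 1.0, seed=1)
        t1, _ = simulate_alterations(comps, {"A": 2.0}, n_genes=5, seed=4)
        t2, _ = simulate_alterations(comps, {"A": 2.0}, n_genes=5, seed=4)
        pd.testing.assert_frame_equal(t1, t2)

    def test_linked_gene_rate_shifted(self):
        comps = dirichlet_compositions([f"M{i}" for i in range(400)], list("AB"), 1.0, seed=2)
        table, links = simulate_alterations(comps, {"A": 3.0}, n_genes=4, background_rate=0.2, seed=2)
        dominant_a = comps.idxmax(axis=1) == "A"
        rate_linked = table.loc[dominant_a, "alt_A"].mean()
        rate_other = table.loc[~dominant_a, "alt_A"].mean()
        assert rate_linked > 0.6 and rate_other < 0.35


class TestWriters:
    def test_fcs_round_trip(self, tmp_path, preset_small):
        _, _, table, _ = preset_small
        small = table.subset_cells(np.arange(100))
        path = tmp_path / "cells.fcs"
        synthetic.write_cell_table_fcs(small, path, cofactor=5.0)
        back = cp.read_cell_table(
            path, format="fcs", metadata_map={"model_id": "m", "sample_id": "s", "batch_id": "b"}
        )
        recovered = np.arcsinh(back.X / 5.0)
        np.testing.assert_allclose(recovered, small.X, atol=1e-4)
        assert back.markers == small.markers

    def test_ground_truth_sidecar(self, tmp_path, preset_small):
        _, comps, _, truth = preset_small
        path = tmp_path / "truth.json"
        synthetic.write_ground_truth(truth, path)
        import json

        payload = json.loads(path.read_text())
        assert payload["seed"] == truth.seed
        assert len(payload["labels"]) == len(truth.labels)
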