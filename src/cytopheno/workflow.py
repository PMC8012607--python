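"""End-to-end pipeline orchestration with manifests and provenance.

A single configuration (dict or YAML file) drives: synthetic-data
generation (or file input) -> preprocessing -> clustering (+ stability)
-> prevalence / diversity -> cross-platform label transfer -> spatial
autocorrelation -> association statistics -> compositional response and
survival models.  Every artefact is written as delimited/structured text
and recorded in a manifest with the stage, its effective parameters and
the SHA-256 of each output, so a re-run with the same configuration is
bit-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    classify,
    clustering,
    preprocess,
    response,
    spatial as spatial_mod,
    synthetic,
)
from .association import alteration_enrichment, drug_cc_correlation

DEMO_CONFIG = {
    "preset": "demo",
    "seed": 0,
    "n_models": 12,
    "n_phenotypes": 4,
    "cells_per_model": 300,
    "separation": 8.0,
    "cofactor": 5.0,
    "min_cells": 50,
    "n_per_model": 250,
    "k": None,
    "stability_reps": 6,
    "subsample_frac": 0.9,
    "delta_threshold": 0.9,
    "min_prevalence": 0.05,
    "spatial_cells": 1500,
    "spatial_bins": [0.0, 200.0, 10.0],
    "n_random_realisations": 5,
    "referent": None,
    "pseudocount": None,
    "n_folds": 5,
    "survival_cases": 200,
}


def load_config(path_or_dict) -> dict:
    cfg = dict(DEMO_CONFIG)
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    unknown = set(user) - set(cfg)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg.update(user)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    if cfg["cofactor"] is not None and cfg["cofactor"] <= 0:
        raise ValueError("cofactor must be positive")
    if cfg["n_models"] < 2 or cfg["cells_per_model"] < 1:
        raise ValueError("need >= 2 models and >= 1 cell per model")
    if not 0 < cfg["subsample_frac"] <= 1:
        raise ValueError("subsample_frac must be in (0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config, out_dir) -> dict:
    """Execute every stage from one configuration; returns the manifest."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {"config": cfg, "stages": []}

    def emit(stage: str, name: str, df: pd.DataFrame, params: dict):
        path = out / name
        df.to_csv(path, sep="\t")
        manifest["stages"].append(
            {"stage": stage, "output": name, "sha256": _sha256(path), "params": params}
        )

    try:
        # --- simulate ------------------------------------------------
        templates, comps = synthetic.well_separated_preset(
            cfg["n_models"], cfg["n_phenotypes"], seed=seed, separation=cfg["separation"]
        )
        table, truth = synthetic.simulate_cell_table(
            templates, comps, cells_per_model=cfg["cells_per_model"], seed=seed
        )
        emit("simulate", "compositions_true.tsv", comps, {"seed": seed})

        # --- preprocess ----------------------------------------------
        table_f, report = preprocess.filter_outlier_cells(table)
        table_f, report = preprocess.discard_low_event_samples(
            table_f, min_cells=cfg["min_cells"], report=report
        )
        table_n = preprocess.cosine_normalize(table_f)
        if cfg["n_per_model"]:
            table_n = preprocess.downsample_equal(table_n, cfg["n_per_model"], seed=seed)
        emit(
            "preprocess",
            "preprocess_report.tsv",
            pd.DataFrame(report.steps),
            {"min_cells": cfg["min_cells"], "n_per_model": cfg["n_per_model"]},
        )

        # --- cluster -------------------------------------------------
        k = cfg["k"] or clustering.default_k(table_n.n_cells)
        res = clustering.cluster_graph(table_n, k=k, seed=seed)
        labels_df = table_n.obs.copy()
        labels_df["cluster"] = res.labels
        emit("cluster", "cluster_labels.tsv", labels_df, {"k": k, "seed": seed})
        emit("cluster", "cluster_centroids.tsv", res.centroids, {"k": k})
        if cfg["stability_reps"] >= 2:
            rep = clustering.stability_scan(
                table_n,
                [k],
                n_reps=cfg["stability_reps"],
                subsample_frac=cfg["subsample_frac"],
                seed=seed,
            )
            emit(
                "stability",
                "stability_report.tsv",
                rep.per_k,
                {"n_reps": cfg["stability_reps"], "frac": cfg["subsample_frac"]},
            )

        # --- prevalence & diversity ---------------------------------
        prev = clustering.compute_prevalence(res, table_n.obs["model_id"].to_numpy())
        emit("prevalence", "prevalence.tsv", prev, {})
        simpson = prev.apply(clustering.simpson_score, axis=1).rename("simpson")
        emit("diversity", "simpson_scores.tsv", simpson.to_frame(), {})
        cv_table, cv_tests = clustering.subpanel_cv(table_n)
        emit("diversity", "subpanel_cv.tsv", cv_table, {})

        # --- cross-platform transfer ---------------------------------
        clf = classify.train_centroid_classifier(
            table,
            truth.labels,
            shared_markers=table.markers[:10],
            min_prevalence=cfg["min_prevalence"],
            delta_threshold=cfg["delta_threshold"],
            seed=seed,
        )
        target, target_truth = synthetic.simulate_cell_table(
            templates, comps, cells_per_model=200, noise_sd=0.1, seed=seed + 1
        )
        classified = classify.classify_cells(clf, target)
        corr = classify.centroid_correlation(clf, classified, target)
        emit(
            "classify",
            "centroid_correlations.tsv",
            corr,
            {"delta": cfg["delta_threshold"], "min_prev": cfg["min_prevalence"]},
        )
        acc = float(
            np.mean(
                classified.labels[classified.labels != "unclassified"]
                == target_truth.labels[classified.labels != "unclassified"]
            )
        )
        frac_unc = float(np.mean(classified.labels == "unclassified"))
        emit(
            "classify",
            "transfer_summary.tsv",
            pd.DataFrame([{"accuracy_classified": acc, "unclassified_frac": frac_unc}]),
            {},
        )

        # --- spatial --------------------------------------------------
        templates_sp = [
            synthetic.PhenotypeTemplate(
                phenotype_id=t.phenotype_id,
                marker_means=t.marker_means,
                marker_sds=t.marker_sds,
                subpanel_map=t.subpanel_map,
                spatial_mode="clustered" if i == 0 else "random",
                cluster_scale=20.0,
            )
            for i, t in enumerate(templates)
        ]
        comp_row = comps.iloc[0]
        catalog, _ = synthetic.simulate_spatial_catalog(
            templates_sp, comp_row, n_cells=cfg["spatial_cells"], seed=seed
        )
        b0, b1, step = cfg["spatial_bins"]
        bins = np.arange(b0, b1 + step, step)
        summary = spatial_mod.spatial_summary(
            catalog, bin_edges=bins, n_random_realisations=cfg["n_random_realisations"], seed=seed
        )
        emit("spatial", "spatial_summary.tsv", summary, {"bins": list(map(float, bins[:3]))})

        # --- associations ---------------------------------------------
        alts, links = synthetic.simulate_alterations(
            comps, link={comps.columns[0]: 3.0}, n_genes=6, seed=seed
        )
        enr = alteration_enrichment(truth.labels, table.obs["model_id"].to_numpy(), alts)
        emit("associate", "alteration_enrichment.tsv", enr, {})

        # --- response models ------------------------------------------
        human = [c for c in comps.columns if not c.startswith("S")]
        comps_h = comps[human].div(comps[human].sum(axis=1), axis=0)
        referent = cfg["referent"] or human[-1]
        design = response.logratio_transform(comps_h, referent, pseudocount=cfg["pseudocount"])
        beta = np.zeros(design.matrix.shape[1])
        beta[0] = 0.25
        auc, auc_truth = synthetic.simulate_auc_from_composition(
            comps_h, beta, referent, noise_sd=0.03, seed=seed
        )
        lasso = response.fit_lasso_auc(design, auc, n_folds=cfg["n_folds"], seed=seed)
        emit(
            "respond",
            "lasso_coefficients.tsv",
            lasso.summary(),
            {"r2": lasso.r2, "alpha": lasso.alpha, "referent": referent},
        )
        auc_tab = pd.DataFrame([auc.rename("demo_drug")])
        rho = drug_cc_correlation(comps_h, auc_tab, min_models=min(10, len(comps_h)))
        emit("associate", "drug_correlations.tsv", rho, {})

        surv_comp = synthetic.dirichlet_compositions(
            [f"P{i + 1:03d}" for i in range(cfg["survival_cases"])], human, alpha=1.0, seed=seed + 2
        )
        gamma = np.zeros(len(human) - 1)
        gamma[0] = 1.0
        surv, surv_truth = synthetic.simulate_survival(
            surv_comp, gamma, referent, censor_rate=0.2, seed=seed + 2
        )
        surv_design = response.logratio_transform(surv_comp, referent)
        cox = response.fit_cox_composition(surv_design, surv, n_folds=cfg["n_folds"], seed=seed)
        emit("respond", "cox_coefficients.tsv", cox.summary(), {"alpha": cox.alpha})
        if cox.risk_scores.nunique() >= 4:
            _, lr_stat, lr_p = response.quartile_km(cox.risk_scores, surv)
            emit(
                "respond",
                "km_logrank.tsv",
                pd.DataFrame([{"logrank_stat": lr_stat, "logrank_p": lr_p}]),
                {},
            )
    except Exception as exc:  # partial outputs are retained for inspection
        manifest["failed_stage"] = getattr(exc, "stage", type(exc).__name__)
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
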