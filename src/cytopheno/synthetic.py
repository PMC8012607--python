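"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: single-cell marker
intensity tables with a subpanel-structured variance hierarchy, spatial
point catalogues (uniform or Thomas-clustered), dose-response viability
plates, compositions-linked drug AUC values, proportional-hazards survival
records and phenotype-linked binary alteration tables.

The variance hierarchy mimics xenograft mass-cytometry panels: lineage
markers (HTC human tumour / MSC mouse stroma) separate phenotypes and vary
little within one, signalling markers (OSA) vary moderately within a model,
and cell-cycle/apoptosis markers (CCA) vary most.  Hence within-model
coefficients of variation are ordered CCA > OSA > HTC by construction.

All randomness flows from one integer seed through named substreams, so any
stage can be regenerated independently of the others.

Intensities are simulated directly on the arcsinh scale (the scale every
downstream statistic operates on) and clipped at zero, a mild departure
from Gaussianity reflecting non-negative ion counts.  A raw-scale export
applies ``sinh`` with a configured cofactor for FCS round trips.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import (
    CellTable,
    DoseResponsePlate,
    SpatialCatalog,
    SurvivalTable,
    check_composition,
)
from . import io_fcs

SUBPANEL_SIZES = {"HTC": 11, "MSC": 7, "OSA": 10, "CCA": 5}

# within-phenotype standard deviations per subpanel (arcsinh scale);
# the ordering CCA > OSA > HTC/MSC is what the generator must guarantee
_SUBPANEL_SD = {"HTC": 0.25, "MSC": 0.25, "OSA": 0.55, "CCA": 0.9}
_SUBPANEL_BASE = {"HTC": 3.0, "MSC": 3.0, "OSA": 1.8, "CCA": 1.3}

# a few canonical marker names useful for annotation rules; the remainder
# of each subpanel is filled with generic names
_NAMED = {
    "HTC": ["CD298", "EpCAM", "E-cadherin", "Keratin8-18"],
    "MSC": ["MHC-I", "Vimentin"],
    "OSA": ["p-S6", "p-ERK1-2", "p-4E-BP1"],
    "CCA": ["Ki-67", "cCasp3"],
}


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named substream of the master seed."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


def _marker_names(n_per_subpanel: Mapping[str, int]) -> tuple[list[str], dict]:
    names, subpanel_map = [], {}
    for sp, n in n_per_subpanel.items():
        if n <= 0:
            raise ValueError(f"non-positive marker count for subpanel {sp}")
        given = _NAMED.get(sp, [])[:n]
        fill = [f"{sp}{i:02d}" for i in range(len(given) + 1, n + 1)]
        for m in given + fill:
            names.append(m)
            subpanel_map[m] = sp
    return names, subpanel_map


@dataclass
class PhenotypeTemplate:
    """Gaussian marker template of one cell phenotype (arcsinh scale)."""

    phenotype_id: str
    marker_means: pd.Series
    marker_sds: pd.Series
    subpanel_map: dict
    spatial_mode: str = "random"  # "random" | "clustered"
    cluster_scale: float = 20.0  # Gaussian offspring scatter sd, um

    def __post_init__(self) -> None:
        if (self.marker_sds <= 0).any():
            raise ValueError("marker_sds must be strictly positive")
        if set(self.marker_means.index) != set(self.subpanel_map):
            raise ValueError("subpanel_map must cover exactly the template markers")
        if self.spatial_mode not in ("random", "clustered"):
            raise ValueError(f"unknown spatial_mode {self.spatial_mode!r}")


@dataclass
class GroundTruth:
    """Recovery targets emitted alongside each simulated artefact."""

    labels: np.ndarray | None = None
    compositions: pd.DataFrame | None = None
    beta: pd.Series | None = None
    gamma: pd.Series | None = None
    spatial: dict = field(default_factory=dict)
    seed: int | None = None


def make_templates(
    n_phenotypes: int,
    n_markers_per_subpanel: Mapping[str, int] | None = None,
    separation: float = 8.0,
    seed: int = 0,
    include_stroma: bool = True,
    spatial_mode: str = "random",
    cluster_scale: float = 20.0,
) -> list[PhenotypeTemplate]:
    """Build phenotype templates with guaranteed lineage separation.

    Parameters
    ----------
    n_phenotypes : int
        Total number of phenotypes (including one mouse-stroma phenotype
        when ``include_stroma``); must be >= 2.
    n_markers_per_subpanel : mapping, optional
        Markers per subpanel; defaults to the 11/7/10/5 HTC/MSC/OSA/CCA
        panel sizes.
    separation : float
        Minimum pairwise Euclidean distance between phenotype HTC-mean
        vectors, in units of the within-phenotype HTC sd.  The default (8)
        is the "well-separated" preset: the Bayes error of lineage-marker
        classification is far below 1% and nearest-centroid transfer on a
        10-marker subset leaves well under 10% of cells rejected.
    seed : int
        Substream master seed; identical seeds give identical templates.
    include_stroma : bool
        Make the last phenotype a mouse-stroma template (high MSC / MHC-I,
        low HTC / CD298).
    spatial_mode, cluster_scale
        Spatial placement defaults stamped on every template (tests and
        catalogues may override per phenotype).
    """
    if n_phenotypes < 2:
        raise ValueError("need at least 2 phenotypes")
    if separation <= 0:
        raise ValueError("separation must be positive")
    sizes = dict(n_markers_per_subpanel or SUBPANEL_SIZES)
    markers, subpanel_map = _marker_names(sizes)
    rng = _stream(seed, "templates")

    sp_of = np.array([subpanel_map[m] for m in markers])
    htc = sp_of == "HTC"
    msc = sp_of == "MSC"

    n_human = n_phenotypes - 1 if include_stroma else n_phenotypes
    # phenotype offsets on lineage markers, rescaled so the minimum pairwise
    # distance equals separation * within-sd (the separation guarantee)
    offs = rng.normal(size=(n_human, int(htc.sum())))
    if n_human > 1:
        d = np.sqrt(((offs[:, None, :] - offs[None, :, :]) ** 2).sum(-1))
        d_min = d[np.triu_indices(n_human, 1)].min()
        offs *= separation * _SUBPANEL_SD["HTC"] / d_min
    else:
        offs[:] = 0.0

    templates = []
    other = ~htc & ~msc
    for p in range(n_phenotypes):
        is_stroma = include_stroma and p == n_phenotypes - 1
        means = np.empty(len(markers))
        sds = np.array([_SUBPANEL_SD[s] for s in sp_of])
        if is_stroma:
            means[htc] = 0.3
            means[msc] = _SUBPANEL_BASE["MSC"] + 0.2 * rng.normal(size=int(msc.sum()))
        else:
            means[htc] = _SUBPANEL_BASE["HTC"] + offs[p]
            means[msc] = 0.3
        # signalling / cell-cycle means barely differ between phenotypes:
        # their variance lives within the model
        means[other] = np.array([_SUBPANEL_BASE[s] for s in sp_of[other]]) + 0.1 * rng.normal(
            size=int(other.sum())
        )
        means = np.clip(means, 0.05, None)
        templates.append(
            PhenotypeTemplate(
                phenotype_id="S1" if is_stroma else f"C{p + 1}",
                marker_means=pd.Series(means, index=markers),
                marker_sds=pd.Series(sds, index=markers),
                subpanel_map=dict(subpanel_map),
                spatial_mode=spatial_mode,
                cluster_scale=cluster_scale,
            )
        )
    return templates


def well_separated_preset(
    n_models: int = 20,
    n_phenotypes: int = 4,
    seed: int = 0,
    separation: float = 8.0,
) -> tuple[list[PhenotypeTemplate], pd.DataFrame]:
    """Default study conditions: separated phenotypes, stroma-light models.

    Human phenotype proportions are Dirichlet(1); the mouse-stroma fraction
    is an independent Beta(2, 30) draw (mean ~6%, rarely above 20%), since
    xenografts are dominated by human tumour cells.  Keeping stroma
    structurally minor is also what keeps per-model lineage-marker CVs
    below the signalling/cell-cycle ones.
    """
    templates = make_templates(n_phenotypes, separation=separation, seed=seed)
    ids = [t.phenotype_id for t in templates]
    human = dirichlet_compositions(
        [f"M{i + 1:02d}" for i in range(n_models)], ids[:-1], alpha=1.0, seed=seed
    )
    rng = _stream(seed, "stroma")
    f = rng.beta(2.0, 30.0, size=n_models)
    comps = human.mul(1.0 - f, axis=0)
    comps[ids[-1]] = f
    return templates, comps


def dirichlet_compositions(
    model_ids: Sequence[str],
    phenotype_ids: Sequence[str],
    alpha: float | Sequence[float] = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Model x phenotype composition matrix drawn from a Dirichlet."""
    rng = _stream(seed, "compositions")
    a = np.broadcast_to(np.asarray(alpha, dtype=float), (len(phenotype_ids),))
    rows = rng.dirichlet(a, size=len(model_ids))
    return pd.DataFrame(rows, index=list(model_ids), columns=list(phenotype_ids))


def simulate_cell_table(
    templates: Sequence[PhenotypeTemplate],
    model_compositions: pd.DataFrame,
    cells_per_model: int = 1600,
    noise_sd: float = 0.0,
    seed: int = 0,
    batch_ids: Sequence[str] | None = None,
) -> tuple[CellTable, GroundTruth]:
    """Draw a cells x markers table from the phenotype templates.

    Per model, phenotype counts are a multinomial draw from the model's
    composition row; each cell is Gaussian around its phenotype template on
    the arcsinh scale, plus optional extra noise, clipped at zero.
    """
    if cells_per_model < 1:
        raise ValueError("cells_per_model must be >= 1")
    check_composition(model_compositions)
    by_id = {t.phenotype_id: t for t in templates}
    missing = [p for p in model_compositions.columns if p not in by_id]
    if missing:
        raise ValueError(f"compositions reference unknown phenotypes: {missing}")
    markers = list(templates[0].marker_means.index)
    rng = _stream(seed, "cells")
    batch_ids = list(batch_ids or ["B1"])

    blocks, labels, obs_rows = [], [], []
    for mi, (model, row) in enumerate(model_compositions.iterrows()):
        counts = rng.multinomial(cells_per_model, row.to_numpy(dtype=float))
        for pheno, n in zip(model_compositions.columns, counts):
            if n == 0:
                continue
            t = by_id[pheno]
            sd = np.sqrt(t.marker_sds.to_numpy() ** 2 + noise_sd**2)
            x = rng.normal(t.marker_means.to_numpy(), sd, size=(n, len(markers)))
            blocks.append(np.clip(x, 0.0, None))
            labels.extend([pheno] * n)
            obs_rows.extend(
                {
                    "model_id": model,
                    "sample_id": model,
                    "batch_id": batch_ids[mi % len(batch_ids)],
                }
                for _ in range(n)
            )
    X = np.vstack(blocks)
    obs = pd.DataFrame(obs_rows)
    t0 = templates[0]
    var = pd.DataFrame(
        {"subpanel": [t0.subpanel_map[m] for m in markers]}, index=pd.Index(markers, name="marker")
    )
    table = CellTable(X=X, obs=obs, var=var, stages=("arcsinh",))
    truth = GroundTruth(
        labels=np.array(labels), compositions=model_compositions.copy(), seed=seed
    )
    return table, truth


# -- spatial ------------------------------------------------------------


def simulate_spatial_catalog(
    templates: Sequence[PhenotypeTemplate],
    composition: pd.Series | Mapping[str, float],
    n_cells: int,
    field: tuple[float, float, float, float] = (0.0, 0.0, 600.0, 600.0),
    seed: int = 0,
    image_id: str = "img1",
    mean_offspring: float = 20.0,
) -> tuple[SpatialCatalog, GroundTruth]:
    """Place phenotype-labelled cells in a rectangle.

    Phenotypes with ``spatial_mode="random"`` are uniform over the field
    (complete spatial randomness); clustered phenotypes follow a Thomas
    process: uniform Poisson parents, each point assigned to a random
    parent and scattered with isotropic Gaussian sd ``cluster_scale``;
    points falling outside the field are redrawn.
    """
    x0, y0, x1, y1 = map(float, field)
    if (x1 - x0) <= 0 or (y1 - y0) <= 0:
        raise ValueError("field must have positive area")
    comp = pd.Series(dict(composition), dtype=float)
    check_composition(comp.to_frame().T)
    by_id = {t.phenotype_id: t for t in templates}
    rng = _stream(seed, "space")
    markers = list(templates[0].marker_means.index)

    rows = []
    counts = rng.multinomial(int(n_cells), comp.to_numpy()) if n_cells else []
    spatial_truth = {}
    for pheno, n in zip(comp.index, counts):
        t = by_id[pheno]
        spatial_truth[pheno] = {
            "mode": t.spatial_mode,
            "cluster_scale": t.cluster_scale if t.spatial_mode == "clustered" else None,
        }
        if n == 0:
            continue
        if t.spatial_mode == "random":
            xs = rng.uniform(x0, x1, n)
            ys = rng.uniform(y0, y1, n)
        else:
            n_parents = max(1, int(round(n / mean_offspring)))
            px = rng.uniform(x0, x1, n_parents)
            py = rng.uniform(y0, y1, n_parents)
            parent = rng.integers(0, n_parents, n)
            xs = px[parent] + rng.normal(0.0, t.cluster_scale, n)
            ys = py[parent] + rng.normal(0.0, t.cluster_scale, n)
            bad = (xs < x0) | (xs > x1) | (ys < y0) | (ys > y1)
            while bad.any():
                k = int(bad.sum())
                pk = rng.integers(0, n_parents, k)
                xs[bad] = px[pk] + rng.normal(0.0, t.cluster_scale, k)
                ys[bad] = py[pk] + rng.normal(0.0, t.cluster_scale, k)
                bad = (xs < x0) | (xs > x1) | (ys < y0) | (ys > y1)
        intens = np.clip(
            rng.normal(
                t.marker_means.to_numpy(), t.marker_sds.to_numpy(), size=(n, len(markers))
            ),
            0.0,
            None,
        )
        for i in range(n):
            rows.append(
                {"image_id": image_id, "x_um": xs[i], "y_um": ys[i], "label": pheno}
                | dict(zip(markers, intens[i]))
            )
    cells = pd.DataFrame(
        rows, columns=["image_id", "x_um", "y_um", "label"] + markers
    )
    catalog = SpatialCatalog(cells=cells, regions={image_id: (x0, y0, x1, y1)})
    truth = GroundTruth(
        labels=cells["label"].to_numpy() if len(cells) else np.array([]),
        spatial=spatial_truth,
        seed=seed,
    )
    return catalog, truth


# -- drug response ------------------------------------------------------


def simulate_dose_response_plate(
    model_sensitivity: float,
    doses: Sequence[float],
    n_reps: int = 3,
    noise_sd: float = 0.0,
    controls: tuple[float, float] = (10000.0, 500.0),
    seed: int = 0,
    ec50: float | None = None,
    hill: float = 1.5,
    drug_id: str = "drug",
    model_id: str = "model",
) -> DoseResponsePlate:
    """Hill-curve viability plate scaled between plate controls.

    ``controls = (pos, neg)``: the positive control is the untreated
    (fully viable) intensity, the negative control the fully killed one,
    matching the response formula response = 100 - 100*(I - neg)/(pos - neg)
    so that sensitivity 0 gives response ~0 and a saturating responder ~100.
    """
    pos, neg = controls
    if pos == neg:
        raise ValueError("positive and negative controls must differ")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0) or np.any(np.diff(doses) < 0):
        raise ValueError("doses must be positive and sorted ascending")
    if not 0.0 <= model_sensitivity <= 1.0:
        raise ValueError("model_sensitivity must be in [0, 1]")
    rng = _stream(seed, "plates")
    if ec50 is None:
        ec50 = float(np.exp(np.mean(np.log(doses))))
    kill = model_sensitivity * doses**hill / (doses**hill + ec50**hill)
    viability = 1.0 - kill
    mean_intensity = neg + (pos - neg) * viability
    intensities = mean_intensity[:, None] + rng.normal(0.0, noise_sd, (doses.size, n_reps))
    return DoseResponsePlate(
        drug_id=drug_id,
        model_id=model_id,
        doses=doses,
        intensities=intensities,
        pos_control=pos,
        neg_control=neg,
    )


def simulate_auc_from_composition(
    compositions: pd.DataFrame,
    beta: Sequence[float] | pd.Series,
    referent: str,
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 0.3,
    pseudocount: float | None = None,
) -> tuple[pd.Series, GroundTruth]:
    """Forward model: AUC linear in phenotype log-ratios, clipped to [0, 1]."""
    from .response import logratio_transform

    design = logratio_transform(compositions, referent, pseudocount=pseudocount)
    beta = np.asarray(beta, dtype=float)
    if beta.size != design.matrix.shape[1]:
        raise ValueError(
            f"beta has {beta.size} entries but design has {design.matrix.shape[1]} log-ratios"
        )
    rng = _stream(seed, "auc")
    auc = intercept + design.matrix.to_numpy() @ beta + rng.normal(0.0, noise_sd, len(compositions))
    auc = np.clip(auc, 0.0, 1.0)
    truth = GroundTruth(
        beta=pd.Series(beta, index=design.matrix.columns), seed=seed
    )
    return pd.Series(auc, index=compositions.index, name="auc"), truth


def simulate_survival(
    compositions: pd.DataFrame,
    gamma: Sequence[float] | pd.Series,
    referent: str,
    baseline: tuple[float, float] = (1.5, 60.0),
    censor_rate: float = 0.2,
    seed: int = 0,
    pseudocount: float | None = None,
) -> tuple[SurvivalTable, GroundTruth]:
    """Weibull proportional-hazards event times driven by log-ratios.

    ``baseline = (shape, scale)`` of the Weibull; the linear predictor
    gamma . log-ratios shifts the log hazard.  Censoring is independent:
    each case is censored with probability ``censor_rate`` at a uniform
    fraction of its event time.
    """
    from .response import logratio_transform

    shape, scale = baseline
    if shape <= 0 or scale <= 0:
        raise ValueError("Weibull shape and scale must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    design = logratio_transform(compositions, referent, pseudocount=pseudocount)
    gamma = np.asarray(gamma, dtype=float)
    if gamma.size != design.matrix.shape[1]:
        raise ValueError("gamma length does not match the number of log-ratios")
    rng = _stream(seed, "survival")
    lp = design.matrix.to_numpy() @ gamma
    u = rng.uniform(size=len(compositions))
    t_event = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)
    censored = rng.uniform(size=len(compositions)) < censor_rate
    time = np.where(censored, t_event * rng.uniform(size=len(compositions)), t_event)
    time = np.maximum(time, 1e-6)
    data = pd.DataFrame(
        {
            "case_id": list(compositions.index),
            "time": time,
            "event": (~censored).astype(int),
        }
    )
    for c in compositions.columns:
        data[c] = compositions[c].to_numpy()
    truth = GroundTruth(gamma=pd.Series(gamma, index=design.matrix.columns), seed=seed)
    return SurvivalTable(data=data), truth


def simulate_alterations(
    compositions: pd.DataFrame,
    link: Mapping[str, float],
    n_genes: int = 10,
    background_rate: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Binary model x gene alteration matrix with phenotype-linked genes.

    For each phenotype in ``link`` a gene ``alt_<phenotype>`` is created
    whose per-model alteration probability is shifted (on the logit scale)
    when that phenotype dominates the model; remaining genes are Bernoulli
    at the background rate.
    """
    for shift in link.values():
        if expit(logit(background_rate) + shift) > 1:
            raise ValueError("linked probability exceeds 1")
    rng = _stream(seed, "alterations")
    dominant = compositions.idxmax(axis=1)
    genes, probs = [], []
    for pheno, shift in link.items():
        genes.append(f"alt_{pheno}")
        p = np.where(
            dominant.to_numpy() == pheno,
            expit(logit(background_rate) + shift),
            background_rate,
        )
        probs.append(p)
    for g in range(n_genes - len(link)):
        genes.append(f"gene{g + 1:02d}")
        probs.append(np.full(len(compositions), background_rate))
    mat = (rng.uniform(size=(len(compositions), len(genes))) < np.column_stack(probs)).astype(int)
    table = pd.DataFrame(mat, index=compositions.index, columns=genes)
    return table, {f"alt_{p}": p for p in link}


# -- writers ------------------------------------------------------------


def write_cell_table(table: CellTable, path) -> None:
    """Delimited text: metadata columns then one column per marker."""
    # %.17g guarantees exact float round trips through text
    table.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_cell_table_fcs(table: CellTable, path, cofactor: float = 5.0) -> None:
    """Raw-scale FCS export: applies sinh with the configured cofactor."""
    raw = pd.DataFrame(np.sinh(table.X) * cofactor, columns=table.markers)
    io_fcs.write_fcs(path, raw)


def write_spatial_catalog(catalog: SpatialCatalog, path) -> None:
    catalog.cells.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "seed": truth.seed,
        "labels": None if truth.labels is None else list(map(str, truth.labels)),
        "compositions": None
        if truth.compositions is None
        else truth.compositions.to_dict(orient="index"),
        "beta": None if truth.beta is None else truth.beta.to_dict(),
        "gamma": None if truth.gamma is None else truth.gamma.to_dict(),
        "spatial": truth.spatial,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
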