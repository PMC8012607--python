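"""Graph-based clustering with subsample-ARI stability scanning.

The clustering follows the PhenoGraph recipe: an exact k-nearest-neighbour
graph on Euclidean distances, edges reweighted by the Jaccard overlap of
the two endpoints' neighbour sets, then modularity maximisation (Louvain by
default, Leiden optional).  Stability of a choice of ``k`` is measured by
re-clustering repeated 90% subsamples and computing the adjusted Rand
index over every pair of runs on their shared cells.

Downstream quantifications: per-model phenotype prevalence (compositions),
Simpson's diversity 1 - sum(p_i^2) of each composition row, and per-model
mean coefficients of variation per marker subpanel.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .containers import CellTable


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    centroids: pd.DataFrame  # cluster x marker medians
    prevalence: pd.DataFrame | None = None
    annotations: dict = field(default_factory=dict)


@dataclass
class StabilityReport:
    per_k: pd.DataFrame  # k, median_ari, mean_n_clusters, n_pairs
    ari_values: dict = field(default_factory=dict)  # k -> list of pairwise ARI
    params: dict = field(default_factory=dict)


def default_k(n_cells: int, reference_k: int = 250, reference_n: int = 78400, floor: int = 80) -> int:
    """Scale the full-scale neighbourhood size down to small runs.

    Keeps the neighbourhood density of the full-scale choice (k=250 at
    78,400 cells) with a floor of 80: with fewer neighbours the modularity
    resolution limit starts splitting genuine phenotypes at desk scale,
    especially ones holding a large share of the cells.
    """
    return max(floor, round(reference_k * n_cells / reference_n))


def _knn_jaccard_graph(X: np.ndarray, k: int) -> ig.Graph:
    """Exact kNN graph (ties by index order) with Jaccard edge weights."""
    n = X.shape[0]
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto").fit(X)
    _, idx = nn.kneighbors(X)
    neigh = idx[:, 1:]  # drop self
    sets = [set(row) for row in neigh]
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in neigh[i]:
            j = int(j)
            key = (i, j) if i < j else (j, i)
            if key in seen:
                continue
            seen.add(key)
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            w = inter / union if union else 0.0
            if w > 0:
                edges.append(key)
                weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_graph(
    table: CellTable | np.ndarray,
    k: int | None = None,
    seed: int = 0,
    method: str = "leiden",
) -> ClusterResult:
    """PhenoGraph-style community detection on a kNN-Jaccard graph.

    Parameters
    ----------
    table : CellTable or ndarray
        Preprocessed intensities (cells x markers).
    k : int, optional
        Neighbour count; defaults to :func:`default_k` of the cell count
        (250 at full scale).
    method : {"leiden", "louvain"}
        Community detection flavour; both maximise modularity.  Leiden is
        the default: it optimises the same objective but avoids the badly
        split partitions plain Louvain can leave behind.
    """
    X = table.X if isinstance(table, CellTable) else np.asarray(table, dtype=float)
    n = X.shape[0]
    if k is None:
        k = default_k(n)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    g = _knn_jaccard_graph(X, k)
    if method == "louvain":
        ig.set_random_number_generator(random.Random(seed))
        part = g.community_multilevel(weights="weight")
        labels = np.asarray(part.membership)
    elif method == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.ModularityVertexPartition,
            weights="weight",
            seed=int(seed),
            n_iterations=2,
        )
        labels = np.asarray(part.membership)
    else:
        raise ValueError(f"unknown method {method!r}")

    if isinstance(table, CellTable):
        cent = cluster_centroids(table, labels)
        prev = compute_prevalence_from_labels(labels, table.obs["model_id"].to_numpy())
    else:
        cent = pd.DataFrame(
            [np.median(X[labels == c], axis=0) for c in np.unique(labels)],
            index=np.unique(labels),
        )
        prev = None
    return ClusterResult(labels=labels, k=k, centroids=cent, prevalence=prev)


def cluster_centroids(table: CellTable, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster marker medians."""
    out = {}
    for c in np.unique(labels):
        out[c] = np.median(table.X[labels == c], axis=0)
    return pd.DataFrame.from_dict(out, orient="index", columns=table.markers)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement (permutation-model ARI)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label lengths differ: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))


def stability_scan(
    table: CellTable | np.ndarray,
    k_values,
    n_reps: int = 100,
    subsample_frac: float = 0.9,
    seed: int = 0,
    method: str = "leiden",
) -> StabilityReport:
    """Subsample-ARI stability of the clustering across candidate ``k``.

    For each ``k``, the clustering is repeated ``n_reps`` times on
    ``subsample_frac`` of the cells; ARI is computed for every pair of
    repetitions on the intersection of their subsampled cells.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    X = table.X if isinstance(table, CellTable) else np.asarray(table, dtype=float)
    n = X.shape[0]
    m = int(round(subsample_frac * n))
    rng = np.random.default_rng(seed)
    rows, ari_values = [], {}
    for k in k_values:
        runs = []
        for r in range(n_reps):
            sub = np.sort(rng.choice(n, size=m, replace=False))
            res = cluster_graph(X[sub], k=k, seed=seed + r, method=method)
            lab = np.full(n, -1)
            lab[sub] = res.labels
            runs.append((sub, lab, len(np.unique(res.labels))))
        aris = []
        for i in range(n_reps):
            for j in range(i + 1, n_reps):
                common = np.intersect1d(runs[i][0], runs[j][0], assume_unique=True)
                if common.size == 0:
                    continue
                aris.append(adjusted_rand_index(runs[i][1][common], runs[j][1][common]))
        ari_values[k] = aris
        rows.append(
            {
                "k": k,
                "median_ari": float(np.median(aris)),
                "mean_n_clusters": float(np.mean([r[2] for r in runs])),
                "n_pairs": len(aris),
            }
        )
    return StabilityReport(
        per_k=pd.DataFrame(rows),
        ari_values=ari_values,
        params={"n_reps": n_reps, "subsample_frac": subsample_frac, "seed": seed},
    )


def compute_prevalence_from_labels(
    labels: np.ndarray, model_ids: np.ndarray, subset=None
) -> pd.DataFrame:
    """Per-model cluster proportions, renormalised over ``subset`` labels."""
    df = pd.DataFrame({"model": model_ids, "label": labels})
    counts = df.groupby(["model", "label"], sort=True).size().unstack(fill_value=0)
    if subset is not None:
        missing = [s for s in subset if s not in counts.columns]
        for s in missing:
            counts[s] = 0
        counts = counts[list(subset)]
    totals = counts.sum(axis=1)
    prev = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    prev.attrs["zero_models"] = list(totals.index[totals == 0])
    return prev


def compute_prevalence(result: ClusterResult, model_ids: np.ndarray, subset=None) -> pd.DataFrame:
    return compute_prevalence_from_labels(result.labels, model_ids, subset=subset)


def simpson_score(prevalence_row) -> float:
    """Simpson's diversity 1 - sum(p_i^2); 0 = homogeneous composition."""
    p = np.asarray(prevalence_row, dtype=float)
    if (p < 0).any():
        raise ValueError("prevalence entries must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("prevalence row must sum to 1")
    return float(1.0 - np.sum(p**2))


def subpanel_cv(table: CellTable, model_ids=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-model mean coefficient of variation per marker subpanel.

    CV = sd/mean per (model, marker) on arcsinh intensities, averaged over
    the markers of each subpanel; markers with zero mean in a model are
    excluded and counted.  Returns (model x subpanel table, paired
    two-sided t-tests between subpanels across models).
    """
    if "subpanel" not in table.var.columns:
        raise ValueError("subpanel map absent from table.var")
    models = table.obs["model_id"].to_numpy() if model_ids is None else np.asarray(model_ids)
    subpanels = [s for s in ("HTC", "MSC", "OSA", "CCA") if (table.var["subpanel"] == s).any()]
    rows = {}
    excluded = 0
    for model in pd.unique(models):
        sel = models == model
        mu = table.X[sel].mean(axis=0)
        sd = table.X[sel].std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mu > 0, sd / mu, np.nan)
        excluded += int(np.sum(mu <= 0))
        rows[model] = {
            sp: float(np.nanmean(cv[(table.var["subpanel"] == sp).to_numpy()]))
            for sp in subpanels
        }
    cv_table = pd.DataFrame.from_dict(rows, orient="index")[subpanels]
    cv_table.attrs["excluded_zero_mean"] = excluded
    tests = []
    if len(cv_table) >= 2:
        for i, a in enumerate(subpanels):
            for b in subpanels[i + 1 :]:
                t, p = stats.ttest_rel(cv_table[a], cv_table[b])
                tests.append({"subpanel_a": a, "subpanel_b": b, "t": float(t), "p": float(p)})
    return cv_table, pd.DataFrame(tests)


DEFAULT_ANNOTATION_RULES = [
    ("stroma", {"MHC-I": (">", 1.5), "CD298": ("<", 1.0)}),
    ("luminal", {"EpCAM": (">", 1.5), "E-cadherin": (">", 1.5)}),
    ("mesenchymal", {"Vimentin": (">", 1.5), "EpCAM": ("<", 1.0)}),
]


def annotate_clusters(centroids: pd.DataFrame, rules=None) -> dict:
    """First-match threshold rules on centroid medians -> lineage label.

    Each rule is ``(label, {marker: (op, threshold)})`` with op in
    {">", "<"}; clusters matching no rule get ``"other"``.  Rules naming
    markers absent from the centroid table raise.
    """
    rules = DEFAULT_ANNOTATION_RULES if rules is None else rules
    for label, conds in rules:
        missing = [m for m in conds if m not in centroids.columns]
        if missing:
            raise ValueError(f"rule {label!r} references unknown markers {missing}")
    out = {}
    for cluster, row in centroids.iterrows():
        assigned = "other"
        for label, conds in rules:
            ok = all(
                (row[m] > thr) if op == ">" else (row[m] < thr)
                for m, (op, thr) in conds.items()
            )
            if ok:
                assigned = label
                break
        out[cluster] = assigned
    return out
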