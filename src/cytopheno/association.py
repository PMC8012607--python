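"""Distribution-shift, dependence and enrichment statistics.

* :func:`signed_emd` -- 1-D Earth Mover's (Wasserstein-1) distance between
  two marker distributions on a shared histogram grid, signed by the
  difference of the group medians (treated - control).
* :func:`dremi` -- density-resampled mutual information: the joint density
  is estimated on a grid by k-nearest-neighbour distances, each X column is
  renormalised to a conditional p(Y|X), and MI is computed giving every
  occupied X bin equal weight.  Emphasises the response shape of Y to X
  rather than the X marginal.
* :func:`alteration_enrichment` -- per (phenotype, alteration)
  hypergeometric over-representation of cells from altered models, with
  Bonferroni control.
* :func:`rank_correlation_enrichment` -- gene-set enrichment on genes
  ranked by correlation of expression with phenotype prevalence.
* :func:`drug_cc_correlation` -- Spearman correlation of phenotype
  prevalence with drug-response AUC across models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree


@dataclass
class SignedEMDResult:
    marker: str
    magnitude: float
    sign: int
    signed_value: float
    median_control: float
    median_treated: float


def signed_emd(
    values_control, values_treated, bin_width: float = 0.1, marker: str = ""
) -> SignedEMDResult:
    """Binned 1-D optimal-transport distance with a median-shift sign.

    Both samples are histogrammed on a shared grid (padded one bin each
    side), normalised to unit mass; the EMD is the integrated absolute
    difference of the two CDFs.  The sign is that of
    median(treated) - median(control); zero magnitude gives sign 0.
    """
    x = np.asarray(values_control, dtype=float)
    y = np.asarray(values_treated, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = min(x.min(), y.min()) - bin_width
    hi = max(x.max(), y.max()) + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    hx, _ = np.histogram(x, bins=edges)
    hy, _ = np.histogram(y, bins=edges)
    cx = np.cumsum(hx / hx.sum())
    cy = np.cumsum(hy / hy.sum())
    magnitude = float(np.sum(np.abs(cx - cy)) * bin_width)
    med_c, med_t = float(np.median(x)), float(np.median(y))
    sign = 0 if magnitude == 0 else int(np.sign(med_t - med_c)) or 1
    return SignedEMDResult(
        marker=marker,
        magnitude=magnitude,
        sign=sign,
        signed_value=sign * magnitude,
        median_control=med_c,
        median_treated=med_t,
    )


def dremi(x_values, y_values, n_bins: int = 20, k_density: int = 10) -> float:
    """Density-resampled mutual information of y on x, in bits.

    Returns 0 (flagged via ``dremi.last_flag``) when x is constant.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired samples of equal length")
    if x.size < 100:
        raise ValueError("need at least 100 paired observations")
    dremi.last_flag = None
    if np.ptp(x) == 0:
        dremi.last_flag = "constant_x"
        return 0.0
    if np.ptp(y) == 0:
        dremi.last_flag = "constant_y"
        return 0.0
    # min-max scale both axes so the kNN density is isotropic on the grid
    xs = (x - x.min()) / np.ptp(x)
    ys = (y - y.min()) / np.ptp(y)
    tree = cKDTree(np.column_stack([xs, ys]))
    centres = (np.arange(n_bins) + 0.5) / n_bins
    gx, gy = np.meshgrid(centres, centres, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    r_k, _ = tree.query(grid, k=k_density)
    r_k = r_k[:, -1]
    dens = k_density / (np.pi * np.maximum(r_k, 1e-12) ** 2)
    dens = dens.reshape(n_bins, n_bins)  # [x_bin, y_bin]

    # occupied X bins: those actually containing data
    occ = np.histogram(xs, bins=n_bins, range=(0, 1))[0] > 0
    cond = dens[occ]
    cond = cond / cond.sum(axis=1, keepdims=True)  # p(y|x) per occupied x
    px = 1.0 / cond.shape[0]  # uniform weight per occupied x bin
    py = (cond * px).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = np.nansum(px * cond * np.log2(cond / py[None, :]))
    return float(max(mi, 0.0))


def alteration_enrichment(
    labels,
    cell_model_ids,
    alteration_table: pd.DataFrame,
    adjusted_alpha: float = 0.01,
    min_prevalence: float | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Hypergeometric over-representation of altered-model cells per phenotype.

    For phenotype k and alteration a: a population of N cells contains K
    cells in k and n cells from models carrying a; the overlap x is tested
    with the upper-tail hypergeometric P(X >= x) (``alternative="greater"``;
    a doubled-tail two-sided option exists).  P-values are Bonferroni
    adjusted over all (phenotype, alteration) pairs.

    ``min_prevalence`` keeps only alterations whose cell percentage exceeds
    the threshold in at least one phenotype.
    """
    labels = np.asarray(labels)
    models = np.asarray(cell_model_ids)
    unknown = set(pd.unique(models)) - set(alteration_table.index)
    if unknown:
        raise ValueError(f"cells from models absent in alteration table: {sorted(unknown)}")
    N = len(labels)
    rows = []
    for alt in alteration_table.columns:
        altered_models = set(alteration_table.index[alteration_table[alt] == 1])
        in_alt = np.isin(models, list(altered_models))
        n = int(in_alt.sum())
        for k in pd.unique(labels):
            sel = labels == k
            K = int(sel.sum())
            x = int((sel & in_alt).sum())
            pct = 100.0 * x / K if K else 0.0
            if n == 0:
                p = 1.0
            elif alternative == "greater":
                p = float(stats.hypergeom.sf(x - 1, N, K, n))
            elif alternative == "two-sided":
                upper = float(stats.hypergeom.sf(x - 1, N, K, n))
                lower = float(stats.hypergeom.cdf(x, N, K, n))
                p = min(1.0, 2.0 * min(upper, lower))
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
            rows.append(
                {
                    "phenotype": k,
                    "alteration": alt,
                    "cell_pct": pct,
                    "n_overlap": x,
                    "p_raw": p,
                    "all_models_altered": n == N,
                }
            )
    out = pd.DataFrame(rows)
    n_tests = len(out)
    out["p_adj"] = np.minimum(1.0, out["p_raw"] * n_tests)
    out["significant"] = out["p_adj"] < adjusted_alpha
    if min_prevalence is not None:
        keep_alts = out.groupby("alteration")["cell_pct"].max() / 100.0 > min_prevalence
        out = out[out["alteration"].map(keep_alts)].reset_index(drop=True)
    return out


def read_gmt(path) -> dict:
    """Gene sets from GMT: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def rank_correlation_enrichment(
    expression: pd.DataFrame,
    prevalence: pd.DataFrame,
    gene_sets: dict | str,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_threshold: float = 0.01,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Gene-set enrichment on correlation-ranked genes, per phenotype.

    Genes (rows of ``expression``, columns = models) are ranked by Pearson
    correlation of expression with each phenotype's prevalence across the
    shared models; a weighted running-sum enrichment analysis with a gene
    permutation null gives NES and FDR per set.
    """
    import gseapy

    if isinstance(gene_sets, str):
        gene_sets = read_gmt(gene_sets)
    shared = [m for m in expression.columns if m in prevalence.index]
    if len(shared) < 2:
        raise ValueError("need at least 2 shared models")
    expr = expression[shared]
    results = []
    dropped = {
        name: [g for g in genes if g not in expression.index]
        for name, genes in gene_sets.items()
    }
    usable = {
        name: [g for g in genes if g in expression.index]
        for name, genes in gene_sets.items()
    }
    usable = {k: v for k, v in usable.items() if len(v) >= min_set_size}
    if not usable:
        raise ValueError("no gene set has enough genes present in the expression matrix")
    for pheno in prevalence.columns:
        pv = prevalence.loc[shared, pheno].to_numpy(dtype=float)
        if np.ptp(pv) == 0:
            continue
        xc = expr.to_numpy(dtype=float)
        r = np.array(
            [
                np.corrcoef(row, pv)[0, 1] if np.ptp(row) > 0 else 0.0
                for row in xc
            ]
        )
        rnk = pd.Series(r, index=expr.index).sort_values(ascending=False)
        res = gseapy.prerank(
            rnk=rnk,
            gene_sets=usable,
            permutation_num=n_perm,
            seed=seed,
            threads=1,
            outdir=None,
            no_plot=True,
            min_size=min_set_size,
            max_size=max(len(v) for v in usable.values()) + 1,
        )
        for _, row in res.res2d.iterrows():
            results.append(
                {
                    "phenotype": pheno,
                    "gene_set": row["Term"],
                    "nes": float(row["NES"]),
                    "fdr": float(row["FDR q-val"]),
                    "significant": float(row["FDR q-val"]) < fdr_threshold,
                    "dropped_genes": len(dropped.get(row["Term"], [])),
                }
            )
    return pd.DataFrame(results)


def drug_cc_correlation(
    prevalence: pd.DataFrame, auc_table: pd.DataFrame, min_models: int = 10
) -> pd.DataFrame:
    """Spearman correlation of phenotype prevalence with per-model drug AUC.

    ``auc_table`` is drug x model (NaN = untested).  Drugs with fewer than
    ``min_models`` overlapping models are skipped with a reason; constant
    prevalence gives an undefined rho, flagged.
    """
    rows = []
    for drug in auc_table.index:
        auc = auc_table.loc[drug].dropna()
        shared = [m for m in auc.index if m in prevalence.index]
        if len(shared) < min_models:
            rows.append(
                {
                    "drug": drug,
                    "phenotype": None,
                    "rho": np.nan,
                    "p": np.nan,
                    "n_models": len(shared),
                    "skipped": True,
                    "reason": f"fewer than {min_models} models",
                }
            )
            continue
        for pheno in prevalence.columns:
            pv = prevalence.loc[shared, pheno].to_numpy(dtype=float)
            if np.ptp(pv) == 0:
                rows.append(
                    {
                        "drug": drug,
                        "phenotype": pheno,
                        "rho": np.nan,
                        "p": np.nan,
                        "n_models": len(shared),
                        "skipped": True,
                        "reason": "constant prevalence",
                    }
                )
                continue
            rho, p = stats.spearmanr(pv, auc.loc[shared].to_numpy())
            rows.append(
                {
                    "drug": drug,
                    "phenotype": pheno,
                    "rho": float(rho),
                    "p": float(p),
                    "n_models": len(shared),
                    "skipped": False,
                    "reason": "",
                }
            )
    return pd.DataFrame(rows)
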