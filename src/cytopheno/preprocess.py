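"""Single-cell table pre-processing.

The canonical mass-cytometry chain is: arcsinh transform -> per-sample
median-signal outlier filter (+/- 2 x IQR) -> low-event sample discard ->
cosine normalisation -> equal-depth downsampling per model.  Stage stamps
on :class:`~cytopheno.containers.CellTable` enforce this order.

An alternative chain for externally processed imaging cohorts (log2
transform, cosine normalisation, per-marker z-scaling) is provided by
:func:`log2_cosine_scale`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CellTable
from . import io_fcs


@dataclass
class PreprocessReport:
    """Cells in/out per filter step plus per-batch concordance tables."""

    steps: list = field(default_factory=list)
    discarded_samples: list = field(default_factory=list)
    concordance: pd.DataFrame | None = None
    warnings: list = field(default_factory=list)

    def record(self, step: str, cells_in: int, cells_out: int, **extra) -> None:
        if cells_out > cells_in:
            raise ValueError("cells_out cannot exceed cells_in")
        self.steps.append({"step": step, "cells_in": cells_in, "cells_out": cells_out, **extra})


def read_cell_table(
    path,
    format: str = "delimited",
    metadata_map: dict | None = None,
    subpanel_map: dict | None = None,
    sep: str = "\t",
) -> CellTable:
    """Load raw intensities from delimited text or FCS.

    ``metadata_map`` maps each of model_id / sample_id / batch_id to either
    a column name in the file or a constant value (for FCS, where no
    metadata columns exist, constants are required).
    """
    metadata_map = dict(metadata_map or {})
    if format == "delimited":
        # round_trip parsing keeps text round trips bit-identical
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    elif format == "fcs":
        df = io_fcs.read_fcs(path)
    else:
        raise IOError(f"unknown format {format!r}")

    obs = pd.DataFrame(index=range(len(df)))
    for key in ("model_id", "sample_id", "batch_id"):
        spec = metadata_map.get(key)
        if spec is None:
            if key in df.columns:
                spec = key
            else:
                raise IOError(f"no mapping or column for required metadata {key!r}")
        if isinstance(spec, str) and spec in df.columns:
            obs[key] = df[spec].to_numpy()
        elif isinstance(spec, str) and format == "delimited":
            raise IOError(f"mapped column {spec!r} for {key!r} not found in file")
        else:
            obs[key] = spec
    meta_cols = {v for v in metadata_map.values() if isinstance(v, str) and v in df.columns}
    meta_cols |= {"model_id", "sample_id", "batch_id", "label"} & set(df.columns)
    marker_cols = [c for c in df.columns if c not in meta_cols]
    var = pd.DataFrame(index=pd.Index(marker_cols, name="marker"))
    if subpanel_map:
        var["subpanel"] = [subpanel_map.get(m, "NA") for m in marker_cols]
    else:
        var["subpanel"] = "NA"
    return CellTable(X=df[marker_cols].to_numpy(dtype=float), obs=obs, var=var)


def arcsinh_transform(table: CellTable, cofactor: float = 5.0) -> CellTable:
    """Elementwise x -> asinh(x / cofactor); standard for ion-count data."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    out = table.with_stage("arcsinh")
    return dataclasses.replace(out, X=np.arcsinh(table.X / cofactor))


def log2_cosine_scale(table: CellTable, pseudo: float = 1.0) -> CellTable:
    """Alternative chain for imaging cohorts: log2, cosine, per-marker z-scale."""
    X = np.log2(table.X + pseudo)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    X = np.divide(X, norms, out=np.zeros_like(X), where=norms > 0)
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, keepdims=True)
    X = np.divide(X - mu, sd, out=np.zeros_like(X), where=sd > 0)
    out = table.with_stage("arcsinh")  # occupies the transform slot in the order
    out = out.with_stage("cosine")
    out = dataclasses.replace(out, X=X)
    out.flags["transform_chain"] = "log2_cosine_scale"
    return out


def filter_outlier_cells(
    table: CellTable, per: str = "sample_id", report: PreprocessReport | None = None
) -> tuple[CellTable, PreprocessReport]:
    """Drop cells whose median marker signal is an outlier within its sample.

    Keeps cells with median in [median - 2 IQR, median + 2 IQR], computed
    per sample (``per="sample_id"``; a global option exists via
    ``per=None``).  Samples with fewer than 4 cells pass through with a
    warning (quartiles undefined).
    """
    report = report or PreprocessReport()
    med = np.median(table.X, axis=1)
    keep = np.ones(table.n_cells, dtype=bool)
    groups = (
        table.obs.groupby(per, sort=False).indices.items()
        if per
        else [("__all__", np.arange(table.n_cells))]
    )
    for name, idx in groups:
        if len(idx) < 4:
            report.warnings.append(f"sample {name!r} has <4 cells; outlier filter skipped")
            continue
        m = med[idx]
        q1, q3 = np.percentile(m, [25, 75])
        iqr = q3 - q1
        centre = np.median(m)
        keep[idx] = (m >= centre - 2 * iqr) & (m <= centre + 2 * iqr)
    out = table.with_stage("cell_filter", allow_repeat=True).subset_cells(keep)
    report.record("cell_filter", table.n_cells, int(keep.sum()))
    return out, report


def discard_low_event_samples(
    table: CellTable, min_cells: int = 500, report: PreprocessReport | None = None
) -> tuple[CellTable, PreprocessReport]:
    """Remove samples with fewer than ``min_cells`` cells."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    report = report or PreprocessReport()
    counts = table.obs["sample_id"].value_counts()
    bad = set(counts.index[counts < min_cells])
    keep = ~table.obs["sample_id"].isin(bad).to_numpy()
    out = table.with_stage("sample_filter", allow_repeat=True).subset_cells(keep)
    report.record("sample_filter", table.n_cells, int(keep.sum()), removed_samples=sorted(map(str, bad)))
    report.discarded_samples.extend(sorted(map(str, bad)))
    return out, report


def cosine_normalize(table: CellTable) -> CellTable:
    """Scale each cell's marker vector to unit L2 norm (zero rows flagged)."""
    norms = np.linalg.norm(table.X, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    X = np.divide(table.X, norms, out=table.X.copy(), where=norms > 0)
    out = table.with_stage("cosine", allow_repeat=True)
    out = dataclasses.replace(out, X=X)
    out.flags["zero_norm_cells"] = int(zero.sum())
    return out


def downsample_equal(table: CellTable, n_per_model: int, seed: int = 0) -> CellTable:
    """Uniform without-replacement sample of ``n_per_model`` cells per model.

    Models with fewer cells are retained whole and flagged.
    """
    rng = np.random.default_rng(seed)
    keep_idx = []
    short = []
    for model, idx in table.obs.groupby("model_id", sort=True).indices.items():
        idx = np.sort(idx)
        if len(idx) <= n_per_model:
            if len(idx) < n_per_model:
                short.append(str(model))
            keep_idx.append(idx)
        else:
            keep_idx.append(np.sort(rng.choice(idx, size=n_per_model, replace=False)))
    keep = np.sort(np.concatenate(keep_idx))
    out = table.with_stage("downsample").subset_cells(keep)
    if short:
        out.flags["undersized_models"] = short
    return out


def batch_concordance(
    table: CellTable, reference_sample_ids, bin_width: float = 0.1
) -> PreprocessReport:
    """Per-marker signed EMD between batch replicates of reference samples.

    For every reference sample run in >= 2 batches, all batch pairs are
    compared marker by marker; the summary records each (reference,
    batch pair, marker) triple and the max |EMD| per marker.
    """
    from .association import signed_emd

    report = PreprocessReport()
    rows = []
    for ref in reference_sample_ids:
        sel = table.obs["sample_id"] == ref
        batches = sorted(table.obs.loc[sel, "batch_id"].unique())
        if len(batches) < 2:
            report.warnings.append(f"reference {ref!r} present in <2 batches")
            continue
        for i in range(len(batches)):
            for j in range(i + 1, len(batches)):
                a = sel & (table.obs["batch_id"] == batches[i])
                b = sel & (table.obs["batch_id"] == batches[j])
                for k, marker in enumerate(table.markers):
                    res = signed_emd(
                        table.X[a.to_numpy(), k], table.X[b.to_numpy(), k], bin_width=bin_width
                    )
                    rows.append(
                        {
                            "reference": ref,
                            "batch_a": batches[i],
                            "batch_b": batches[j],
                            "marker": marker,
                            "signed_emd": res.signed_value,
                        }
                    )
    report.concordance = pd.DataFrame(rows)
    return report


def preprocess_chain(
    table: CellTable,
    cofactor: float = 5.0,
    min_cells: int = 500,
    n_per_model: int | None = None,
    seed: int = 0,
) -> tuple[CellTable, PreprocessReport]:
    """Run the canonical chain in order; returns table + combined report."""
    report = PreprocessReport()
    out = arcsinh_transform(table, cofactor)
    out, report = filter_outlier_cells(out, report=report)
    out, report = discard_low_event_samples(out, min_cells=min_cells, report=report)
    out = cosine_normalize(out)
    if n_per_model is not None:
        out = downsample_equal(out, n_per_model, seed=seed)
    return out, report
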