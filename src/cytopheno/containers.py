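"""Core in-memory containers shared across the pipeline.

The universal single-cell container is :class:`CellTable`: a cells x markers
intensity matrix with per-cell metadata (model, sample, batch) and per-marker
metadata (subpanel membership, species reactivity).  Marker subpanels follow
the mass-cytometry panel design for xenograft samples:

* ``HTC`` -- human tumour compartment (lineage markers),
* ``MSC`` -- mouse stroma compartment,
* ``OSA`` -- oncogenic signalling activation (phosphoproteins),
* ``CCA`` -- cell cycle and apoptosis.

A :class:`CellTable` carries a ``stages`` tuple stamping which preprocessing
steps have been applied, so the driver can refuse out-of-order application.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SUBPANELS = ("HTC", "MSC", "OSA", "CCA")

#: canonical preprocessing order enforced by the pipeline driver
STAGE_ORDER = ("arcsinh", "cell_filter", "sample_filter", "cosine", "downsample")


class StageOrderError(RuntimeError):
    """Raised when a preprocessing step is applied out of order."""


@dataclass
class CellTable:
    """Cells x markers intensity matrix with cell and marker metadata.

    Parameters
    ----------
    X : ndarray, shape (n_cells, n_markers)
        Marker intensities. Raw scale on load; arcsinh scale after transform.
    obs : DataFrame
        Per-cell metadata with at least ``model_id``, ``sample_id``,
        ``batch_id`` columns; one row per row of ``X``.
    var : DataFrame
        Per-marker metadata indexed by unique marker name, with a
        ``subpanel`` column in {HTC, MSC, OSA, CCA} and an optional
        ``species`` column ("human"/"mouse"/"cross").
    stages : tuple of str
        Preprocessing stage stamps, in order of application.
    """

    X: np.ndarray
    obs: pd.DataFrame
    var: pd.DataFrame
    stages: tuple = ()
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (cells x markers)")
        if len(self.obs) != self.X.shape[0]:
            raise ValueError(
                f"obs has {len(self.obs)} rows but X has {self.X.shape[0]} cells"
            )
        if len(self.var) != self.X.shape[1]:
            raise ValueError(
                f"var has {len(self.var)} rows but X has {self.X.shape[1]} markers"
            )
        if self.var.index.has_duplicates:
            dupes = self.var.index[self.var.index.duplicated()].tolist()
            raise ValueError(f"duplicate marker names: {dupes}")
        if np.isnan(self.X).any():
            raise ValueError("intensity matrix contains missing values")

    # -- convenience ----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def markers(self) -> list[str]:
        return list(self.var.index)

    def subpanel_markers(self, subpanel: str) -> list[str]:
        return list(self.var.index[self.var["subpanel"] == subpanel])

    def marker_index(self, names: Sequence[str]) -> np.ndarray:
        missing = [m for m in names if m not in self.var.index]
        if missing:
            raise KeyError(f"markers not in table: {missing}")
        pos = {m: i for i, m in enumerate(self.var.index)}
        return np.array([pos[m] for m in names], dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "CellTable":
        mask = np.asarray(mask)
        return dataclasses.replace(
            self,
            X=self.X[mask],
            obs=self.obs.iloc[np.flatnonzero(mask)].reset_index(drop=True)
            if mask.dtype == bool
            else self.obs.iloc[mask].reset_index(drop=True),
            flags=dict(self.flags),
        )

    def subset_markers(self, names: Sequence[str]) -> "CellTable":
        idx = self.marker_index(names)
        return dataclasses.replace(
            self, X=self.X[:, idx], var=self.var.loc[list(names)], flags=dict(self.flags)
        )

    def with_stage(self, stage: str, allow_repeat: bool = False) -> "CellTable":
        """Return a copy stamped with ``stage``, enforcing canonical order.

        ``allow_repeat`` permits idempotent steps (the filters, cosine) to
        run again; non-idempotent transforms keep raising on repeat.
        """
        if stage in self.stages:
            if allow_repeat:
                return dataclasses.replace(self)
            raise StageOrderError(f"stage {stage!r} already applied")
        if stage in STAGE_ORDER:
            k = STAGE_ORDER.index(stage)
            later = [s for s in self.stages if s in STAGE_ORDER and STAGE_ORDER.index(s) > k]
            if later:
                raise StageOrderError(
                    f"cannot apply {stage!r} after {later}: pipeline order is {STAGE_ORDER}"
                )
        return dataclasses.replace(self, stages=self.stages + (stage,))

    # -- I/O -------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """Wide frame: metadata columns followed by one column per marker."""
        df = self.obs.reset_index(drop=True).copy()
        for j, m in enumerate(self.var.index):
            df[m] = self.X[:, j]
        return df

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (optional dependency)."""
        import anndata

        return anndata.AnnData(
            X=self.X.copy(), obs=self.obs.reset_index(drop=True), var=self.var.copy()
        )


@dataclass
class SpatialCatalog:
    """Segmented cells with planar positions (micrometres) and labels.

    ``cells`` columns: ``image_id``, ``x_um``, ``y_um``, optional ``label``
    plus any marker-intensity columns.  ``regions`` maps each image id to its
    bounding rectangle ``(x0, y0, x1, y1)`` in micrometres; when absent the
    convex hull of the image's cells is used downstream.
    """

    cells: pd.DataFrame
    regions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"image_id", "x_um", "y_um"}
        missing = req - set(self.cells.columns)
        if missing:
            raise ValueError(f"catalogue missing columns: {sorted(missing)}")
        xy = self.cells[["x_um", "y_um"]].to_numpy(dtype=float)
        if xy.size and not np.isfinite(xy).all():
            raise ValueError("non-finite coordinates in catalogue")

    def image_points(self, image_id, label=None) -> np.ndarray:
        sel = self.cells["image_id"] == image_id
        if label is not None:
            sel &= self.cells["label"] == label
        return self.cells.loc[sel, ["x_um", "y_um"]].to_numpy(dtype=float)


@dataclass
class DoseResponsePlate:
    """Raw viability plate for one (drug, model) pair.

    ``doses`` strictly positive ascending; ``intensities`` has shape
    (n_doses, n_replicates); plate controls bracket the viability scale
    (positive control = untreated intensity, negative control = full kill).
    """

    drug_id: str
    model_id: str
    doses: np.ndarray
    intensities: np.ndarray
    pos_control: float
    neg_control: float

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if np.any(self.doses <= 0):
            raise ValueError("doses must be strictly positive")
        if np.any(np.diff(self.doses) < 0):
            raise ValueError("doses must be sorted ascending")
        if self.pos_control == self.neg_control:
            raise ValueError("positive and negative controls are equal: response undefined")
        if self.intensities.shape[0] != self.doses.size:
            raise ValueError("intensities rows must match number of doses")


@dataclass
class SurvivalTable:
    """Per-case survival records with phenotype compositions.

    ``data`` columns: ``case_id``, ``time`` (>0), ``event`` (0/1) plus one
    column per phenotype (the composition).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("case_id", "time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"survival table missing column {col!r}")
        if (self.data["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def composition_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("case_id", "time", "event")]


def check_composition(matrix: pd.DataFrame, atol: float = 1e-9) -> pd.DataFrame:
    """Validate a model x phenotype composition matrix (rows sum to 1)."""
    arr = matrix.to_numpy(dtype=float)
    if (arr < -atol).any():
        raise ValueError("composition has negative entries")
    sums = arr.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > max(atol, 1e-9))
    if bad.size:
        raise ValueError(
            f"composition rows do not sum to 1: {list(matrix.index[bad])}"
        )
    return matrix
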