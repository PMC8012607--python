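"""Model-specific nearest-centroid label transfer with posterior rejection.

Phenotype labels learned on one platform (suspension mass cytometry) are
transferred to cells measured on another (imaging mass cytometry, treated
samples, external cohorts) using a nearest-centroid classifier in the
nearest-shrunken-centroid family with shrinkage disabled:

    delta_k(x) = sum_j (x_j - c_kj)^2 / (s_j + s0)^2  -  2 log pi_k

with per-marker pooled within-class sd ``s_j``, stabiliser ``s0`` =
median_j(s_j), and class priors ``pi_k``.  Posteriors are the softmax of
``-delta_k/2``; a cell is left "unclassified" when the gap between its two
highest posteriors falls below a rejection threshold (default 0.9).

Only classes above a training-prevalence gate (default 5%) are modelled,
and transfer is validated by correlating training-side and test-side class
centroids (matching vs non-matching pairs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .containers import CellTable


@dataclass
class CentroidClassifier:
    centroids: pd.DataFrame  # class x shared-marker means
    s: pd.Series  # pooled within-class sd per marker
    s0: float
    priors: pd.Series
    shared_markers: list
    delta_threshold: float = 0.9
    transform_chain: str = "arcsinh_cosine"
    cv_accuracy: float | None = None

    @property
    def classes(self) -> list:
        return list(self.centroids.index)

    # -- persistence (structured text) ---------------------------------

    def to_json(self, path) -> None:
        payload = {
            "centroids": self.centroids.to_dict(orient="index"),
            "s": self.s.to_dict(),
            "s0": self.s0,
            "priors": self.priors.to_dict(),
            "shared_markers": self.shared_markers,
            "delta_threshold": self.delta_threshold,
            "transform_chain": self.transform_chain,
            "cv_accuracy": self.cv_accuracy,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CentroidClassifier":
        with open(path) as fh:
            d = json.load(fh)
        markers = d["shared_markers"]
        return cls(
            centroids=pd.DataFrame.from_dict(d["centroids"], orient="index")[markers],
            s=pd.Series(d["s"])[markers],
            s0=d["s0"],
            priors=pd.Series(d["priors"]),
            shared_markers=markers,
            delta_threshold=d["delta_threshold"],
            transform_chain=d["transform_chain"],
            cv_accuracy=d.get("cv_accuracy"),
        )


@dataclass
class ClassifiedCatalog:
    labels: np.ndarray  # assigned class or "unclassified"
    posteriors: pd.DataFrame  # cell x class
    delta: np.ndarray  # P(1st) - P(2nd)
    threshold: float
    flags: dict = field(default_factory=dict)

    def fractions(self) -> pd.Series:
        vals, counts = np.unique(self.labels, return_counts=True)
        return pd.Series(counts / len(self.labels), index=vals)


def _posteriors(
    X: np.ndarray, centroids: np.ndarray, s: np.ndarray, s0: float, priors: np.ndarray
) -> np.ndarray:
    scale = (s + s0) ** 2
    d = ((X[:, None, :] - centroids[None, :, :]) ** 2 / scale[None, None, :]).sum(-1)
    d = d - 2.0 * np.log(priors)[None, :]
    logp = -d / 2.0
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def train_centroid_classifier(
    table: CellTable | pd.DataFrame,
    labels,
    shared_markers=None,
    min_prevalence: float = 0.05,
    delta_threshold: float = 0.9,
    priors: str = "training",
    transform_chain: str = "arcsinh_cosine",
    cv_folds: int = 10,
    seed: int = 0,
) -> CentroidClassifier:
    """Fit the nearest-centroid classifier for one model's cells.

    Classes with training prevalence <= ``min_prevalence`` are excluded.
    Shrinkage is disabled, so centroids are the raw class means over the
    shared markers.  A stratified ``cv_folds``-fold training-accuracy
    estimate is reported as a diagnostic.
    """
    if isinstance(table, CellTable):
        markers = shared_markers or table.markers
        X = table.X[:, table.marker_index(markers)]
    else:
        markers = list(shared_markers or table.columns)
        X = table[markers].to_numpy(dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length does not match cell count")

    classes, counts = np.unique(labels, return_counts=True)
    prev = counts / counts.sum()
    gated = classes[prev > min_prevalence]
    if len(gated) < 2:
        raise ValueError(
            f"fewer than 2 classes pass the {min_prevalence:.0%} prevalence gate "
            f"(surviving: {list(gated)})"
        )
    keep = np.isin(labels, gated)
    Xg, yg = X[keep], labels[keep]

    cents = np.vstack([Xg[yg == c].mean(axis=0) for c in gated])
    # pooled within-class sd per marker
    ss = np.zeros(X.shape[1])
    for c in gated:
        xc = Xg[yg == c]
        ss += ((xc - xc.mean(axis=0)) ** 2).sum(axis=0)
    s = np.sqrt(ss / (len(Xg) - len(gated)))
    s = np.maximum(s, 1e-12)
    s0 = float(np.median(s))
    n_by_class = np.array([(yg == c).sum() for c in gated], dtype=float)
    pi = n_by_class / n_by_class.sum() if priors == "training" else np.full(len(gated), 1 / len(gated))

    clf = CentroidClassifier(
        centroids=pd.DataFrame(cents, index=gated, columns=markers),
        s=pd.Series(s, index=markers),
        s0=s0,
        priors=pd.Series(pi, index=gated),
        shared_markers=list(markers),
        delta_threshold=delta_threshold,
        transform_chain=transform_chain,
    )

    # diagnostic cross-validated training accuracy
    folds = min(cv_folds, int(n_by_class.min()))
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        hits = 0
        for tr, te in skf.split(Xg, yg):
            c_tr = np.vstack([Xg[tr][yg[tr] == c].mean(axis=0) for c in gated])
            p = _posteriors(Xg[te], c_tr, s, s0, pi)
            hits += int((gated[p.argmax(axis=1)] == yg[te]).sum())
        clf.cv_accuracy = hits / len(Xg)
    return clf


def classify_cells(
    classifier: CentroidClassifier,
    target: CellTable | pd.DataFrame | np.ndarray,
    delta_threshold: float | None = None,
) -> ClassifiedCatalog:
    """Assign each target cell the max-posterior class, or "unclassified".

    The rejection rule leaves a cell unlabelled when the difference between
    its first and second highest posterior probabilities is below the
    threshold (default: the classifier's stored 0.9).
    """
    thr = classifier.delta_threshold if delta_threshold is None else delta_threshold
    markers = classifier.shared_markers
    if isinstance(target, CellTable):
        X = target.X[:, target.marker_index(markers)]
    elif isinstance(target, pd.DataFrame):
        missing = [m for m in markers if m not in target.columns]
        if missing:
            raise KeyError(f"target table missing shared markers: {missing}")
        X = target[markers].to_numpy(dtype=float)
    else:
        X = np.asarray(target, dtype=float)
        if X.shape[1] != len(markers):
            raise ValueError("target array width does not match shared markers")
    p = _posteriors(
        X,
        classifier.centroids.to_numpy(),
        classifier.s.to_numpy(),
        classifier.s0,
        classifier.priors.to_numpy(),
    )
    order = np.argsort(p, axis=1)
    delta = p[np.arange(len(p)), order[:, -1]] - p[np.arange(len(p)), order[:, -2]]
    classes = np.asarray(classifier.classes, dtype=object)
    labels = classes[p.argmax(axis=1)].copy()
    labels[delta < thr] = "unclassified"
    return ClassifiedCatalog(
        labels=labels,
        posteriors=pd.DataFrame(p, columns=classifier.classes),
        delta=delta,
        threshold=thr,
    )


def centroid_correlation(
    classifier: CentroidClassifier,
    classified: ClassifiedCatalog,
    target: CellTable | pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of test-side vs training-side class centroids.

    Test-side centroids are means over cells assigned to each class.
    Returns the long table of (train_class, test_class, r, matching); the
    matching/non-matching medians are in ``.attrs``.
    """
    markers = classifier.shared_markers
    if isinstance(target, CellTable):
        X = target.X[:, target.marker_index(markers)]
    else:
        X = target[markers].to_numpy(dtype=float)
    rows = []
    skipped = []
    for cls in classifier.classes:
        sel = classified.labels == cls
        if not sel.any():
            skipped.append(cls)
            continue
        test_centroid = X[sel].mean(axis=0)
        for train_cls in classifier.classes:
            r = float(np.corrcoef(test_centroid, classifier.centroids.loc[train_cls])[0, 1])
            rows.append(
                {
                    "test_class": cls,
                    "train_class": train_cls,
                    "r": r,
                    "matching": cls == train_cls,
                }
            )
    if not rows:
        raise ValueError("no class has assigned cells in the target")
    out = pd.DataFrame(rows)
    out.attrs["median_matching"] = float(out.loc[out.matching, "r"].median())
    out.attrs["median_non_matching"] = float(out.loc[~out.matching, "r"].median())
    out.attrs["skipped_classes"] = skipped
    return out


def track_treatment_dynamics(
    classifier: CentroidClassifier, tables_by_dose: dict, control_key=None
) -> pd.DataFrame:
    """Class (+ unclassified) fractions per dose, with change vs control.

    ``tables_by_dose`` maps dose -> CellTable/DataFrame on the classifier's
    shared markers; ``control_key`` defaults to the first key in order.
    """
    keys = list(tables_by_dose)
    control_key = keys[0] if control_key is None else control_key
    cols = list(classifier.classes) + ["unclassified"]
    rows = {}
    for dose, tbl in tables_by_dose.items():
        n = tbl.n_cells if isinstance(tbl, CellTable) else len(tbl)
        if n == 0:
            rows[dose] = pd.Series(0.0, index=cols)
            continue
        frac = classify_cells(classifier, tbl).fractions()
        rows[dose] = frac.reindex(cols).fillna(0.0)
    out = pd.DataFrame(rows).T[cols]
    out.index.name = "dose"
    change = (out - out.loc[control_key]) * 100.0
    out.attrs["percent_change_vs_control"] = change
    out.attrs["control_key"] = control_key
    return out
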