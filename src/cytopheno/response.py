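"""Drug-response AUC computation and compositional regression models.

Raw viability plates are converted to percent response with
``100 - 100 * (I - neg) / (pos - neg)``, fitted with a non-decreasing
isotonic function of log10(dose), and integrated by the trapezoid rule,
normalised so AUC lies in [0, 1] (0 = no response, 1 = complete response
at every dose).

Phenotype compositions enter regression models through additive log-ratios
against a referent phenotype, ``log((p_i + pc) / (p_ref + pc))`` -- the
standard device making proportions valid covariates.  Two models are
provided: an L1-penalised linear model for drug AUC (lambda by k-fold CV,
reported with R^2 and the selected support) and an L1-penalised Cox
proportional-hazards model for survival (lambda by k-fold CV on the
partial-likelihood deviance, Breslow ties), with quartile Kaplan-Meier
curves and a log-rank test on the resulting risk scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LassoCV, Lasso
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .containers import DoseResponsePlate, SurvivalTable


# -- AUC from plates ----------------------------------------------------


def compute_response(plate: DoseResponsePlate, clip: bool = False) -> np.ndarray:
    """Percent response per replicate: 100 - 100*(I - neg)/(pos - neg)."""
    resp = 100.0 - 100.0 * (plate.intensities - plate.neg_control) / (
        plate.pos_control - plate.neg_control
    )
    if clip:
        resp = np.clip(resp, 0.0, 100.0)
    return resp


def compute_auc(plate: DoseResponsePlate, clip_response: bool = False) -> float:
    """Normalised area under the isotonic dose-response fit, in [0, 1].

    Replicates are pooled, a non-decreasing isotonic regression of percent
    response on log10(dose) is fitted, and the trapezoid integral over the
    log-dose range is divided by 100 x range.
    """
    if np.unique(plate.doses).size < 2:
        raise ValueError("need at least 2 distinct doses for an AUC")
    resp = compute_response(plate, clip=clip_response)
    log_dose = np.log10(plate.doses)
    xs = np.repeat(log_dose, resp.shape[1])
    ys = resp.ravel()
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip").fit(xs, ys)
    fit = iso.predict(log_dose)
    span = log_dose[-1] - log_dose[0]
    area = np.trapezoid(fit, log_dose)
    return float(area / (100.0 * span))


def filter_drugs(
    auc_table: pd.DataFrame,
    curve_cluster_flags: pd.DataFrame | None = None,
    min_models: int = 10,
    auc_threshold: float = 0.2,
    max_flagged_frac: float = 1 / 3,
) -> pd.DataFrame:
    """Apply the three drug quality rules; every exclusion carries a reason.

    ``auc_table`` is drug x model (NaN = untested).  ``curve_cluster_flags``
    (same shape, boolean) marks response curves assigned to degenerate
    shape clusters (no response / toxic); drugs with >= ``max_flagged_frac``
    flagged curves are excluded.  Also required: at least ``min_models``
    tested models and both a responder (AUC > threshold) and a resistant
    model (AUC < threshold).
    """
    rows = []
    for drug in auc_table.index:
        auc = auc_table.loc[drug].dropna()
        reasons = []
        if len(auc) < min_models:
            reasons.append("min models")
        if curve_cluster_flags is not None and drug in curve_cluster_flags.index:
            flags = curve_cluster_flags.loc[drug].reindex(auc.index).fillna(False)
            if len(auc) and flags.mean() >= max_flagged_frac:
                reasons.append("33% rule")
        if len(auc) and not (auc > auc_threshold).any():
            reasons.append("no responding model")
        if len(auc) and not (auc < auc_threshold).any():
            reasons.append("no resistant model")
        rows.append(
            {
                "drug": drug,
                "included": not reasons,
                "reason": "; ".join(reasons),
                "n_models": len(auc),
            }
        )
    return pd.DataFrame(rows)


# -- log-ratio design ---------------------------------------------------


@dataclass
class LogRatioDesign:
    matrix: pd.DataFrame  # model x (K-1) log-ratios
    referent: str
    pseudocount: float


def logratio_transform(
    prevalence: pd.DataFrame, referent: str, pseudocount: float | None = None
) -> LogRatioDesign:
    """Additive log-ratios log((p_i + pc)/(p_ref + pc)) against a referent.

    The default pseudocount, 0.5 / 1600, is half a cell at the default
    per-model sampling depth, keeping zero prevalences finite.
    """
    if referent not in prevalence.columns:
        raise ValueError(f"referent {referent!r} not in composition columns")
    pc = 0.5 / 1600 if pseudocount is None else float(pseudocount)
    ref = prevalence[referent].to_numpy(dtype=float) + pc
    cols = {}
    for c in prevalence.columns:
        if c == referent:
            continue
        cols[f"log({c}/{referent})"] = np.log(
            (prevalence[c].to_numpy(dtype=float) + pc) / ref
        )
    mat = pd.DataFrame(cols, index=prevalence.index)
    if not np.isfinite(mat.to_numpy()).all():
        raise ValueError("non-finite log-ratios; check pseudocount and compositions")
    return LogRatioDesign(matrix=mat, referent=referent, pseudocount=pc)


# -- penalised regression -----------------------------------------------


@dataclass
class LassoAUCResult:
    coefficients: pd.Series  # on the original (unstandardised) scale
    intercept: float
    alpha: float
    r2: float
    support: list
    fitted: pd.Series
    cv_folds: int
    warnings: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        df = self.coefficients.to_frame("coef")
        df["selected"] = df["coef"] != 0.0
        return df


def fit_lasso_auc(
    design: LogRatioDesign,
    auc: pd.Series | np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    alpha: float | None = None,
) -> LassoAUCResult:
    """L1-penalised linear regression of AUC on log-ratios.

    Predictors are standardised internally; lambda is chosen at the
    minimum k-fold cross-validation error (``alpha`` overrides the CV
    choice, with ``alpha=0`` giving ordinary least squares).  R^2 is
    between fitted and observed AUC on the full data.
    """
    X = design.matrix.to_numpy(dtype=float)
    y = np.asarray(auc, dtype=float)
    n = len(y)
    warnings_ = []
    folds = n_folds
    if n < n_folds:
        folds = max(2, n // 2)
        warnings_.append(f"n={n} < {n_folds} folds; reduced to {folds}")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    if alpha is None:
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        model = LassoCV(cv=cv, alphas=100, max_iter=50000, random_state=seed).fit(Xs, y)
        chosen = float(model.alpha_)
    else:
        chosen = float(alpha)
        model = Lasso(alpha=max(chosen, 1e-12), max_iter=200000, tol=1e-10).fit(Xs, y)
    coef_std = model.coef_
    fitted = model.predict(Xs)
    ss_res = np.sum((y - fitted) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0
    coefs = pd.Series(coef_std / sd, index=design.matrix.columns)
    index = design.matrix.index if hasattr(auc, "index") else pd.RangeIndex(n)
    return LassoAUCResult(
        coefficients=coefs,
        intercept=float(model.intercept_ - np.sum(coef_std * mu / sd)),
        alpha=chosen,
        r2=r2,
        support=list(coefs.index[coefs != 0.0]),
        fitted=pd.Series(fitted, index=index),
        cv_folds=folds,
        warnings=warnings_,
    )


@dataclass
class CoxCompositionResult:
    coefficients: pd.Series
    alpha: float
    risk_scores: pd.Series  # linear predictor per case
    cv_folds: int
    ties: str = "breslow"

    def summary(self) -> pd.DataFrame:
        df = self.coefficients.to_frame("coef")
        df["selected"] = df["coef"] != 0.0
        return df


def _breslow_log_partial_likelihood(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    order = np.argsort(time)
    lp, time, event = lp[order], time[order], event[order]
    ll = 0.0
    exp_lp = np.exp(lp)
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        d = (time == t) & (event == 1)
        ll += lp[d].sum() - d.sum() * np.log(exp_lp[at_risk].sum())
    return float(ll)


def fit_cox_composition(
    design: LogRatioDesign,
    survival: SurvivalTable,
    n_folds: int = 10,
    seed: int = 0,
) -> CoxCompositionResult:
    """L1-penalised Cox proportional hazards on log-ratios.

    The lambda path comes from an elastic-net Cox solver (pure L1);
    lambda is chosen at the minimum k-fold cross-validated partial-
    likelihood deviance (Breslow ties).  Returns coefficients and the
    per-case linear predictor (risk score).
    """
    y = survival.data
    if (y["event"] == 1).sum() == 0:
        raise ValueError("no events in the survival table")
    X = design.matrix.loc[y["case_id"]].to_numpy(dtype=float)
    time = y["time"].to_numpy(dtype=float)
    event = y["event"].to_numpy(dtype=int)
    surv = Surv.from_arrays(event=event.astype(bool), time=time)

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=50)
    path.fit(X, surv)
    alphas = path.alphas_

    folds = min(n_folds, int(event.sum()))
    folds = max(2, folds)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_dev = np.zeros(len(alphas))
    for tr, te in cv.split(X):
        if event[tr].sum() == 0 or event[te].sum() == 0:
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        m.fit(X[tr], surv[tr])
        for ai, a in enumerate(alphas):
            try:
                lp = m.predict(X[te], alpha=a)
            except ValueError:
                cv_dev[ai] += np.inf
                continue
            cv_dev[ai] += -2.0 * _breslow_log_partial_likelihood(lp, time[te], event[te])
    best = int(np.argmin(cv_dev))
    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
    final.fit(X, surv)
    coef = final.coef_[:, best]
    lp = X @ coef
    return CoxCompositionResult(
        coefficients=pd.Series(coef, index=design.matrix.columns),
        alpha=float(alphas[best]),
        risk_scores=pd.Series(lp, index=y["case_id"]),
        cv_folds=folds,
    )


def quartile_km(risk_scores: pd.Series, survival: SurvivalTable):
    """Quartile-group Kaplan-Meier curves plus a 4-group log-rank test.

    Scores are cut at their quartiles (ties to the lower group); raises on
    fewer than 4 distinct scores (degenerate quartiles).
    """
    scores = pd.Series(risk_scores)
    if scores.nunique() < 4:
        raise ValueError("degenerate quartiles: fewer than 4 distinct risk scores")
    q = scores.quantile([0.25, 0.5, 0.75]).to_numpy()
    groups = np.searchsorted(q, scores.to_numpy(), side="left")  # ties to lower
    y = survival.data.set_index("case_id").loc[scores.index]
    time = y["time"].to_numpy(dtype=float)
    event = y["event"].to_numpy(dtype=int)
    curves = {}
    for g in range(4):
        sel = groups == g
        kmf = KaplanMeierFitter(label=f"Q{g + 1}")
        if sel.any():
            kmf.fit(time[sel], event[sel])
        curves[f"Q{g + 1}"] = kmf
    lr = multivariate_logrank_test(time, groups, event)
    return curves, float(lr.test_statistic), float(lr.p_value)
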