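"""Group-level statistics on aligned gradients.

Covers network aggregation of gradient scores, ROI/network-wise group
comparisons with Benjamini–Hochberg FDR control, linear-SVM
classification of network gradient features with ROC/AUC, and
covariate-controlled (partial) Pearson correlation between
treatment-induced gradient change and clinical motor improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .gradients import GradientSet

__all__ = [
    "CANONICAL_NETWORKS",
    "NetworkPartition",
    "SubjectRecord",
    "StatResult",
    "ClassifierReport",
    "CorrelationResult",
    "network_scores",
    "roiwise_compare",
    "fdr_bh",
    "classify",
    "delta_features",
    "delta_clinical",
    "partial_correlation",
]

# Yeo 7-network scheme used by the Schaefer parcellation
CANONICAL_NETWORKS = ("VIS", "SMN", "DAN", "VAN", "LIB", "FPN", "DMN")


@dataclass
class NetworkPartition:
    """Assignment of each ROI to one canonical network."""

    assignment: Mapping[str, str]
    labels: tuple[str, ...] = CANONICAL_NETWORKS

    def __post_init__(self) -> None:
        self.assignment = dict(self.assignment)
        self.labels = tuple(self.labels)
        unknown = set(self.assignment.values()) - set(self.labels)
        if unknown:
            raise ValueError(f"networks not in label set: {sorted(unknown)}")
        present = set(self.assignment.values())
        missing = [l for l in self.labels if l not in present]
        if missing:
            raise ValueError(f"networks with no ROI: {missing}")

    def networks_for(self, roi_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.asarray([self.assignment[r] for r in roi_ids])
        except KeyError as e:
            raise ValueError(f"ROI {e.args[0]!r} has no network assignment") from None


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # control | patient
    age: float
    sex: int
    updrs3_pre: float | None = None
    updrs3_post: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.group == "patient" and (self.updrs3_pre is None or self.updrs3_post is None):
            raise ValueError(f"patient {self.subject_id} lacks UPDRS-III entries")


@dataclass
class StatResult:
    """Per-unit t statistics with raw and FDR-adjusted p values."""

    table: pd.DataFrame  # unit, t, p, p_fdr, reject, direction, degenerate
    test_kind: str  # independent | paired
    q: float


@dataclass
class ClassifierReport:
    feature_set: str  # FCG1 | STG1 | combined
    accuracy: float
    auc: float
    roc_points: np.ndarray  # (fpr, tpr) rows
    cv_scheme: str


@dataclass
class CorrelationResult:
    network: str
    r: float
    p: float
    n: int
    covariates: tuple[str, ...]


# ---------------------------------------------------------------------------
# Network aggregation
# ---------------------------------------------------------------------------

def network_scores(
    gs: GradientSet,
    part: NetworkPartition,
    component: int = 0,
) -> pd.Series:
    """Mean gradient score per network for one embedding component."""
    nets = part.networks_for(gs.roi_ids)
    s = pd.Series(gs.scores[:, component], index=nets)
    means = s.groupby(level=0).mean()
    empty = [l for l in part.labels if l not in means.index]
    if empty:
        raise ValueError(f"networks with no ROI in this gradient set: {empty}")
    return means.reindex(list(part.labels))


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def roiwise_compare(
    group_a: np.ndarray,
    group_b: np.ndarray,
    paired: bool = False,
    q: float = 0.05,
    unit_ids: Sequence[str] | None = None,
) -> StatResult:
    """Per-ROI two-sided t tests (Welch when independent) with BH-FDR.

    Degenerate ROIs (zero variance) are flagged rather than producing
    infinities: identical groups give t = 0, p = 1 by convention; a
    constant non-zero paired difference is flagged ``degenerate`` with
    NaN statistics and is excluded from the FDR family.
    """
    A = np.atleast_2d(np.asarray(group_a, float))
    B = np.atleast_2d(np.asarray(group_b, float))
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValueError("need at least 3 subjects per group")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must cover the same ROIs")
    n_units = A.shape[1]
    degenerate = np.zeros(n_units, dtype=bool)
    if paired:
        if A.shape[0] != B.shape[0]:
            raise ValueError("paired comparison requires equal, matched groups")
        d = A - B
        sd = d.std(axis=0, ddof=1)
        zero_var = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            res = sps.ttest_rel(A, B, axis=0)
        t, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
        # zero difference everywhere: no evidence, t=0/p=1 by convention
        both = zero_var & (np.abs(d.mean(axis=0)) < 1e-300)
        t[both], p[both] = 0.0, 1.0
        # constant non-zero difference: flagged degenerate, excluded from FDR
        degenerate = zero_var & ~both
        t[degenerate] = np.nan
        p[degenerate] = np.nan
        kind = "paired"
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = sps.ttest_ind(A, B, axis=0, equal_var=False)
        t, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
        zero_var = (A.std(axis=0, ddof=1) == 0) & (B.std(axis=0, ddof=1) == 0)
        same_mean = zero_var & (np.abs(A.mean(axis=0) - B.mean(axis=0)) < 1e-300)
        t[same_mean], p[same_mean] = 0.0, 1.0
        degenerate = zero_var & ~same_mean
        t[degenerate] = np.nan
        p[degenerate] = np.nan
        kind = "independent"

    p_fdr = np.full(n_units, np.nan)
    reject = np.zeros(n_units, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        p_adj, rej = fdr_bh(p[ok], q=q)
        p_fdr[ok] = p_adj
        reject[ok] = rej
    units = list(unit_ids) if unit_ids is not None else [str(i) for i in range(n_units)]
    table = pd.DataFrame(
        {
            "unit": units,
            "t": t,
            "p": p,
            "p_fdr": p_fdr,
            "reject": reject,
            "direction": np.where(np.isnan(t), "", np.where(t > 0, "A>B", np.where(t < 0, "A<B", "="))),
            "degenerate": degenerate,
        }
    )
    return StatResult(table=table, test_kind=kind, q=q)


def fdr_bh(pvals: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (adjusted p values, rejection mask)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify(
    features: pd.DataFrame,
    labels: Sequence[int],
    feature_set: str = "combined",
    n_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> ClassifierReport:
    """Linear-SVM discrimination of patients from controls.

    Features are standardized inside each training fold only (leak-free
    via a scaler+SVM pipeline under cross_val_predict). Accuracy is the
    pooled out-of-fold correct fraction; the ROC/AUC come from pooled
    out-of-fold decision values over a stratified k-fold with a fixed
    shuffle seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree on n_subjects")
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"class with {counts.min()} subjects cannot fill {n_folds} folds; use fewer folds"
        )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
    pred = cross_val_predict(model, X, y, cv=cv)
    decision = cross_val_predict(model, X, y, cv=cv, method="decision_function")
    accuracy = float(np.mean(pred == y))
    auc = float(roc_auc_score(y, decision))
    fpr, tpr, _ = roc_curve(y, decision)
    return ClassifierReport(
        feature_set=feature_set,
        accuracy=accuracy,
        auc=auc,
        roc_points=np.column_stack([fpr, tpr]),
        cv_scheme=f"stratified {n_folds}-fold, shuffled, seed={seed}",
    )


# ---------------------------------------------------------------------------
# Treatment-change features and partial correlation
# ---------------------------------------------------------------------------

def delta_features(
    pre: GradientSet,
    post: GradientSet,
    part: NetworkPartition,
    component: int = 0,
) -> pd.Series:
    """Per-network gradient change |pre score| - |post score| for one subject."""
    if pre.roi_ids != post.roi_ids:
        raise ValueError("pre and post gradient sets cover different ROIs")
    s_pre = network_scores(pre, part, component)
    s_post = network_scores(post, part, component)
    return s_pre.abs() - s_post.abs()


def delta_clinical(rec: SubjectRecord) -> float:
    """Clinical motor improvement: UPDRS-III pre minus post (positive = better)."""
    if rec.updrs3_pre is None or rec.updrs3_post is None:
        raise ValueError(f"subject {rec.subject_id} is missing a session score")
    return float(rec.updrs3_pre - rec.updrs3_post)


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
    covariate_names: Sequence[str] = ("age", "sex"),
    network: str = "",
) -> CorrelationResult:
    """Pearson correlation of x and y after residualizing both on covariates.

    Both variables are regressed on [intercept, covariates] by least
    squares; r is the Pearson correlation of the residuals and the
    two-sided p value uses df = n - 2 - n_covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        Z = np.empty((n, 0))
        covariate_names = ()
    else:
        Z = np.atleast_2d(np.asarray(covariates, float))
        if Z.shape[0] != n:
            Z = Z.T
    n_cov = Z.shape[1]
    if n <= n_cov + 2:
        raise ValueError("need n > n_covariates + 2 observations")
    X = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank deficient")
    coef_x, *_ = np.linalg.lstsq(X, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    rx = x - X @ coef_x
    ry = y - X @ coef_y
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        raise ValueError("zero residual variance; correlation undefined")
    r = float(np.sum(rx * ry) / denom)
    r = max(-1.0, min(1.0, r))
    df = n - 2 - n_cov
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(
        network=network, r=r, p=p, n=n, covariates=tuple(covariate_names)
    )
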