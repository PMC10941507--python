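"""Connectome gradients by diffusion-map embedding.

A connectome row describes how one ROI connects to every other ROI.
Rows are sparsified (top 10% of entries kept), converted to a cosine
similarity affinity matrix, and embedded with a diffusion map using
anisotropic normalization alpha = 0.5 — the setting that balances the
influence of sampling density and retains the global relations between
ROIs. The principal component of the embedding (largest eigenvalue) is
the principal gradient: a continuous sensorimotor-to-association axis
along which ROIs with similar connectivity profiles receive similar
scores. Subject-level gradient sets are made comparable by iterative
Procrustes rotation onto a common template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import eigh, svd
from scipy.sparse.csgraph import connected_components

from .connectomes import ConnectivityMatrix

__all__ = [
    "AffinityMatrix",
    "GradientSet",
    "AlignmentResult",
    "sparsify_rows",
    "cosine_affinity",
    "diffusion_map",
    "procrustes_align",
    "gradient_span",
    "select_principal",
    "orient_reference",
    "orient_to_reference",
]

DEFAULT_SPARSITY_KEEP = 0.10
DEFAULT_ALPHA = 0.5
DEFAULT_N_COMPONENTS = 10


@dataclass
class AffinityMatrix:
    values: np.ndarray
    sparsity_used: float
    source_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("affinity must be symmetric within 1e-10")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("affinity entries must lie in [0, 1]")
        if np.any(np.diag(self.values) <= 0):
            raise ValueError("affinity diagonal must be positive")


@dataclass
class GradientSet:
    """R×k embedding scores with eigenvalues and explained ratios."""

    scores: np.ndarray
    eigenvalues: np.ndarray
    explained_ratio: np.ndarray
    alpha: float = DEFAULT_ALPHA
    diffusion_time: float = 0.0
    aligned: bool = False
    roi_ids: tuple[str, ...] = ()
    subject_id: str = ""
    session: str = ""
    kind: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.explained_ratio = np.asarray(self.explained_ratio, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("gradient scores must be finite")
        if np.any(np.diff(self.explained_ratio) > 1e-12):
            raise ValueError("explained ratios must be non-increasing")
        if self.explained_ratio.sum() > 1 + 1e-9:
            raise ValueError("explained ratios must sum to <= 1")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def with_scores(self, scores: np.ndarray, aligned: bool | None = None) -> "GradientSet":
        return GradientSet(
            scores=scores,
            eigenvalues=self.eigenvalues,
            explained_ratio=self.explained_ratio,
            alpha=self.alpha,
            diffusion_time=self.diffusion_time,
            aligned=self.aligned if aligned is None else aligned,
            roi_ids=self.roi_ids,
            subject_id=self.subject_id,
            session=self.session,
            kind=self.kind,
        )


@dataclass
class AlignmentResult:
    rotations: list[np.ndarray]
    reference: np.ndarray
    iterations_run: int
    discrepancy_per_iteration: list[float]


# ---------------------------------------------------------------------------
# Affinity construction
# ---------------------------------------------------------------------------

def sparsify_rows(
    m: ConnectivityMatrix | np.ndarray,
    keep_fraction: float = DEFAULT_SPARSITY_KEEP,
) -> np.ndarray:
    """Keep the top ``keep_fraction`` of each row's off-diagonal entries.

    Negative entries are zeroed first; ties are broken toward the lower
    column index for determinism; the diagonal is excluded from ranking
    and returned as zero. Each row keeps exactly ceil(f*(R-1)) entries.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    values = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
    R = values.shape[0]
    W = np.maximum(values, 0.0)
    n_keep = math.ceil(keep_fraction * (R - 1))
    out = np.zeros_like(W)
    cols = np.arange(R)
    for i in range(R):
        row = W[i].copy()
        row[i] = -np.inf  # exclude diagonal from ranking
        # descending by value, ascending column index among ties
        order = np.lexsort((cols, -row))
        keep = order[:n_keep]
        out[i, keep] = W[i, keep]
    np.fill_diagonal(out, 0.0)
    return out


def cosine_affinity(
    rows: np.ndarray,
    sparsity_used: float = DEFAULT_SPARSITY_KEEP,
    source_kind: str = "functional",
    roi_ids: Sequence[str] | None = None,
) -> AffinityMatrix:
    """Cosine similarity between connectivity rows, clipped to [0, 1]."""
    rows = np.asarray(rows, dtype=float)
    norms = np.linalg.norm(rows, axis=1)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        names = (
            ", ".join(roi_ids[i] for i in dead[:5])
            if roi_ids is not None
            else ", ".join(map(str, dead[:5]))
        )
        raise ValueError(f"all-zero connectivity row(s) for ROI(s): {names}")
    unit = rows / norms[:, None]
    C = unit @ unit.T
    C = np.clip(C, 0.0, 1.0)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return AffinityMatrix(values=C, sparsity_used=sparsity_used, source_kind=source_kind)


# ---------------------------------------------------------------------------
# Diffusion embedding
# ---------------------------------------------------------------------------

def diffusion_map(
    aff: AffinityMatrix | np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    diffusion_time: float = 0.0,
    n_components: int = DEFAULT_N_COMPONENTS,
    roi_ids: Sequence[str] | None = None,
    subject_id: str = "",
    session: str = "",
    kind: str = "",
) -> GradientSet:
    """Diffusion-map embedding of a symmetric non-negative affinity.

    The affinity W is density-normalized, W' = D^-a W D^-a with
    D = diag(row sums), and the Markov operator P = row-normalized W'
    is eigendecomposed through its symmetric conjugate. The trivial
    constant eigenvector (eigenvalue 1) is dropped; component c is
    psi_c scaled by lambda_c^t, where t = 0 requests the multiscale
    scaling lambda_c / (1 - lambda_c). The explained ratio of a
    component is its eigenvalue's share of the retained eigenvalue
    mass. Components are ordered by eigenvalue, descending.
    """
    W = aff.values if isinstance(aff, AffinityMatrix) else np.asarray(aff, float)
    source_kind = aff.source_kind if isinstance(aff, AffinityMatrix) else kind
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if W.min() < 0:
        raise ValueError("affinity must be non-negative")
    n_comp_graph, labels = connected_components(W > 0, directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"affinity graph is disconnected (component sizes {sizes})")

    R = W.shape[0]
    d = W.sum(axis=1)
    W1 = W / np.outer(d**alpha, d**alpha)
    d1 = W1.sum(axis=1)
    # symmetric conjugate of the Markov operator P = D1^-1 W1
    M = W1 / np.sqrt(np.outer(d1, d1))
    M = (M + M.T) / 2.0
    evals, evecs = eigh(M)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # map back to right eigenvectors of P; column 0 is the constant vector
    psi = evecs / np.sqrt(d1)[:, None]
    psi = psi / np.linalg.norm(psi, axis=0)
    k = min(n_components, R - 1)
    lam = evals[1 : k + 1]
    comps = psi[:, 1 : k + 1]
    lam = np.clip(lam, None, 1.0 - 1e-12)
    if diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam**diffusion_time
    scores = comps * scale
    lam_pos = np.maximum(lam, 0.0)
    explained = lam_pos / lam_pos.sum() if lam_pos.sum() > 0 else lam_pos
    return GradientSet(
        scores=scores,
        eigenvalues=lam,
        explained_ratio=explained,
        alpha=alpha,
        diffusion_time=diffusion_time,
        aligned=False,
        roi_ids=tuple(roi_ids) if roi_ids is not None else (),
        subject_id=subject_id,
        session=session,
        kind=source_kind,
    )


# ---------------------------------------------------------------------------
# Sign conventions
# ---------------------------------------------------------------------------

def orient_reference(
    gs: GradientSet,
    roi_networks: Sequence[str],
    high_network: str = "DMN",
    low_network: str = "VIS",
) -> GradientSet:
    """Fix component signs of a template so gradients run primary → association.

    Each component is flipped, if needed, so the mean score of the
    designated association network exceeds that of the designated
    primary (visual) network.
    """
    nets = np.asarray(roi_networks)
    hi = nets == high_network
    lo = nets == low_network
    if not hi.any() or not lo.any():
        raise ValueError("high/low networks absent from roi_networks")
    scores = gs.scores.copy()
    for c in range(scores.shape[1]):
        if scores[hi, c].mean() < scores[lo, c].mean():
            scores[:, c] = -scores[:, c]
    return gs.with_scores(scores)


def orient_to_reference(gs: GradientSet, reference: np.ndarray) -> GradientSet:
    """Flip each component whose correlation with the reference is negative."""
    reference = np.asarray(reference, dtype=float)
    scores = gs.scores.copy()
    for c in range(scores.shape[1]):
        if np.dot(scores[:, c] - scores[:, c].mean(), reference[:, c] - reference[:, c].mean()) < 0:
            scores[:, c] = -scores[:, c]
    return gs.with_scores(scores)


# ---------------------------------------------------------------------------
# Procrustes alignment
# ---------------------------------------------------------------------------

def procrustes_align(
    sets: Sequence[GradientSet],
    reference: np.ndarray | None = None,
    n_iter: int = 10,
    tol: float = 1e-8,
) -> tuple[list[GradientSet], AlignmentResult]:
    """Iteratively rotate every gradient set onto a shared template.

    Alternating minimization of sum_i ||S_i Q_i - ref||_F^2: each subject
    gets the orthogonal rotation from the SVD of S_i^T ref, then the
    reference is refreshed as the element-wise mean of aligned sets.
    The initial reference defaults to the first set (callers pass a
    group-average template). Stops after ``n_iter`` rounds or when the
    discrepancy improves by less than ``tol``.
    """
    if not sets:
        raise ValueError("no gradient sets to align")
    shapes = {gs.scores.shape for gs in sets}
    if len(shapes) != 1:
        raise ValueError(f"gradient sets have mismatched shapes: {sorted(shapes)}")
    mats = [gs.scores for gs in sets]
    ref = np.asarray(reference, float).copy() if reference is not None else mats[0].copy()
    if ref.shape != mats[0].shape:
        raise ValueError("reference shape does not match gradient sets")

    rotations = [np.eye(ref.shape[1]) for _ in mats]
    aligned = [m.copy() for m in mats]
    discrepancies: list[float] = []
    iterations = 0
    for _ in range(n_iter):
        iterations += 1
        for i, m in enumerate(mats):
            U, _, Vt = svd(m.T @ ref)
            Q = U @ Vt
            rotations[i] = Q
            aligned[i] = m @ Q
        ref = np.mean(aligned, axis=0)
        disc = float(sum(np.sum((a - ref) ** 2) for a in aligned))
        discrepancies.append(disc)
        if len(discrepancies) >= 2 and discrepancies[-2] - disc < tol:
            break
    aligned_sets = [gs.with_scores(a, aligned=True) for gs, a in zip(sets, aligned)]
    result = AlignmentResult(
        rotations=rotations,
        reference=ref,
        iterations_run=iterations,
        discrepancy_per_iteration=discrepancies,
    )
    return aligned_sets, result


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def gradient_span(scores: np.ndarray, roi_subset: Sequence[int] | None = None) -> float:
    """Range (max - min) of one component's scores, optionally over a subset."""
    scores = np.asarray(scores, dtype=float)
    if roi_subset is not None:
        idx = np.asarray(roi_subset)
        if idx.size == 0:
            raise ValueError("empty ROI subset")
        scores = scores[idx]
    if scores.size == 0:
        raise ValueError("no scores")
    return float(scores.max() - scores.min())


def select_principal(gs: GradientSet) -> tuple[int, "pd.DataFrame"]:
    """Principal component index (0 = largest eigenvalue) plus a scree table."""
    import pandas as pd

    if gs.n_components < 1:
        raise ValueError("gradient set has no components")
    report = pd.DataFrame(
        {
            "component": np.arange(1, gs.n_components + 1),
            "eigenvalue": gs.eigenvalues,
            "explained_ratio": gs.explained_ratio,
        }
    )
    return 0, report
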