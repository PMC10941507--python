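"""Subject-level connectome construction.

Two connectome kinds are built from pre-parcellated data:

* **functional** — Fisher-Z transformed Pearson correlation between ROI
  time series, optionally residualized for age/sex across subjects;
* **structural_kl** — symmetric Kullback–Leibler divergence between the
  per-ROI probability densities of vertex-wise cortical surface-area
  values (a morphometric-similarity connectome: small divergence means
  similar cortical morphology).

Densities are Gaussian kernel density estimates evaluated on a single
common grid per subject, floored at a small positive mass so the KL sum
is always finite, and renormalized to unit total mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ParcellatedTimeSeries",
    "VertexAreaTable",
    "DiscreteDensity",
    "ConnectivityMatrix",
    "functional_connectome",
    "regress_confounds",
    "estimate_density",
    "kl_divergence",
    "symmetric_kl",
    "structural_connectome",
    "silverman_bandwidth",
    "common_grid",
]

FISHER_Z_CLIP = 1.0 - 1e-7
DENSITY_FLOOR = 1e-12
GRID_POINTS = 256


@dataclass
class ParcellatedTimeSeries:
    """One subject-session's T×R ROI time-series matrix."""

    subject_id: str
    session: str  # control | pre | post
    data: np.ndarray
    roi_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_ids = tuple(self.roi_ids)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D (T x R) array")
        if self.data.shape[0] < 3:
            raise ValueError("need at least 3 time points")
        if self.data.shape[1] != len(self.roi_ids):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.roi_ids)} roi_ids"
            )
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("roi_ids must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]


@dataclass
class VertexAreaTable:
    """Per-ROI lists of vertex surface-area values (mm²) for one session."""

    subject_id: str
    session: str
    areas: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for roi, vals in self.areas.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size < 2:
                raise ValueError(f"ROI {roi!r} has fewer than 2 vertices")
            if np.any(arr <= 0):
                raise ValueError(f"ROI {roi!r} has non-positive vertex areas")
            clean[str(roi)] = arr
        self.areas = clean

    @property
    def roi_ids(self) -> tuple[str, ...]:
        return tuple(self.areas.keys())


@dataclass
class DiscreteDensity:
    """A probability mass function on an ordered evaluation grid (mm²)."""

    grid: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.grid.shape != self.mass.shape or self.grid.ndim != 1:
            raise ValueError("grid and mass must be 1-D arrays of equal length")
        if np.any(self.mass <= 0):
            raise ValueError("mass must be strictly positive (floored)")
        if abs(float(self.mass.sum()) - 1.0) > 1e-12:
            raise ValueError("mass must sum to 1 within 1e-12")


@dataclass
class ConnectivityMatrix:
    """R×R symmetric connectome, functional (Fisher-Z) or structural (KL)."""

    values: np.ndarray
    kind: str  # "functional" | "structural_kl"
    roi_ids: tuple[str, ...]
    subject_id: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_ids = tuple(self.roi_ids)
        r = len(self.roi_ids)
        if self.values.shape != (r, r):
            raise ValueError("values must be R x R matching roi_ids")
        if self.kind not in ("functional", "structural_kl"):
            raise ValueError(f"unknown connectome kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric within 1e-10")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if self.kind == "structural_kl" and np.any(self.values < -1e-12):
            raise ValueError("structural KL entries must be non-negative")

    @property
    def n_roi(self) -> int:
        return len(self.roi_ids)


# ---------------------------------------------------------------------------
# Functional connectome
# ---------------------------------------------------------------------------

def functional_connectome(ts: ParcellatedTimeSeries) -> ConnectivityMatrix:
    """Fisher-Z Pearson functional connectivity with zeroed diagonal.

    Correlations are clipped to |r| <= 1 - 1e-7 before atanh so the
    matrix stays finite for the downstream cosine-affinity step.
    """
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.roi_ids[i] for i in dead[:5])
        raise ValueError(f"zero-variance time series for ROI(s): {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip(r, -FISHER_Z_CLIP, FISHER_Z_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # remove float asymmetry from corrcoef
    return ConnectivityMatrix(
        values=z, kind="functional", roi_ids=ts.roi_ids,
        subject_id=ts.subject_id, session=ts.session,
    )


def regress_confounds(
    matrices: Sequence[ConnectivityMatrix],
    age: Sequence[float],
    sex: Sequence[float],
) -> list[ConnectivityMatrix]:
    """Remove age/sex effects from every edge across subjects by OLS.

    Each edge is regressed on [intercept, age, sex] across the supplied
    matrices; the returned value is residual + intercept, so the grand
    mean is preserved while covariate effects are removed. Symmetry and
    the zero diagonal are preserved exactly (the diagonal edge is all
    zeros, hence fitted and residualized to zero).
    """
    if len(matrices) < 3:
        raise ValueError("need at least 3 subjects for confound regression")
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if len(age) != len(matrices) or len(sex) != len(matrices):
        raise ValueError("age/sex must match the number of matrices")
    roi_ids = matrices[0].roi_ids
    kind = matrices[0].kind
    for m in matrices:
        if m.roi_ids != roi_ids:
            raise ValueError("all matrices must share roi_ids")
    X = np.column_stack([np.ones_like(age), age, sex])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank deficient (constant age or sex?)")
    Y = np.stack([m.values.ravel() for m in matrices])  # n_subj x R^2
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid + beta[0]  # add intercept back
    result = []
    for m, row in zip(matrices, out):
        vals = row.reshape(m.values.shape)
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 0.0)
        result.append(
            ConnectivityMatrix(vals, kind, roi_ids, m.subject_id, m.session)
        )
    return result


# ---------------------------------------------------------------------------
# Densities and KL divergence
# ---------------------------------------------------------------------------

def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman-rule Gaussian KDE bandwidth (scipy's factor, 1-D)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1)
    factor = (n * 3.0 / 4.0) ** (-1.0 / 5.0)
    return float(sd * factor)


def common_grid(
    pooled_values_by_roi: Mapping[str, np.ndarray],
    n_points: int = GRID_POINTS,
) -> np.ndarray:
    """Shared evaluation grid spanning [min - 3h, max + 3h] of pooled values.

    h is the largest Silverman bandwidth over ROIs, so every ROI's kernel
    mass is essentially contained in the grid.
    """
    all_vals = np.concatenate([np.asarray(v, float) for v in pooled_values_by_roi.values()])
    h = max(silverman_bandwidth(v) for v in pooled_values_by_roi.values())
    if h <= 0:
        h = 1e-3 * float(np.mean(all_vals))
    return np.linspace(all_vals.min() - 3 * h, all_vals.max() + 3 * h, n_points)


def estimate_density(
    values: np.ndarray,
    grid: np.ndarray,
    floor: float = DENSITY_FLOOR,
) -> DiscreteDensity:
    """Gaussian-KDE probability masses on a shared grid, floored and renormalized.

    Identical input values make the Silverman bandwidth degenerate; in
    that case a bandwidth of 1e-3 x mean(value) is substituted with a
    warning rather than failing the whole subject.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a density estimate")
    if values.min() < grid.min() or values.max() > grid.max():
        raise ValueError("grid does not cover the value range")
    if values.std() == 0:
        bw = 1e-3 * float(values.mean())
        warnings.warn(
            "identical vertex areas: falling back to bandwidth 1e-3*mean",
            RuntimeWarning,
            stacklevel=2,
        )
        dens = np.exp(-0.5 * ((grid - values[0]) / bw) ** 2)
    else:
        kde = sps.gaussian_kde(values, bw_method="silverman")
        dens = kde(grid)
    dens = np.maximum(dens, 0.0)
    total = dens.sum()
    if total <= 0:
        raise ValueError("degenerate density estimate (zero total mass)")
    mass = np.maximum(dens / total, floor)
    mass = mass / mass.sum()
    return DiscreteDensity(grid=grid, mass=mass)


def _check_grids(f1: DiscreteDensity, f2: DiscreteDensity) -> None:
    if f1.grid.shape != f2.grid.shape or not np.allclose(f1.grid, f2.grid):
        raise ValueError("densities are not on the same grid")


def kl_divergence(f1: DiscreteDensity, f2: DiscreteDensity) -> float:
    """KL(f1 || f2) = sum f1 * log(f1/f2) in nats over the shared grid."""
    _check_grids(f1, f2)
    return float(np.sum(f1.mass * (np.log(f1.mass) - np.log(f2.mass))))


def symmetric_kl(f1: DiscreteDensity, f2: DiscreteDensity) -> float:
    """Symmetrized KL divergence: mean of the two directions."""
    return 0.5 * (kl_divergence(f1, f2) + kl_divergence(f2, f1))


def structural_connectome(
    vt: VertexAreaTable,
    roi_ids: Sequence[str] | None = None,
    n_points: int = GRID_POINTS,
    floor: float = DENSITY_FLOOR,
) -> ConnectivityMatrix:
    """Symmetric-KL morphometric connectome from vertex surface areas.

    All ROI densities are evaluated on one subject-wide common grid, so
    the R×R divergence matrix reduces to products of shared density
    vectors: KL(f_i || f_k) = sum f_i log f_i - sum f_i log f_k.
    """
    if roi_ids is None:
        roi_ids = vt.roi_ids
    roi_ids = tuple(roi_ids)
    missing = [r for r in roi_ids if r not in vt.areas]
    if missing:
        raise ValueError(f"missing ROI(s) in vertex-area table: {', '.join(missing[:5])}")
    grid = common_grid({r: vt.areas[r] for r in roi_ids}, n_points=n_points)
    F = np.stack([estimate_density(vt.areas[r], grid, floor=floor).mass for r in roi_ids])
    logF = np.log(F)
    self_term = np.sum(F * logF, axis=1)  # sum f_i log f_i per ROI
    A = self_term[:, None] - F @ logF.T  # A[i,k] = KL(f_i || f_k)
    S = 0.5 * (A + A.T)
    S = np.maximum(S, 0.0)  # clip -1e-12-scale rounding
    np.fill_diagonal(S, 0.0)
    return ConnectivityMatrix(
        values=S, kind="structural_kl", roi_ids=roi_ids,
        subject_id=vt.subject_id, session=vt.session,
    )
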