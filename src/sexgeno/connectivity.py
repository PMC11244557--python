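"""Voxelwise functional-connectivity maps.

Three per-subject maps over a common brain mask:

* global — weighted degree centrality: for each voxel, the mean
  Fisher-z-transformed Pearson correlation with every other in-mask voxel;
* local — the same restricted to voxels within a fixed Euclidean radius
  (in voxel units, default 6);
* seed — Fisher z of the correlation between each voxel and the mean time
  course of a small seed block (default 3x3x1 voxels).

Correlations are clipped to |r| <= R_MAX = 1 - 1e-7 before atanh so z stays
finite.  Zero-variance voxels are excluded from target sets and flagged NaN
in the output.  Averaging is done on the z scale by default (``average_domain
= "z"``); averaging raw r before transforming is available via ``"r"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preproc import BoldSeries

log = logging.getLogger(__name__)

#: correlation clip ceiling applied before the r-to-z transform
R_MAX = 1.0 - 1e-7
#: largest attainable z value under clipping
Z_MAX = float(np.arctanh(R_MAX))


@dataclass
class ConnectivityMap:
    """Per-subject 3D connectivity map (NaN outside the mask)."""

    data: np.ndarray
    kind: str  # "global" | "local" | "seed"
    mask: np.ndarray
    subject_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise ValueError("map and mask shapes differ")

    def in_mask(self) -> np.ndarray:
        return self.data[self.mask]


@dataclass
class SeedSpec:
    """Seed voxel block: center plus half-extent per axis (default 3x3x1)."""

    center: tuple[int, int, int]
    extent: tuple[int, int, int] = (3, 3, 1)
    label: str = "seed"

    def voxels(self, shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
        """Index arrays of the block; raises if it leaves the volume."""
        slices = []
        for c, e, n in zip(self.center, self.extent, shape):
            if e < 1:
                raise ValueError("seed extents must be >= 1")
            # even extents are anchored with the extra voxel on the high side
            lo = c - (e - 1) // 2
            hi = lo + e
            if lo < 0 or hi > n:
                raise ValueError(f"seed block {self.label} outside volume (axis bound {n})")
            slices.append(slice(lo, hi))
        idx = np.zeros(shape, dtype=bool)
        idx[tuple(slices)] = True
        return np.nonzero(idx)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing r-to-z transform with clipping at |r| = R_MAX."""
    return np.arctanh(np.clip(r, -R_MAX, R_MAX))


def _standardize(b: BoldSeries) -> tuple[np.ndarray, np.ndarray]:
    """Return (Z, ok): row-standardized in-mask series and valid-voxel flags.

    Rows of Z for zero-variance voxels are zero; ok marks voxels with
    positive temporal variance.
    """
    Y = b.in_mask().astype(np.float64)
    Y = Y - Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1)
    ok = sd > 0
    Z = np.zeros_like(Y)
    Z[ok] = Y[ok] / sd[ok, None]
    return Z, ok


def _pairwise_corr(Z: np.ndarray, t: int) -> np.ndarray:
    return (Z @ Z.T) / t


def global_connectivity(b: BoldSeries, average_domain: str = "z") -> ConnectivityMap:
    """Weighted degree centrality: mean (z-transformed) correlation to all voxels."""
    if average_domain not in ("z", "r"):
        raise ValueError("average_domain must be 'z' or 'r'")
    Z, ok = _standardize(b)
    n_ok = int(ok.sum())
    if n_ok < 2:
        raise ValueError("need at least 2 in-mask voxels with nonzero variance")
    if (~ok).any():
        log.info("global_connectivity: %d zero-variance voxels flagged NaN", int((~ok).sum()))
    R = _pairwise_corr(Z[ok], b.n_timepoints)
    vals = fisher_z(R) if average_domain == "z" else R
    # mean over others: row sum minus the diagonal (self term)
    mean_other = (vals.sum(axis=1) - np.diag(vals)) / (n_ok - 1)
    if average_domain == "r":
        mean_other = fisher_z(mean_other)
    flat = np.full(ok.shape, np.nan)
    flat[ok] = mean_other
    out = np.full(b.mask.shape, np.nan)
    out[b.mask] = flat
    return ConnectivityMap(out, "global", b.mask, b.subject_id,
                           {"average_domain": average_domain})


def local_connectivity(
    b: BoldSeries, radius_vox: int = 6, average_domain: str = "z"
) -> ConnectivityMap:
    """Degree centrality restricted to a sphere of ``radius_vox`` voxels."""
    if radius_vox < 1:
        raise ValueError("radius_vox must be >= 1")
    if average_domain not in ("z", "r"):
        raise ValueError("average_domain must be 'z' or 'r'")
    Z, ok = _standardize(b)
    coords = np.argwhere(b.mask).astype(float)
    n_ok = int(ok.sum())
    if n_ok < 2:
        raise ValueError("need at least 2 in-mask voxels with nonzero variance")
    c_ok = coords[ok]
    d2 = ((c_ok[:, None, :] - c_ok[None, :, :]) ** 2).sum(axis=2)
    neigh = (d2 <= radius_vox**2) & ~np.eye(n_ok, dtype=bool)
    R = _pairwise_corr(Z[ok], b.n_timepoints)
    vals = fisher_z(R) if average_domain == "z" else R
    counts = neigh.sum(axis=1)
    sums = np.where(neigh, vals, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_neigh = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if average_domain == "r":
        mean_neigh = np.where(np.isnan(mean_neigh), np.nan, fisher_z(mean_neigh))
    flat = np.full(ok.shape, np.nan)
    flat[ok] = mean_neigh
    out = np.full(b.mask.shape, np.nan)
    out[b.mask] = flat
    return ConnectivityMap(out, "local", b.mask, b.subject_id,
                           {"radius_vox": radius_vox, "average_domain": average_domain})


def seed_connectivity(b: BoldSeries, s: SeedSpec) -> ConnectivityMap:
    """Fisher-z map of correlation with the mean seed time course."""
    idx = s.voxels(b.mask.shape)
    if not b.mask[idx].all():
        raise ValueError(f"seed block {s.label} not fully inside the brain mask")
    seed_tc = b.data[idx].mean(axis=0)
    seed_tc = seed_tc - seed_tc.mean()
    seed_sd = seed_tc.std()
    if seed_sd == 0:
        raise ValueError("seed time course has zero variance")
    Z, ok = _standardize(b)
    r = Z @ (seed_tc / seed_sd) / b.n_timepoints
    z = fisher_z(r)
    flat = np.full(ok.shape, np.nan)
    flat[ok] = z[ok]
    out = np.full(b.mask.shape, np.nan)
    out[b.mask] = flat
    return ConnectivityMap(out, "seed", b.mask, b.subject_id,
                           {"seed_center": tuple(s.center), "seed_extent": tuple(s.extent),
                            "seed_label": s.label})


def voi_score(m: ConnectivityMap, voi_mask: np.ndarray) -> float:
    """Mean map value over in-mask VOI voxels, ignoring NaN."""
    voi_mask = np.asarray(voi_mask, dtype=bool)
    sel = voi_mask & m.mask
    if not sel.any():
        raise ValueError("VOI does not intersect the map mask")
    vals = m.data[sel]
    n_nan = int(np.isnan(vals).sum())
    if n_nan:
        log.info("voi_score: %d/%d VOI voxels are NaN", n_nan, vals.size)
    if n_nan == vals.size:
        raise ValueError("all VOI voxels are NaN")
    return float(np.nanmean(vals))
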