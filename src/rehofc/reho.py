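"""Regional homogeneity (ReHo) via Kendall's coefficient of concordance.

ReHo measures local temporal synchrony: for every in-mask voxel,
Kendall's W is computed across the voxel and its nearest neighbors (27,
19, or 7 including the center) over the time axis.  Maps are then
divided by the whole-brain mean and smoothed with a Gaussian kernel; a
group-difference map over smoothed, normalized ReHo maps yields the
data-driven seed regions for the connectivity stage.

ReHo is computed on the unsmoothed preprocessed series and the *map* is
smoothed afterwards; the connectivity branch instead smooths the data
first.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .atlas import AtlasSpec
from .core import BoldSeries, SeedROI, StatMap

log = logging.getLogger(__name__)

NEIGHBORHOODS = (7, 19, 27)


def _neighborhood_offsets(size: int) -> list[tuple[int, int, int]]:
    if size not in NEIGHBORHOODS:
        raise ValueError(f"neighborhood must be one of {NEIGHBORHOODS}")
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if size == 7 and order > 1:
                    continue
                if size == 19 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    return offsets


def _rank_along_time(data: np.ndarray) -> np.ndarray:
    """Ranks 1..t along the last axis; ties broken by first occurrence."""
    order = np.argsort(data, axis=-1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order,
                      np.broadcast_to(np.arange(data.shape[-1]), data.shape),
                      axis=-1)
    return (ranks + 1).astype(np.float64)


def kendalls_w(block: np.ndarray) -> float:
    """Kendall's coefficient of concordance for a (k, n) block.

    Each of the k series is ranked over its n time points; with R_t the
    across-series rank sum at time t and Rbar = k(n+1)/2,

        W = 12 * sum_t (R_t - Rbar)^2 / (k^2 * (n^3 - n)).

    W = 1 for perfectly concordant series; E[W] = 1/k for independent
    continuous series.  No tie correction is applied: BOLD values are
    continuous, so exact ties have probability ~0 (constant series get
    first-occurrence ranks and a logged warning).
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2:
        raise ValueError("block must be (k, n)")
    k, n = block.shape
    if k < 2 or n < 2:
        raise ValueError("need k >= 2 series and n >= 2 time points")
    if (block.max(axis=1) == block.min(axis=1)).any():
        log.warning("constant series in KCC block; ranks by first occurrence")
    ranks = _rank_along_time(block)
    r_t = ranks.sum(axis=0)
    s = ((r_t - k * (n + 1) / 2.0) ** 2).sum()
    return float(12.0 * s / (k ** 2 * (n ** 3 - n)))


def reho_map(series: BoldSeries, mask: np.ndarray | None = None,
             neighborhood: int = 27):
    """Voxelwise Kendall's W over each voxel and its in-mask neighbors.

    At mask edges the neighborhood is intersected with the mask and k is
    the actual neighbor count (voxels with fewer than 2 in-mask members
    get 0).  Returns a ``ReHoMap``.
    """
    mask = np.asarray(series.mask if mask is None else mask, dtype=bool)
    t = series.n_volumes
    if t < 10:
        raise ValueError("need at least 10 volumes for a ReHo map")
    offsets = _neighborhood_offsets(neighborhood)

    ranks = np.zeros(series.data.shape, dtype=np.float64)
    ranks[mask] = _rank_along_time(series.data[mask])

    shape = mask.shape
    r_sum = np.zeros(shape + (t,), dtype=np.float64)
    k_count = np.zeros(shape, dtype=np.int32)

    def shifted_slices(off):
        dst, src = [], []
        for d, n in zip(off, shape):
            dst.append(slice(max(d, 0), n + min(d, 0)))
            src.append(slice(max(-d, 0), n + min(-d, 0)))
        return tuple(dst), tuple(src)

    for off in offsets:
        dst, src = shifted_slices(off)
        r_sum[dst] += ranks[src] * mask[src][..., None]
        k_count[dst] += mask[src]

    k = k_count.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = ((r_sum - k[..., None] * (t + 1) / 2.0) ** 2).sum(axis=-1)
        w = 12.0 * s / (k ** 2 * (t ** 3 - t))
    valid = mask & (k_count >= 2)
    values = np.where(valid, w, 0.0)
    return ReHoMap(values=values, mask=mask, neighborhood_size=neighborhood,
                   normalized=False)


class ReHoMap:
    """A 3D ReHo map: raw W values in [0, 1] or whole-brain-normalized."""

    def __init__(self, values: np.ndarray, mask: np.ndarray,
                 neighborhood_size: int, normalized: bool):
        self.values = values
        self.mask = mask
        self.neighborhood_size = neighborhood_size
        self.normalized = normalized

    def in_mask_mean(self) -> float:
        return float(self.values[self.mask].mean())


def normalize_reho(rmap: ReHoMap) -> ReHoMap:
    """Divide by the whole-brain mean, making the in-mask mean exactly 1."""
    mean = rmap.in_mask_mean()
    if mean <= 0:
        raise ValueError("whole-brain mean ReHo must be positive")
    values = np.where(rmap.mask, rmap.values / mean, 0.0)
    return ReHoMap(values=values, mask=rmap.mask,
                   neighborhood_size=rmap.neighborhood_size, normalized=True)


def smooth_map(values: np.ndarray, fwhm_mm: float, voxel_size_mm: float,
               mask: np.ndarray | None = None) -> np.ndarray:
    """Gaussian smoothing with sigma = FWHM / (2*sqrt(2 ln 2)) voxels.

    With a mask, normalized convolution is used (smooth map*mask and the
    mask, then divide) so edge voxels are not diluted by out-of-mask
    zeros; out-of-mask voxels stay 0.  fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    values = np.asarray(values, dtype=float)
    if fwhm_mm == 0:
        return values.copy()
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    if mask is None:
        return ndimage.gaussian_filter(values, sigma)
    mask = np.asarray(mask, dtype=bool)
    num = ndimage.gaussian_filter(np.where(mask, values, 0.0), sigma)
    den = ndimage.gaussian_filter(mask.astype(float), sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mask & (den > 0), num / den, 0.0)
    return out


def smooth_series(series: BoldSeries, fwhm_mm: float) -> BoldSeries:
    """Spatially smooth every volume of a 4D series (connectivity branch)."""
    if fwhm_mm == 0:
        return series.with_data(series.data.copy())
    out = np.empty_like(series.data)
    for i in range(series.n_volumes):
        out[..., i] = smooth_map(series.data[..., i], fwhm_mm,
                                 series.voxel_size_mm, series.mask)
    return series.with_data(out)


def select_seeds(group_diff: StatMap, t_threshold: float,
                 min_extent_voxels: int, atlas: AtlasSpec) -> list[SeedROI]:
    """Seed ROIs from suprathreshold clusters of a group-difference map.

    Clusters of |t| > ``t_threshold`` (26-connectivity, formed per sign)
    with at least ``min_extent_voxels`` voxels become seeds, each named
    by the atlas region at its peak-|t| voxel.  The full cluster voxel
    set is the ROI.
    """
    structure = np.ones((3, 3, 3), dtype=bool)
    seeds: list[SeedROI] = []
    for sign in (1, -1):
        supra = (sign * group_diff.values > t_threshold) & group_diff.mask
        labels, n = ndimage.label(supra, structure=structure)
        for lab in range(1, n + 1):
            cluster = labels == lab
            if cluster.sum() < min_extent_voxels:
                continue
            absvals = np.where(cluster, np.abs(group_diff.values), -np.inf)
            peak = np.unravel_index(np.argmax(absvals), cluster.shape)
            name = atlas.region_at(peak) or f"cluster_{peak}"
            seeds.append(SeedROI(name=name, voxels=cluster, source="reho_cluster"))
    if not seeds:
        log.warning("no suprathreshold ReHo-difference clusters; no seeds")
    seeds.sort(key=lambda s: -s.size)
    return seeds


def sphere_roi(atlas: AtlasSpec, center_voxel, radius_mm: float,
               name: str = "sphere") -> SeedROI:
    """Alternative fixed-radius spherical ROI at a peak voxel."""
    ix = np.indices(atlas.grid_shape).astype(float)
    center = np.asarray(center_voxel, dtype=float)
    d2 = sum(((ix[i] - center[i]) * atlas.voxel_size_mm) ** 2 for i in range(3))
    voxels = (d2 <= radius_mm ** 2) & atlas.brain_mask
    return SeedROI(name=name, voxels=voxels, source="sphere")
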