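"""Seed-based whole-brain functional connectivity with Fisher z transform.

For each subject the seed's mean time course is correlated with every
in-mask voxel, and the correlation map is Fisher z-transformed.  The
connectivity branch operates on spatially smoothed, scrubbed data;
degrees of freedom downstream use the retained volume count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import BoldSeries, SeedROI, StatMap

log = logging.getLogger(__name__)


@dataclass
class FCMap:
    """One subject's seed-to-whole-brain Fisher-z connectivity map."""

    values: np.ndarray  # 3D, Fisher z
    seed: str
    subject_id: str
    mask: np.ndarray
    n_volumes: int  # retained volumes entering the correlation
    zero_variance: np.ndarray | None = None  # flagged voxels with r set to 0


def seed_timeseries(series: BoldSeries, roi: SeedROI) -> np.ndarray:
    """Mean time course over the ROI voxels (the reference time course)."""
    voxels = np.asarray(roi.voxels, dtype=bool)
    if not voxels.any():
        raise ValueError(f"seed ROI {roi.name!r} is empty")
    if not (voxels <= series.mask).all():
        raise ValueError(f"seed ROI {roi.name!r} leaves the analysis mask")
    return series.data[voxels].mean(axis=0)


def fc_map(series: BoldSeries, reference: np.ndarray,
           mask: np.ndarray | None = None,
           seed_name: str = "seed", subject_id: str = "") -> FCMap:
    """Voxelwise Pearson correlation with a reference time course (raw r).

    Zero-variance voxels get r = 0 and are flagged rather than producing
    NaNs.
    """
    mask = np.asarray(series.mask if mask is None else mask, dtype=bool)
    reference = np.asarray(reference, dtype=float)
    t = series.n_volumes
    if reference.shape != (t,):
        raise ValueError("reference length must equal the volume count")
    if t < 10:
        raise ValueError("need at least 10 volumes for correlation")
    y = series.data[mask]  # (nvox, t)
    yc = y - y.mean(axis=1, keepdims=True)
    xc = reference - reference.mean()
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum(axis=1))
    # constant series leave only rounding residue after centering
    scale = np.sqrt((y ** 2).sum(axis=1))
    bad = (sy <= 1e-12 * np.maximum(scale, 1e-300)) | (sx == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ xc) / (sy * sx)
    r[bad] = 0.0
    if bad.any():
        log.warning("%d zero-variance voxel(s) set to r=0", int(bad.sum()))
    r = np.clip(r, -1.0, 1.0)
    values = np.zeros(mask.shape)
    values[mask] = r
    flags = np.zeros(mask.shape, dtype=bool)
    flags[mask] = bad
    return FCMap(values=values, seed=seed_name, subject_id=subject_id,
                 mask=mask, n_volumes=t, zero_variance=flags)


def fisher_z(r):
    """Fisher z = 0.5*ln((1+r)/(1-r)); |r| >= 1 is clamped with a warning."""
    r = np.asarray(r, dtype=float)
    limit = 1.0 - 1e-7
    if (np.abs(r) >= 1.0).any():
        log.warning("clamping |r| >= 1 before Fisher z")
    rc = np.clip(r, -limit, limit)
    z = np.arctanh(rc)
    return float(z) if z.ndim == 0 else z


def fc_map_z(series: BoldSeries, roi: SeedROI,
             mask: np.ndarray | None = None, subject_id: str = "") -> FCMap:
    """Seed extraction -> voxelwise correlation -> Fisher z, in one call."""
    reference = seed_timeseries(series, roi)
    raw = fc_map(series, reference, mask=mask,
                 seed_name=roi.name, subject_id=subject_id)
    raw.values = np.where(raw.mask, fisher_z(raw.values), 0.0)
    return raw


def positive_mask(group_map: StatMap, significant: np.ndarray) -> np.ndarray:
    """Voxels with significantly *positive* group-mean connectivity.

    Group comparisons are restricted to this set: apparently negative
    connectivity after global-signal regression is not interpreted.
    """
    out = np.asarray(significant, dtype=bool) & (group_map.values > 0)
    if not out.any():
        log.warning("positive-connectivity mask is empty")
    return out
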