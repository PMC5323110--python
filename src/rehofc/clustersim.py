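"""Monte-Carlo cluster-extent thresholds (AlphaSim-style).

Estimates the minimum cluster size such that, under smooth Gaussian
noise restricted to the analysis mask, a suprathreshold cluster at a
given uncorrected voxel p occurs with familywise probability at most
alpha.  Spatial autocorrelation is modeled as pure Gaussian smoothing
at the nominal applied FWHM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .stats import CONNECTIVITY_STRUCTURE


@dataclass
class ClusterSimResult:
    """Extent threshold achieving familywise alpha, with the null table."""

    extent_threshold_voxels: int
    extent_threshold_mm3: float
    null_max_extent_quantiles: dict[str, float]
    n_iterations: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "extent_threshold_voxels": self.extent_threshold_voxels,
            "extent_threshold_mm3": self.extent_threshold_mm3,
            "null_max_extent_quantiles": self.null_max_extent_quantiles,
            "n_iterations": self.n_iterations,
            "params": self.params,
        }


def estimate_extent_threshold(mask: np.ndarray, fwhm_mm: float,
                              voxel_size_mm: float, voxel_p: float,
                              alpha: float, n_iter: int = 5000,
                              seed: int = 0, connectivity: int = 26,
                              return_null: bool = False):
    """AlphaSim-style Monte-Carlo extent threshold.

    Per iteration: fill the mask's bounding volume with unit white
    noise, smooth to ``fwhm_mm``, re-standardize to zero mean / unit
    variance within the mask, threshold two-sided at ``voxel_p``, and
    record the largest cluster formed per sign (default
    26-connectivity).  The reported threshold is

        ceil( (1 - alpha) quantile of max extents ) + 1

    i.e. the smallest extent *strictly greater* than the null quantile.
    """
    mask = np.asarray(mask, dtype=bool)
    if not (0 < voxel_p < 0.5):
        raise ValueError("voxel_p must be in (0, 0.5)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_iter < 500:
        raise ValueError("need at least 500 iterations")
    if fwhm_mm < 0 or voxel_size_mm <= 0:
        raise ValueError("bad geometry")
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    zcrit = sps.norm.isf(voxel_p / 2.0)
    structure = CONNECTIVITY_STRUCTURE[connectivity]
    rng = np.random.default_rng(seed)

    max_extents = np.zeros(n_iter, dtype=np.int64)
    exceed_rate = 0.0
    n_mask = int(mask.sum())
    for it in range(n_iter):
        noise = rng.standard_normal(mask.shape)
        if sigma > 0:
            noise = ndimage.gaussian_filter(noise, sigma)
        vals = noise[mask]
        vals = (vals - vals.mean()) / vals.std()
        field3d = np.zeros(mask.shape)
        field3d[mask] = vals
        biggest = 0
        for sign in (1, -1):
            supra = (sign * field3d > zcrit) & mask
            if not supra.any():
                continue
            labels, n = ndimage.label(supra, structure=structure)
            biggest = max(biggest, int(np.bincount(labels.ravel())[1:].max()))
        max_extents[it] = biggest
        exceed_rate += (np.abs(vals) > zcrit).sum() / n_mask
    exceed_rate /= n_iter

    q = float(np.quantile(max_extents, 1.0 - alpha))
    threshold = int(np.ceil(q)) + 1
    quantiles = {f"{p:g}": float(np.quantile(max_extents, p))
                 for p in (0.5, 0.9, 0.95, 0.99)}
    result = ClusterSimResult(
        extent_threshold_voxels=threshold,
        extent_threshold_mm3=threshold * voxel_size_mm ** 3,
        null_max_extent_quantiles=quantiles,
        n_iterations=n_iter,
        params={
            "mask_voxels": n_mask,
            "fwhm_mm": fwhm_mm,
            "voxel_size_mm": voxel_size_mm,
            "voxel_p": voxel_p,
            "realized_voxel_exceedance": float(exceed_rate),
            "alpha": alpha,
            "connectivity": connectivity,
            "seed": seed,
        },
    )
    if return_null:
        return result, max_extents
    return result
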