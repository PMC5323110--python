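"""Voxelwise group statistics for connectivity and ReHo maps.

Covers the group-level inference chain: one-sample network maps with
familywise (Bonferroni) voxel correction, covariate-adjusted group
differences with a voxelwise gray-matter covariate, behavior-score
regressions, partial correlation on extracted strengths, conjunction of
significant sets, and cluster tabulation with peak coordinates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .atlas import AtlasSpec
from .core import StatMap
from .reho import smooth_map

CONNECTIVITY_STRUCTURE = {
    26: np.ones((3, 3, 3), dtype=bool),
    18: ndimage.generate_binary_structure(3, 2),
    6: ndimage.generate_binary_structure(3, 1),
}

#: paper-style defaults: group maps {p<0.005, 74 voxels = 1,998 mm^3},
#: behavior maps {p<0.05, 389 voxels = 10,503 mm^3} at 3 mm voxels
GROUP_VOXEL_P, GROUP_MIN_EXTENT = 0.005, 74
BEHAVIOR_VOXEL_P, BEHAVIOR_MIN_EXTENT = 0.05, 389


def logit_gm(gm: np.ndarray, fwhm_mm: float = 8.0, voxel_size_mm: float = 3.0,
             mask: np.ndarray | None = None, eps: float = 1e-6) -> np.ndarray:
    """Half-logit transform of a GM probability map, then smoothing.

    logit(a) = 0.5*ln(a/(1-a)) with a clamped to [eps, 1-eps] so the
    transform is finite, followed by Gaussian smoothing at ``fwhm_mm``.
    """
    a = np.clip(np.asarray(gm, dtype=float), eps, 1.0 - eps)
    values = 0.5 * np.log(a / (1.0 - a))
    return smooth_map(values, fwhm_mm, voxel_size_mm, mask=mask)


def _stack(maps: list[np.ndarray], mask: np.ndarray) -> np.ndarray:
    """Stack per-subject 3D maps into (n_subjects, n_in_mask_voxels)."""
    return np.stack([np.asarray(m)[mask] for m in maps])


def voxelwise_ols(y: np.ndarray, x_fixed: np.ndarray, col: int,
                  x_voxel: np.ndarray | None = None):
    """Batched per-voxel OLS; returns (beta, se, t, df) for column ``col``.

    ``y`` is (n, v); ``x_fixed`` (n, p) is shared across voxels; if
    ``x_voxel`` (n, v) is given it is appended as a per-voxel regressor
    (each voxel's design uses that voxel's values).
    """
    y = np.asarray(y, dtype=float)
    xf = np.asarray(x_fixed, dtype=float)
    n, p = xf.shape
    if np.linalg.matrix_rank(xf) < p:
        corr = np.corrcoef(xf[:, 1:], rowvar=False)
        raise ValueError(
            "collinear design matrix; pairwise correlations of non-intercept "
            f"columns:\n{np.array2string(np.atleast_2d(corr), precision=3)}")
    if x_voxel is None:
        df = n - p
        xtx = xf.T @ xf
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ xf.T @ y  # (p, v)
        resid = y - xf @ beta
        sigma2 = (resid ** 2).sum(axis=0) / df
        se = np.sqrt(sigma2 * xtx_inv[col, col])
        b = beta[col]
    else:
        g = np.asarray(x_voxel, dtype=float)  # (n, v)
        v = y.shape[1]
        q = p + 1
        df = n - q
        a = xf.T @ xf                     # (p, p)
        bvec = xf.T @ g                   # (p, v)
        cvec = (g ** 2).sum(axis=0)       # (v,)
        m = np.empty((v, q, q))
        m[:, :p, :p] = a
        m[:, :p, p] = bvec.T
        m[:, p, :p] = bvec.T
        m[:, p, p] = cvec
        rhs = np.empty((v, q))
        rhs[:, :p] = (xf.T @ y).T
        rhs[:, p] = (g * y).sum(axis=0)
        minv = np.linalg.inv(m)
        beta = np.einsum("vij,vj->vi", minv, rhs)  # (v, q)
        fitted = xf @ beta[:, :p].T + g * beta[:, p]
        resid = y - fitted
        sigma2 = (resid ** 2).sum(axis=0) / df
        se = np.sqrt(sigma2 * minv[:, col, col])
        b = beta[:, col]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, 0.0)
    return b, se, t, df


def one_sample_map(fc_maps: list[np.ndarray], mask: np.ndarray,
                   alpha_fwe: float = 0.01, positive_only: bool = True
                   ) -> tuple[StatMap, np.ndarray]:
    """One-sample t of the subject maps against 0, Bonferroni-corrected.

    Significance requires two-sided p below ``alpha_fwe`` / n_voxels;
    with ``positive_only`` (the default) only positive-t voxels survive,
    restricting downstream comparisons to positive connectivity.
    """
    mask = np.asarray(mask, dtype=bool)
    y = _stack(fc_maps, mask)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = y.mean(axis=0)
    sd = y.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    df = n - 1
    p = 2.0 * sps.t.sf(np.abs(t), df)
    n_vox = int(mask.sum())
    sig = p < (alpha_fwe / n_vox)
    if positive_only:
        sig &= t > 0
    tvol = np.zeros(mask.shape)
    tvol[mask] = t
    sigvol = np.zeros(mask.shape, dtype=bool)
    sigvol[mask] = sig
    return StatMap(values=tvol, df=df, contrast="one_sample", mask=mask), sigvol


def group_glm(fc_maps: list[np.ndarray], groups: np.ndarray,
              covariates: pd.DataFrame, gm_maps: list[np.ndarray] | None,
              mask: np.ndarray, patient_label="patient") -> StatMap:
    """Voxelwise GLM: FC ~ group + age + gender + education (+ voxel GM).

    Group is coded patient=1/other=0, so positive t means higher values
    in patients.  The gray-matter covariate enters voxel-wise: each
    voxel's design column holds the subjects' (logit-transformed) GM
    values at that voxel.  Returns the t map for the group column.
    """
    mask = np.asarray(mask, dtype=bool)
    y = _stack(fc_maps, mask)
    n = y.shape[0]
    group = (np.asarray(groups) == patient_label).astype(float)
    if group.sum() < 3 or (1 - group).sum() < 3:
        raise ValueError("need at least 3 subjects per group")
    xf = np.column_stack([
        np.ones(n), group,
        covariates["age"].to_numpy(dtype=float),
        covariates["gender"].to_numpy(dtype=float),
        covariates["education"].to_numpy(dtype=float),
    ])
    x_voxel = _stack(gm_maps, mask) if gm_maps is not None else None
    _, _, t, df = voxelwise_ols(y, xf, col=1, x_voxel=x_voxel)
    tvol = np.zeros(mask.shape)
    tvol[mask] = t
    return StatMap(values=tvol, df=df, contrast="group", mask=mask)


def behavior_regression(fc_maps: list[np.ndarray], score: np.ndarray,
                        covariates: pd.DataFrame, mask: np.ndarray,
                        gm_maps: list[np.ndarray] | None = None) -> StatMap:
    """Voxelwise multiple regression of FC on a behavioral score.

    Returns the t map for the score coefficient, controlling age,
    gender, and education (plus voxelwise GM when provided).  Scores are
    entered one model per score by default.
    """
    mask = np.asarray(mask, dtype=bool)
    y = _stack(fc_maps, mask)
    score = np.asarray(score, dtype=float)
    if not np.isfinite(score).all():
        raise ValueError("score contains non-finite values")
    if score.std() == 0:
        raise ValueError("score is constant")
    n = y.shape[0]
    xf = np.column_stack([
        np.ones(n), score,
        covariates["age"].to_numpy(dtype=float),
        covariates["gender"].to_numpy(dtype=float),
        covariates["education"].to_numpy(dtype=float),
    ])
    if n < xf.shape[1] + (2 if gm_maps is None else 3):
        raise ValueError("too few subjects for the design")
    x_voxel = _stack(gm_maps, mask) if gm_maps is not None else None
    _, _, t, df = voxelwise_ols(y, xf, col=1, x_voxel=x_voxel)
    tvol = np.zeros(mask.shape)
    tvol[mask] = t
    return StatMap(values=tvol, df=df, contrast="score", mask=mask)


def partial_correlation(strengths, score, covariates=None):
    """Partial correlation of two per-subject scalars given covariates.

    Both variables are OLS-residualized on [intercept | covariates]; the
    Pearson r of the residuals is returned with a t-based p-value at
    df = n - n_covariates - 2.  With no covariates this is the plain
    Pearson correlation.
    """
    x = np.asarray(strengths, dtype=float)
    y = np.asarray(score, dtype=float)
    n = x.size
    if covariates is None:
        z = np.ones((n, 1))
        k = 0
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        k = c.shape[1]
        z = np.column_stack([np.ones(n), c])
    q, _ = np.linalg.qr(z)
    rx = x - q @ (q.T @ x)
    ry = y - q @ (q.T @ y)
    # residuals indistinguishable from zero (variable inside covariate span)
    if ((rx ** 2).sum() <= 1e-16 * (x ** 2).sum()
            or (ry ** 2).sum() <= 1e-16 * (y ** 2).sum()):
        return 0.0, 1.0
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    r = float((rx * ry).sum() / denom)
    df = n - k - 2
    r_c = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_c * np.sqrt(df / (1 - r_c ** 2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def conjunction(set_a: np.ndarray, set_b: np.ndarray) -> np.ndarray:
    """Voxelwise intersection of two significant-voxel sets."""
    a = np.asarray(set_a, dtype=bool)
    b = np.asarray(set_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("conjunction inputs must share a mask/grid")
    return a & b


def t_critical(voxel_p: float, df: int) -> float:
    """Two-sided critical |t| for an uncorrected voxel threshold."""
    return float(sps.t.isf(voxel_p / 2.0, df))


def cluster_table(stat_map: StatMap, voxel_p: float, min_extent_voxels: int,
                  atlas: AtlasSpec, network: str = "",
                  connectivity: int = 26) -> pd.DataFrame:
    """Tabulate suprathreshold clusters of a stat map.

    Voxels with |t| above the two-sided ``voxel_p`` critical value are
    grouped into connected components (default 26-connectivity) per
    sign; clusters below ``min_extent_voxels`` are dropped.  Rows are
    sorted by extent (descending) and report the atlas label and world
    coordinate of the peak-|t| voxel.
    """
    structure = CONNECTIVITY_STRUCTURE[connectivity]
    tcrit = t_critical(voxel_p, stat_map.df)
    rows = []
    for sign in (1, -1):
        supra = (sign * stat_map.values > tcrit) & stat_map.mask
        labels, n = ndimage.label(supra, structure=structure)
        for lab in range(1, n + 1):
            cluster = labels == lab
            extent = int(cluster.sum())
            if extent < min_extent_voxels:
                continue
            absvals = np.where(cluster, np.abs(stat_map.values), -np.inf)
            peak = np.unravel_index(np.argmax(absvals), cluster.shape)
            world = atlas.voxel_to_world(peak)
            region = atlas.region_at(peak) or "unlabeled"
            rows.append({
                "region_label": region,
                "side": "L" if world[0] < 0 else "R",
                "network": network,
                "extent_voxels": extent,
                "extent_mm3": extent * atlas.voxel_size_mm ** 3,
                "peak_x_mm": float(world[0]),
                "peak_y_mm": float(world[1]),
                "peak_z_mm": float(world[2]),
                "peak_stat": float(sign * absvals[peak]),
            })
    cols = ["region_label", "side", "network", "extent_voxels", "extent_mm3",
            "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_stat"]
    table = pd.DataFrame(rows, columns=cols)
    return table.sort_values("extent_voxels", ascending=False,
                             kind="stable").reset_index(drop=True)


def cluster_table_from_set(voxel_set: np.ndarray, atlas: AtlasSpec,
                           stat_values: np.ndarray | None = None,
                           network: str = "", connectivity: int = 26,
                           min_extent_voxels: int = 1) -> pd.DataFrame:
    """Tabulate the connected components of a binary voxel set.

    Used for conjunction maps, which carry no test statistic of their
    own; when ``stat_values`` is given (e.g. one source map's t values)
    the peak is the max-|stat| voxel and its value is reported,
    otherwise the peak is the component's centroid voxel and the stat
    column is NaN.
    """
    voxel_set = np.asarray(voxel_set, dtype=bool)
    structure = CONNECTIVITY_STRUCTURE[connectivity]
    labels, n = ndimage.label(voxel_set, structure=structure)
    rows = []
    for lab in range(1, n + 1):
        cluster = labels == lab
        extent = int(cluster.sum())
        if extent < min_extent_voxels:
            continue
        if stat_values is not None:
            absvals = np.where(cluster, np.abs(stat_values), -np.inf)
            peak = np.unravel_index(np.argmax(absvals), cluster.shape)
            peak_stat = float(stat_values[peak])
        else:
            idx = np.argwhere(cluster)
            centroid = idx.mean(axis=0)
            peak = tuple(idx[np.argmin(((idx - centroid) ** 2).sum(axis=1))])
            peak_stat = float("nan")
        world = atlas.voxel_to_world(peak)
        rows.append({
            "region_label": atlas.region_at(peak) or "unlabeled",
            "side": "L" if world[0] < 0 else "R",
            "network": network,
            "extent_voxels": extent,
            "extent_mm3": extent * atlas.voxel_size_mm ** 3,
            "peak_x_mm": float(world[0]),
            "peak_y_mm": float(world[1]),
            "peak_z_mm": float(world[2]),
            "peak_stat": peak_stat,
        })
    cols = ["region_label", "side", "network", "extent_voxels", "extent_mm3",
            "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_stat"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        "extent_voxels", ascending=False, kind="stable").reset_index(drop=True)


def significant_set(stat_map: StatMap, voxel_p: float, min_extent_voxels: int,
                    connectivity: int = 26) -> np.ndarray:
    """Boolean volume of voxels in surviving clusters (both signs)."""
    structure = CONNECTIVITY_STRUCTURE[connectivity]
    tcrit = t_critical(voxel_p, stat_map.df)
    out = np.zeros(stat_map.mask.shape, dtype=bool)
    for sign in (1, -1):
        supra = (sign * stat_map.values > tcrit) & stat_map.mask
        labels, n = ndimage.label(supra, structure=structure)
        if n == 0:
            continue
        counts = np.bincount(labels.ravel())
        for lab in range(1, n + 1):
            if counts[lab] >= min_extent_voxels:
                out |= labels == lab
    return out
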