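"""Synthetic brain atlas: grid geometry, tissue masks, and named regions.

The atlas lives on a small 3 mm isotropic grid and hosts two seed regions
(a DLPFC-like frontal seed and an RSC-like retrosplenial seed) plus the
target regions of their networks (MCC, bilateral IPL, PCC/precuneus,
caudate, ACG/SMA), embedded in an ellipsoidal brain with deep white-matter
and ventricular CSF compartments.  Region extents are on the order of
100-350 voxels, the scale at which group-level clusters are typically
reported for this kind of analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: region label -> integer code used in label volumes
REGION_CODES = {
    "seed_DLPFC": 1,
    "seed_RSC": 2,
    "target_MCC": 3,
    "target_IPL_L": 4,
    "target_IPL_R": 5,
    "target_PCC_PCu": 6,
    "target_caudate": 7,
    "target_ACG_SMA": 8,
    "wm": 9,
    "csf": 10,
}

SEED_REGIONS = ("seed_DLPFC", "seed_RSC")

#: seed -> the targets of its network
NETWORKS = {
    "seed_DLPFC": ("target_MCC", "target_IPL_L", "target_caudate", "target_ACG_SMA"),
    "seed_RSC": ("target_PCC_PCu", "target_IPL_R"),
}


@dataclass
class AtlasSpec:
    """Geometry plus named voxel sets for the synthetic brain.

    Attributes
    ----------
    grid_shape : tuple of int
        Volume shape (x, y, z) in voxels.
    voxel_size_mm : float
        Isotropic voxel edge length.
    affine : ndarray (4, 4)
        Voxel-index to world-mm mapping.
    regions : dict of str -> ndarray
        Boolean volume per named region (seeds, targets, wm, csf).
    brain_mask : ndarray
        Boolean volume of all brain voxels.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    affine: np.ndarray
    regions: dict[str, np.ndarray]
    brain_mask: np.ndarray

    @property
    def gm_mask(self) -> np.ndarray:
        """Gray matter: brain minus white matter and CSF."""
        return self.brain_mask & ~self.regions["wm"] & ~self.regions["csf"]

    @property
    def background(self) -> np.ndarray:
        return ~self.brain_mask

    def label_volume(self) -> np.ndarray:
        """Integer-coded region labels (0 = unlabeled)."""
        lab = np.zeros(self.grid_shape, dtype=np.int16)
        for name, code in REGION_CODES.items():
            lab[self.regions[name]] = code
        return lab

    def region_at(self, voxel: tuple[int, int, int]) -> str | None:
        """Name of the region containing ``voxel``, or None."""
        for name, m in self.regions.items():
            if m[voxel]:
                return name
        return None

    def voxel_to_world(self, voxel) -> np.ndarray:
        v = np.asarray(voxel, dtype=float)
        return (self.affine[:3, :3] @ v) + self.affine[:3, 3]

    def validate(self) -> None:
        """Raise ValueError on any violated structural invariant."""
        total = np.zeros(self.grid_shape, dtype=np.int32)
        for name, m in self.regions.items():
            if not m.any():
                raise ValueError(f"region {name!r} is empty")
            if not (m <= self.brain_mask).all():
                raise ValueError(f"region {name!r} leaves the brain mask")
            total += m.astype(np.int32)
        if (total > 1).any():
            raise ValueError("atlas regions overlap")
        gm = self.gm_mask
        for name in REGION_CODES:
            if name in ("wm", "csf"):
                continue
            if not (self.regions[name] <= gm).all():
                raise ValueError(f"GM region {name!r} intersects wm/csf")


def _box(shape, x, y, z) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[x[0]:x[1], y[0]:y[1], z[0]:z[1]] = True
    return m


def default_atlas(grid_shape=(24, 28, 24), voxel_size_mm=3.0) -> AtlasSpec:
    """Build the default desk-scale atlas.

    The brain is an axis-aligned ellipsoid filling most of the grid; the
    affine places the grid center at the world origin with +x = right.
    Region placements are fixed box carves chosen to be disjoint, inside
    gray matter, and roughly anatomically arranged (frontal seed anterior
    superior right, retrosplenial seed posterior midline, etc.).
    """
    nx, ny, nz = grid_shape
    vs = float(voxel_size_mm)
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = -vs * (np.array(grid_shape) - 1) / 2.0

    center = (np.array(grid_shape) - 1) / 2.0
    semi = np.array([nx, ny, nz]) / 2.0 - 0.8
    ix = np.indices(grid_shape).astype(float)
    d2 = sum(((ix[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    brain = d2 <= 1.0

    shape = grid_shape
    # y axis: posterior (low) -> anterior (high); z: inferior -> superior
    boxes = {
        "seed_DLPFC":     ((15, 20), (17, 22), (12, 16)),   # right, anterior, superior
        "seed_RSC":       ((12, 17), (5, 10), (8, 12)),     # right-of-midline, posterior
        "target_MCC":     ((9, 15), (10, 16), (14, 19)),    # bilateral midline, superior
        "target_IPL_L":   ((3, 8),  (7, 13),  (12, 17)),    # left posterior lateral
        "target_IPL_R":   ((18, 23), (7, 13), (11, 16)),    # right posterior lateral
        "target_PCC_PCu": ((9, 15), (3, 8),  (14, 19)),     # midline posterior superior
        "target_caudate": ((9, 15), (14, 19), (7, 11)),     # deep bilateral, inferior
        "target_ACG_SMA": ((4, 9), (18, 23), (13, 17)),     # left anterior superior
        "csf":            ((10, 14), (10, 14), (3, 7)),     # ventricle-like, inferior
        "wm":             ((4, 9), (13, 18), (5, 10)),      # deep left white matter
    }
    regions = {name: _box(shape, *b) & brain for name, b in boxes.items()}
    # second white-matter lobe on the right, mirrored
    regions["wm"] |= _box(shape, (16, 21), (13, 18), (5, 10)) & brain
    # carve any accidental overlap in favour of the earlier-listed region
    claimed = np.zeros(shape, dtype=bool)
    for name in boxes:
        regions[name] &= ~claimed
        claimed |= regions[name]

    atlas = AtlasSpec(
        grid_shape=tuple(grid_shape),
        voxel_size_mm=vs,
        affine=affine,
        regions=regions,
        brain_mask=brain,
    )
    atlas.validate()
    return atlas
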