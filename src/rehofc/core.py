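"""Shared in-memory containers for volumes, motion traces, and stat maps."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass
class BoldSeries:
    """One subject's 4D BOLD volume.

    ``data`` is (x, y, z, t); voxels outside ``mask`` are carried along
    untouched by every temporal operation and excluded from statistics.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float
    voxel_size_mm: float
    mask: np.ndarray

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return replace(self, data=data)

    def masked(self) -> np.ndarray:
        """In-mask voxel time series as (n_voxels, t)."""
        return self.data[self.mask]

    def put_masked(self, values: np.ndarray) -> "BoldSeries":
        """New series with in-mask series replaced by ``values`` (n_voxels, t)."""
        out = self.data.copy()
        out[self.mask] = values
        return self.with_data(out)


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters per volume.

    Translations in mm, rotations in degrees; one row per retained volume.
    """

    params: np.ndarray  # (t, 6)

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be (t, 6)")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.params[:, 3:]

    def subset(self, volumes) -> "MotionTrace":
        return MotionTrace(self.params[np.asarray(volumes)])


@dataclass
class StatMap:
    """3D map of test statistics with its degrees of freedom and mask."""

    values: np.ndarray
    df: int
    contrast: str
    mask: np.ndarray
    affine: np.ndarray | None = None


@dataclass
class SeedROI:
    """A named seed region: a voxel set within the analysis mask."""

    name: str
    voxels: np.ndarray  # boolean 3D mask
    source: str = "reho_cluster"  # or "sphere"

    @property
    def size(self) -> int:
        return int(self.voxels.sum())
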