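"""NIfTI / TSV / JSON readers and writers for the pipeline's file interfaces."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import MOTION_COLUMNS, BoldSeries, MotionTrace


def save_nifti(path, data: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), np.asarray(img.affine)


def save_bold(path, series: BoldSeries) -> None:
    save_nifti(path, series.data, series.affine)


def load_bold(path, mask: np.ndarray, tr_s: float, voxel_size_mm: float) -> BoldSeries:
    data, affine = load_nifti(path)
    return BoldSeries(data=data, affine=affine, tr_s=tr_s,
                      voxel_size_mm=voxel_size_mm, mask=mask)


def save_motion_tsv(path, motion: MotionTrace) -> None:
    df = pd.DataFrame(motion.params, columns=list(MOTION_COLUMNS))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_motion_tsv(path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    return MotionTrace(df[list(MOTION_COLUMNS)].to_numpy())


def save_phenotypes_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())
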