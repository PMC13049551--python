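"""File formats: NIfTI-1 volumes, SPM-style motion text files, TSV tables.

Round-trip fidelity is the contract: writing then reading reproduces the
data payload and geometry (voxel sizes, TR) exactly for the supported
dtypes (float32 volumes, int16 labels).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import LABEL_CLASSES, MotionParams, PhantomLabels, Volume4D

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_labels",
    "read_labels",
    "write_motion_txt",
    "read_motion_txt",
    "write_tsv",
    "read_tsv",
    "SchemaError",
]


class SchemaError(ValueError):
    """A table is missing a required column."""


def write_nifti(path: str | Path, vol: Volume4D) -> Path:
    """Write a 4D volume as NIfTI-1 (float32), TR carried in the time zoom."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine=vol.affine)
    img.header.set_zooms(tuple(vol.voxel_size_mm) + (vol.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    return path


def read_nifti(path: str | Path) -> Volume4D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()
    if len(zooms) < 4 or zooms[3] <= 0:
        raise ValueError(f"{path}: malformed header, no positive TR in time zoom")
    return Volume4D(data, tuple(float(z) for z in zooms[:3]), float(zooms[3]))


def write_labels(path: str | Path, labels: PhantomLabels) -> Path:
    path = Path(path)
    aff = np.diag(list(labels.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(labels.label_volume.astype(np.int16), affine=aff)
    img.header.set_zooms(tuple(labels.voxel_size_mm))
    nib.save(img, path)
    return path


def read_labels(path: str | Path) -> PhantomLabels:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int16)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PhantomLabels(data, dict(LABEL_CLASSES), zooms)


def write_motion_txt(path: str | Path, motion: MotionParams) -> Path:
    """Six whitespace-delimited columns (SPM ``rp_*.txt`` dialect)."""
    path = Path(path)
    np.savetxt(path, motion.params, fmt="%.8e")
    return path


def read_motion_txt(path: str | Path) -> MotionParams:
    arr = np.loadtxt(str(path))
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 6:
        raise ValueError(
            f"{path}: motion file must have exactly 6 columns, found {arr.shape[1]}"
        )
    return MotionParams(arr)


def write_tsv(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_tsv(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df
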