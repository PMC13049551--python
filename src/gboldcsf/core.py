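"""Core in-memory containers for volumes, labels and motion traces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume4D", "PhantomLabels", "MotionParams", "LABEL_CLASSES"]

#: Tissue/network classes of the phantom label volume.
LABEL_CLASSES: dict[str, int] = {
    "background": 0,
    "GM_LN": 1,
    "GM_SN": 2,
    "GM_DAN": 3,
    "GM_DMN": 4,
    "GM_other": 5,
    "WM": 6,
    "CSF_bottom": 7,
    "lesion": 8,
}

GM_CLASSES = ("GM_LN", "GM_SN", "GM_DAN", "GM_DMN", "GM_other")


@dataclass
class Volume4D:
    """A 4D fMRI volume: data indexed (x, y, z, t) plus voxel geometry and TR."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D data must be 4D, got shape {self.data.shape}")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff

    def copy(self) -> "Volume4D":
        return Volume4D(self.data.copy(), self.voxel_size_mm, self.tr_s)


@dataclass
class PhantomLabels:
    """Integer-labelled 3D volume assigning voxels to tissue/network classes."""

    label_volume: np.ndarray
    class_map: dict[str, int] = field(default_factory=lambda: dict(LABEL_CLASSES))
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("label volume must be 3D")
        # CSF inflow logic requires the CSF parcel on the lowest slice only
        csf = self.label_volume == self.class_map["CSF_bottom"]
        if csf.any() and csf[:, :, 1:].any():
            raise ValueError("CSF_bottom voxels must lie on the lowest slice (z=0)")

    def mask(self, *classes: str) -> np.ndarray:
        """Boolean mask of the union of the named classes."""
        ids = [self.class_map[c] for c in classes]
        return np.isin(self.label_volume, ids)

    def gm_mask(self, include_lesion: bool = False) -> np.ndarray:
        classes = list(GM_CLASSES) + (["lesion"] if include_lesion else [])
        return self.mask(*classes)

    def brain_mask(self) -> np.ndarray:
        return self.label_volume != self.class_map["background"]


@dataclass
class MotionParams:
    """Six rigid-body realignment traces: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"motion parameters must be (n_timepoints, 6), got {self.params.shape}"
            )
        if not np.isfinite(self.params).all():
            raise ValueError("motion parameters must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.params.shape[0]
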