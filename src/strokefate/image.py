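"""Lightweight image containers and NIfTI I/O.

The pipeline works on co-registered native-space volumes, so a volume is a
plain scalar array plus physical voxel dimensions.  The left/right hemisphere
split is a grid plane on axis 0 (the left-right axis): voxels with
``x < nx // 2`` belong to the contralateral (left) hemisphere, the rest to the
ipsilesional (right) hemisphere.  All grids used by the pipeline have an even
size along axis 0 so mirroring across the midline is an exact voxel
permutation (``numpy.flip`` on axis 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeImage",
    "DscSeries",
    "load_volume",
    "save_volume",
    "load_series",
    "save_series",
    "mirror",
    "hemisphere_masks",
]


@dataclass
class VolumeImage:
    """A 3D scalar map (ADC, T2, CBF, CBV, MTT or a mask) on a voxel grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values; masks use 0/1 or boolean.
    voxel_size : tuple of float
        Physical voxel dimensions in mm per axis.
    name : str
        Free-form label used in filenames and provenance.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (0.3, 0.3, 1.2)
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeImage requires a 3D array, got {self.data.ndim}D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ul(self) -> float:
        """Volume of one voxel in microlitres (1 mm^3 == 1 uL)."""
        return float(np.prod(self.voxel_size))

    def same_grid(self, other: "VolumeImage") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size, other.voxel_size
        )

    def require_same_grid(self, other: "VolumeImage") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch: {self.shape}/{self.voxel_size} vs "
                f"{other.shape}/{other.voxel_size}"
            )

    def copy_with(self, data: np.ndarray, name: str | None = None) -> "VolumeImage":
        return VolumeImage(
            data=np.asarray(data),
            voxel_size=self.voxel_size,
            name=self.name if name is None else name,
        )


@dataclass
class DscSeries:
    """A 4D dynamic susceptibility contrast signal time series.

    Frame ordinals quoted by acquisition protocols ("bolus at the 180th
    image", "truncated at the 400th image") are 1-based; internally all frame
    indices are 0-based.  ``bolus_frame`` and ``truncation_frame`` store the
    0-based indices; use :meth:`from_ordinals` to convert.
    """

    data: np.ndarray  # (nx, ny, nz, nt)
    tr_ms: float = 164.0
    te_ms: float = 13.0
    bolus_frame: int = 179  # 0-based; 180th image
    truncation_frame: int = 399  # 0-based; 400th image
    voxel_size: tuple[float, float, float] = (0.3, 0.3, 1.2)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"DscSeries requires a 4D array, got {self.data.ndim}D")
        if self.tr_ms <= 0 or self.te_ms <= 0:
            raise ValueError("TR and TE must be strictly positive")
        if not (0 <= self.bolus_frame < self.truncation_frame < self.n_frames):
            raise ValueError(
                "require 0 <= bolus_frame < truncation_frame < n_frames, got "
                f"{self.bolus_frame}, {self.truncation_frame}, {self.n_frames}"
            )

    @classmethod
    def from_ordinals(
        cls,
        data: np.ndarray,
        bolus_image_ordinal: int = 180,
        truncation_ordinal: int = 400,
        **kw,
    ) -> "DscSeries":
        """Build a series from 1-based frame ordinals as quoted in protocols."""
        return cls(
            data=data,
            bolus_frame=bolus_image_ordinal - 1,
            truncation_frame=truncation_ordinal - 1,
            **kw,
        )

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def frame_interval_s(self) -> float:
        """Time between frames in seconds (TR-derived)."""
        return self.tr_ms / 1000.0


def mirror(data: np.ndarray) -> np.ndarray:
    """Reflect a volume across the hemispheric midline plane (axis 0).

    Requires an even size along axis 0 so the reflection is an exact voxel
    permutation; it is then an involution.
    """
    if data.shape[0] % 2 != 0:
        raise ValueError("midline mirroring requires an even size along axis 0")
    return np.flip(data, axis=0)


def hemisphere_masks(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (left, right) hemisphere masks for a grid with axis-0 midline."""
    nx = shape[0]
    if nx % 2 != 0:
        raise ValueError("hemisphere split requires an even size along axis 0")
    x = np.arange(nx)[:, None, None]
    left = np.broadcast_to(x < nx // 2, shape)
    return left.copy(), (~left).copy()


def save_volume(vol: VolumeImage, path) -> None:
    affine = np.diag(list(vol.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), affine), str(path))


def load_volume(path, name: str = "") -> VolumeImage:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return VolumeImage(
        data=np.asarray(img.dataobj, dtype=np.float64),
        voxel_size=tuple(float(z) for z in zooms),
        name=name,
    )


def save_series(series: DscSeries, path) -> None:
    affine = np.diag(list(series.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(series.voxel_size) + (series.tr_ms / 1000.0,))
    nib.save(img, str(path))


def load_series(
    path,
    tr_ms: float = 164.0,
    te_ms: float = 13.0,
    bolus_image_ordinal: int = 180,
    truncation_ordinal: int = 400,
) -> DscSeries:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return DscSeries.from_ordinals(
        data=np.asarray(img.dataobj, dtype=np.float64),
        bolus_image_ordinal=bolus_image_ordinal,
        truncation_ordinal=truncation_ordinal,
        tr_ms=tr_ms,
        te_ms=te_ms,
        voxel_size=tuple(float(z) for z in zooms[:3]),
    )
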