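"""Core in-memory containers shared across the pipeline.

Conventions used everywhere in :mod:`rsdiag`:

* 4D scans are indexed ``(x, y, z, t)``; 3D volumes ``(x, y, z)``.
* Flattening of a masked volume is lexicographic with x fastest, then y,
  then z (Fortran ravel order).  The inverse operation zero-fills voxels
  outside the mask.
* Voxels are cubic; ``voxel_mm`` is the edge length in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np


class GridMismatchError(ValueError):
    """Raised when two spatial objects live on different grids."""


@dataclass
class Scan4D:
    """A 4D resting-state scan in a common volumetric space.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, nt)
        Intensity values.
    voxel_mm : float
        Cubic voxel edge length in mm.
    tr_s : float
        Repetition time (sampling interval) in seconds.
    """

    data: np.ndarray
    voxel_mm: float = 3.0
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"scan data must be 4D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all scan dimensions must be >= 1")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def duration_s(self) -> float:
        """Nominal scan length: number of volumes times the volume time."""
        return self.n_timepoints * self.tr_s

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag([self.voxel_mm] * 3 + [1.0])
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms((self.voxel_mm,) * 3 + (self.tr_s,))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path) -> "Scan4D":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
        return cls(np.asarray(img.dataobj, dtype=float), voxel_mm=float(zooms[0]), tr_s=tr)


@dataclass
class Mask:
    """Binary brain mask with provenance of its construction."""

    data: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def to_nifti(self, voxel_mm: float = 3.0) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), np.diag([voxel_mm] * 3 + [1.0]))

    def save(self, path, voxel_mm: float = 3.0) -> None:
        nib.save(self.to_nifti(voxel_mm), str(path))

    @classmethod
    def from_nifti(cls, img_or_path) -> "Mask":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        return cls(np.asarray(img.dataobj) > 0)


@dataclass
class StatMap:
    """3D map of t-values with degrees of freedom and contrast tag.

    Values are zero outside the mask and finite inside it.
    """

    t: np.ndarray
    df: int
    contrast: str
    mask: Mask
    voxel_mm: float = 3.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.shape != self.mask.grid_dims:
            raise GridMismatchError(
                f"stat map grid {self.t.shape} != mask grid {self.mask.grid_dims}"
            )
        if not np.all(np.isfinite(self.t[self.mask.data])):
            raise ValueError("non-finite t-values inside mask")

    def copy_with(self, t: np.ndarray) -> "StatMap":
        return StatMap(t, self.df, self.contrast, self.mask, self.voxel_mm)


@dataclass
class Cluster:
    """A contiguous set of suprathreshold voxels.

    ``mass`` is the statistical mass: the sum of |t| over member voxels.
    """

    voxels: np.ndarray  # (n, 3) int voxel coordinates
    peak: tuple[int, int, int]
    volume_mm3: float
    mass: float

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class ClusterSet:
    """Clusters ordered by decreasing statistical mass."""

    clusters: list[Cluster]
    voxel_mm: float = 3.0

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def __getitem__(self, i: int) -> Cluster:
        return self.clusters[i]


@dataclass
class FeatureVolumeSet:
    """Per-voxel feature volumes V_k for one participant.

    ``volumes`` has shape (eta, nx, ny, nz) where eta is the number of
    feature values per voxel (T Avg: 1, PCA_1: 1, PCA_1-5: 5, FFT: 36,
    ALFF: 1, FC_DMN: 1, FC_1-20: 20).  Voxels excluded by the mask are
    zero-filled.
    """

    volumes: np.ndarray
    mask: Mask
    names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim == 3:
            self.volumes = self.volumes[None]
        if self.volumes.shape[1:] != self.mask.grid_dims:
            raise GridMismatchError(
                f"feature volumes grid {self.volumes.shape[1:]} != mask {self.mask.grid_dims}"
            )

    @property
    def eta(self) -> int:
        return self.volumes.shape[0]


def flatten_volume(volume: np.ndarray, mask: Mask) -> np.ndarray:
    """Extract masked voxels in x-fastest lexicographic order."""
    volume = np.asarray(volume)
    if volume.shape != mask.grid_dims:
        raise GridMismatchError(f"volume grid {volume.shape} != mask {mask.grid_dims}")
    return np.ravel(volume, order="F")[np.ravel(mask.data, order="F")]


def unflatten_vector(vector: np.ndarray, mask: Mask) -> np.ndarray:
    """Inverse of :func:`flatten_volume`; masked-out voxels are zero-filled."""
    vector = np.asarray(vector, dtype=float)
    if vector.size != mask.n_voxels:
        raise ValueError(f"vector length {vector.size} != mask voxel count {mask.n_voxels}")
    flat = np.zeros(int(np.prod(mask.grid_dims)))
    flat[np.ravel(mask.data, order="F")] = vector
    return flat.reshape(mask.grid_dims, order="F")
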