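"""NIfTI-1 volume and label-map I/O.

All images are canonicalized to the RAS+ axis order on load so that voxel
axis 0 increases toward +x, axis 1 toward +y and axis 2 toward +z of the
canonical frame.  Throughout the package class 1 ("left" masseter) is the
structure whose centroid lies on the +x side and class 2 ("right") the one
on the -x side; this is a fixed repository convention, never inferred from
image metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

VALID_LABELS = (0, 1, 2)
LABEL_NAMES = {0: "background", 1: "left_mm", 2: "right_mm"}


class VolumeIOError(RuntimeError):
    """Raised when a file cannot be read as a valid volume or label map."""


@dataclass
class Volume:
    """A 3-D intensity grid in Hounsfield units with physical geometry.

    Attributes
    ----------
    voxels : (nx, ny, nz) float32 array of HU values.
    spacing : voxel edge lengths (sx, sy, sz) in mm, all > 0.
    origin : physical coordinate of voxel (0, 0, 0) in mm.
    orientation : axis code; always ``"RAS"`` after canonicalization.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("expected a non-empty 3-D voxel grid")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        return replace(self, voxels=np.asarray(voxels, dtype=np.float32))


@dataclass
class LabelMap:
    """An integer class grid aligned to a :class:`Volume`.

    Classes: 0 background, 1 left masseter (+x side), 2 right masseter.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        bad = np.setdiff1d(np.unique(labels), VALID_LABELS)
        if bad.size:
            raise ValueError(f"invalid label values present: {bad.tolist()}")
        self.labels = labels.astype(np.uint8)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("expected a non-empty 3-D label grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def structure_counts(self) -> tuple[int, int]:
        """Voxel counts of (left, right) structures."""
        return int(np.sum(self.labels == 1)), int(np.sum(self.labels == 2))

    def same_grid_as(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _load_canonical(path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise VolumeIOError(f"cannot read {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected 3-D volume, got {data.ndim}-D")
    aff = img.affine
    spacing = tuple(float(s) for s in np.sqrt((aff[:3, :3] ** 2).sum(axis=0)))
    origin = tuple(float(o) for o in aff[:3, 3])
    return data, spacing, origin


def read_volume(path) -> Volume:
    """Read a NIfTI-1 intensity volume, canonicalized to RAS+."""
    data, spacing, origin = _load_canonical(path)
    data = np.asarray(data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise VolumeIOError(f"{path}: non-finite voxel values")
    return Volume(voxels=data, spacing=spacing, origin=origin)


def write_volume(v: Volume, path) -> None:
    """Write a volume as NIfTI-1 with float32 storage (lossless round-trip)."""
    img = nib.Nifti1Image(v.voxels.astype(np.float32), _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def read_labels(path) -> LabelMap:
    """Read a NIfTI-1 label map; values outside {0, 1, 2} are rejected."""
    data, spacing, origin = _load_canonical(path)
    data = np.asarray(data)
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6):
        raise VolumeIOError(f"{path}: label map contains non-integer values")
    bad = np.setdiff1d(np.unique(rounded), VALID_LABELS)
    if bad.size:
        raise VolumeIOError(
            f"{path}: invalid label values present: {bad.astype(int).tolist()}"
        )
    return LabelMap(labels=rounded.astype(np.uint8), spacing=spacing, origin=origin)


def write_labels(lab: LabelMap, path) -> None:
    """Write a label map as unsigned 8-bit NIfTI-1."""
    img = nib.Nifti1Image(lab.labels.astype(np.uint8), _affine(lab.spacing, lab.origin))
    img.header.set_zooms(lab.spacing)
    nib.save(img, str(path))
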