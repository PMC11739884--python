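"""Label-volume container, NIfTI I/O and segmentation-mask editing.

A :class:`LabelVolume` is a 3D integer grid of body labels (0 = background)
together with the anisotropic voxel spacing and the voxel-to-world affine.
The editing operations implement the mask-cleanup rules applied before
surface extraction: removal of partial-volume islands below a linked-voxel
threshold, merging of endplate labels into the adjacent disc label, and
connected-component counting used to detect disconnected segmentations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeFormatError(ValueError):
    """Raised when a file does not contain a 3D integer label volume."""


#: 3x3x3 structuring element connecting all 26 neighbours of a voxel.
STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)
#: 6-connectivity (faces only) alternative.
STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return STRUCTURE_26
    if connectivity == 6:
        return STRUCTURE_6
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValueError(f"unsupported connectivity: {connectivity}")


@dataclass
class LabelVolume:
    """3D integer label grid with voxel spacing and world affine.

    Attributes
    ----------
    grid : numpy.ndarray
        3D array of non-negative integer label ids; 0 is background.
    spacing_mm : numpy.ndarray
        Voxel edge lengths ``(sx, sy, sz)`` in mm.  The slice direction
        (third axis) may be substantially coarser than the in-plane axes.
    affine : numpy.ndarray
        4x4 voxel-index-to-world-mm transform.  The column norms of its
        linear part equal the spacing components.
    names : dict
        Optional map from label id to a human-readable body name.
    """

    grid: np.ndarray
    spacing_mm: np.ndarray
    affine: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise VolumeFormatError(f"label grid must be 3D, got {self.grid.ndim}D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise VolumeFormatError(f"label grid must be integer, got {self.grid.dtype}")
        if self.grid.size and self.grid.min() < 0:
            raise VolumeFormatError("label grid contains negative values")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        if np.any(self.spacing_mm <= 0):
            raise VolumeFormatError(f"non-positive spacing: {self.spacing_mm}")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        col_norms = np.linalg.norm(self.affine[:3, :3], axis=0)
        if not np.allclose(col_norms, self.spacing_mm, rtol=1e-6, atol=1e-9):
            raise VolumeFormatError(
                f"affine column norms {col_norms} inconsistent with spacing {self.spacing_mm}"
            )

    @classmethod
    def from_grid(
        cls,
        grid: np.ndarray,
        spacing_mm,
        origin_mm=(0.0, 0.0, 0.0),
        names: dict[int, str] | None = None,
    ) -> "LabelVolume":
        """Build a volume with an axis-aligned affine from spacing and origin."""
        spacing_mm = np.asarray(spacing_mm, dtype=float)
        affine = np.eye(4)
        affine[:3, :3] = np.diag(spacing_mm)
        affine[:3, 3] = origin_mm
        return cls(grid=np.asarray(grid), spacing_mm=spacing_mm, affine=affine,
                   names=dict(names or {}))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def labels(self) -> np.ndarray:
        """Sorted array of nonzero labels present in the grid."""
        vals = np.unique(self.grid)
        return vals[vals > 0]

    def voxel_count(self, label: int) -> int:
        return int(np.count_nonzero(self.grid == label))

    def world_coordinates(self, ijk: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (n, 3), to world mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def copy(self) -> "LabelVolume":
        return LabelVolume(grid=self.grid.copy(), spacing_mm=self.spacing_mm.copy(),
                           affine=self.affine.copy(), names=dict(self.names))


def read_label_volume(path) -> LabelVolume:
    """Read a 3D integer NIfTI label volume.

    Raises :class:`VolumeFormatError` for 4D images or floating-point data
    (a label mask must be integral).
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D volume, got {data.ndim}D")
    if np.issubdtype(data.dtype, np.floating):
        raise VolumeFormatError(f"{path}: floating-point data is not a label volume")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    names: dict[int, str] = {}
    sidecar = path.with_name(path.name.split(".")[0] + "_labels.json")
    if sidecar.exists():
        names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return LabelVolume(grid=data.astype(np.int32), spacing_mm=spacing,
                       affine=np.asarray(img.affine, dtype=float), names=names)


def write_label_volume(vol: LabelVolume, path) -> None:
    """Write a label volume as NIfTI plus a JSON label-name sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(vol.grid.astype(np.int32), vol.affine)
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, str(path))
    if vol.names:
        sidecar = path.with_name(path.name.split(".")[0] + "_labels.json")
        sidecar.write_text(json.dumps({str(k): v for k, v in vol.names.items()}, indent=1))


def remove_small_components(
    vol: LabelVolume, min_voxels: int = 4, connectivity: int = 26
) -> LabelVolume:
    """Remove per-label connected components smaller than ``min_voxels``.

    Partial-volume islands below the linked-voxel threshold are set to
    background; components with ``count >= min_voxels`` are kept untouched
    (strictly-below removal).  Idempotent.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    out = vol.copy()
    structure = _structure(connectivity)
    for label in vol.labels():
        mask = vol.grid == label
        comp, n = ndimage.label(mask, structure=structure)
        if n <= 1:
            if n == 1 and mask.sum() < min_voxels:
                out.grid[mask] = 0
            continue
        sizes = np.bincount(comp.ravel())
        small = np.flatnonzero(sizes < min_voxels)
        small = small[small > 0]
        if small.size:
            out.grid[np.isin(comp, small)] = 0
    return out


def merge_ivd_endplates(
    vol: LabelVolume, endplate_labels, ivd_label: int
) -> LabelVolume:
    """Relabel endplate voxels into the adjacent disc label.

    The endplates are treated as part of the disc so that one surface is
    extracted per disc; total foreground voxel count is unchanged.
    """
    if ivd_label == 0:
        raise ValueError("cannot merge endplates into the background label")
    out = vol.copy()
    for lab in endplate_labels:
        out.grid[vol.grid == lab] = ivd_label
        out.names.pop(int(lab), None)
    return out


def count_components(vol: LabelVolume, label: int, connectivity: int = 26) -> int:
    """Number of connected components of ``label`` (0 if absent)."""
    if label <= 0:
        raise ValueError("label must be positive")
    mask = vol.grid == label
    if not mask.any():
        return 0
    _, n = ndimage.label(mask, structure=_structure(connectivity))
    return int(n)
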