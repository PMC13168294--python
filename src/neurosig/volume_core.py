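"""Domain types and NIfTI I/O shared by every pipeline stage.

All statistical maps live as flat vectors over the in-mask voxels of a
:class:`BrainMask`.  The mask fixes a deterministic linear scan order —
first axis fastest (x, then y, then z), 0-based voxel indices — so that
vectorize/unvectorize round-trips exactly and every downstream vector is
comparable voxel-for-voxel.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd


class DimensionError(ValueError):
    """Grid shapes of two volumes/masks disagree."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel lattice of all maps in an analysis.

    Parameters
    ----------
    dims
        Voxels per axis (x, y, z); each >= 1.
    voxel_size
        Edge lengths in mm; informational only (no resampling is ever done).
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValidationError(f"dims must be three positive integers, got {self.dims}")
        if any(s <= 0 for s in self.voxel_size):
            raise ValidationError("voxel sizes must be positive")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def affine(self) -> np.ndarray:
        """Diagonal voxel-to-mm affine (no rotation; origin at voxel 0)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff


class BrainMask:
    """Boolean inclusion volume plus the fixed voxel -> vector-position order.

    The scan order is Fortran (first axis fastest); it is deterministic,
    stable across runs, and fingerprinted so models refuse mismatched masks.
    """

    def __init__(self, grid: VolumeGrid, inclusion: np.ndarray):
        inclusion = np.asarray(inclusion, dtype=bool)
        if inclusion.shape != grid.dims:
            raise DimensionError(
                f"inclusion shape {inclusion.shape} does not match grid {grid.dims}"
            )
        if not inclusion.any():
            raise ValidationError("mask must contain at least one in-mask voxel")
        self.grid = grid
        self.inclusion = inclusion
        # positions of in-mask voxels in the x-fastest linear scan
        self._flat_order = np.flatnonzero(inclusion.ravel(order="F"))

    @property
    def n_voxels(self) -> int:
        return int(self._flat_order.size)

    def coordinates(self) -> np.ndarray:
        """(n_voxels, 3) integer voxel coordinates in scan order."""
        return np.column_stack(
            np.unravel_index(self._flat_order, self.grid.dims, order="F")
        )

    def vectorize(self, volume: np.ndarray) -> np.ndarray:
        volume = np.asarray(volume, dtype=float)
        if volume.shape != self.grid.dims:
            raise DimensionError(
                f"volume shape {volume.shape} does not match grid {self.grid.dims}"
            )
        return volume.ravel(order="F")[self._flat_order].copy()

    def unvectorize(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise ValidationError(
                f"expected {self.n_voxels} values, got {values.shape}"
            )
        flat = np.full(self.grid.n_voxels, fill, dtype=float)
        flat[self._flat_order] = values
        return flat.reshape(self.grid.dims, order="F")

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.asarray(self.grid.dims, dtype=np.int64).tobytes())
        h.update(np.packbits(self.inclusion.ravel(order="F")).tobytes())
        return h.hexdigest()[:16]

    def __and__(self, other: "BrainMask") -> "BrainMask":
        if other.grid.dims != self.grid.dims:
            raise DimensionError("conjunction of masks on different grids")
        return BrainMask(self.grid, self.inclusion & other.inclusion)


@dataclass
class ContrastImage:
    """One subject's masked voxel vector for a condition-pair contrast."""

    subject_id: str
    contrast_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("contrast values must be a flat in-mask vector")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(
                f"non-finite voxel values in contrast {self.contrast_label} "
                f"of subject {self.subject_id}"
            )


@dataclass
class SubjectTrialData:
    """Trial-level voxel vectors for one subject (rows = trials)."""

    subject_id: str
    conditions: list[str]
    trial_maps: np.ndarray

    def __post_init__(self) -> None:
        self.trial_maps = np.asarray(self.trial_maps, dtype=float)
        if self.trial_maps.ndim != 2 or self.trial_maps.shape[0] < 2:
            raise ValidationError("trial data needs >= 2 trials, one row each")
        if len(self.conditions) != self.trial_maps.shape[0]:
            raise ValidationError("one condition label per trial required")


@dataclass
class Parcellation:
    """Grid-aligned integer label volume (0 = unlabeled) with a name table."""

    grid: VolumeGrid
    labels: np.ndarray
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.dims:
            raise DimensionError("parcellation labels do not match the grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be integers")
        if self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValidationError(f"labels missing from label_table: {sorted(missing)}")

    def region_labels(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})


# ---------------------------------------------------------------------------
# I/O


def read_volume(path, mask: BrainMask | None = None):
    """Read a 3D NIfTI volume; with a mask, return the in-mask vector.

    Returns the raw 3D array when ``mask`` is None, otherwise the values at
    in-mask voxels in the mask's scan order.  Non-finite values inside the
    mask raise :class:`ValidationError`.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValidationError(f"expected a 3D volume, got shape {data.shape}")
    if mask is None:
        return data
    if data.shape != mask.grid.dims:
        raise DimensionError(
            f"volume shape {data.shape} does not match mask grid {mask.grid.dims}"
        )
    values = mask.vectorize(data)
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"non-finite voxels inside mask in {path}")
    return values


def write_map(values: np.ndarray, mask: BrainMask, path, affine: np.ndarray | None = None):
    """Write an in-mask vector as a NIfTI volume; out-of-mask voxels are 0."""
    volume = mask.unvectorize(np.asarray(values, dtype=float))
    aff = mask.grid.affine() if affine is None else affine
    img = nib.Nifti1Image(volume.astype(np.float64), aff)
    nib.save(img, str(path))
    return path


def write_mask(mask: BrainMask, path, affine: np.ndarray | None = None):
    aff = mask.grid.affine() if affine is None else affine
    img = nib.Nifti1Image(mask.inclusion.astype(np.uint8), aff)
    nib.save(img, str(path))
    return path


def read_mask(path) -> BrainMask:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    grid = VolumeGrid(tuple(int(d) for d in data.shape))
    return BrainMask(grid, data > 0)


def write_parcellation(parc: Parcellation, volume_path, table_path):
    img = nib.Nifti1Image(parc.labels.astype(np.int32), parc.grid.affine())
    nib.save(img, str(volume_path))
    pd.DataFrame(
        {"label": list(parc.label_table), "name": list(parc.label_table.values())}
    ).to_csv(table_path, sep="\t", index=False)


def read_parcellation(volume_path, table_path) -> Parcellation:
    img = nib.load(str(volume_path))
    labels = np.asarray(img.get_fdata()).astype(np.int64)
    grid = VolumeGrid(tuple(int(d) for d in labels.shape))
    table = pd.read_csv(table_path, sep="\t")
    label_table = dict(zip(table["label"].astype(int), table["name"].astype(str)))
    return Parcellation(grid, labels, label_table)


def region_mask(parcellation: Parcellation, labels) -> BrainMask:
    """Mask selecting exactly the voxels whose label is in ``labels``."""
    labels = set(int(l) for l in labels)
    known = set(parcellation.region_labels())
    unknown = labels - known
    if unknown:
        raise ValidationError(f"unknown parcellation labels: {sorted(unknown)}")
    inclusion = np.isin(parcellation.labels, sorted(labels))
    return BrainMask(parcellation.grid, inclusion)
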