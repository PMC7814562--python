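"""Volume I/O, voxel-grid geometry, and mm ↔ voxel-index conversion.

Coordinate conventions
----------------------
* z is the vertical (plant-height) axis; z = 0 mm is the bottom of the
  beakers, which is the height reference for all region boundaries.
* ``origin`` is the physical position (mm) of the *center* of voxel
  (0, 0, 0).
* Voxel ``i`` along an axis with spacing ``s`` and origin ``o`` covers the
  half-open physical interval ``[o + i*s - s/2, o + i*s + s/2)``; a position
  exactly on a boundary belongs to the higher index.  This makes the mm →
  index mapping total over the grid extent and lets stacked regions
  partition the volume with no double counting.

Dynamic volumes are stored as 4D NIfTI-1 (x, y, z, frame) with the voxel
spacing and origin in the header; the frame schedule travels in a JSON
sidecar because NIfTI has no native notion of frame timing.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "FrameSchedule",
    "DynamicImage",
    "LabelVolume",
    "mm_to_voxel_index",
    "voxel_center_mm",
    "load_dynamic_image",
    "save_dynamic_image",
    "load_label_volume",
    "save_label_volume",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular axis-aligned voxel grid in physical millimetres."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.dims) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("grid dims/spacing/origin must be triples")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def extent_mm(self, axis: int) -> tuple[float, float]:
        """Half-open physical extent ``[lo, hi)`` covered along one axis."""
        o, s, d = self.origin[axis], self.spacing[axis], self.dims[axis]
        return (o - s / 2.0, o + (d - 1) * s + s / 2.0)

    def contains_mm(self, position_mm) -> bool:
        return all(
            self.extent_mm(ax)[0] <= float(position_mm[ax]) < self.extent_mm(ax)[1]
            for ax in range(3)
        )


def _axis_index(position: float, origin: float, spacing: float) -> int:
    """Index of the half-open voxel interval containing ``position``.

    Boundary ties resolve to the higher index.
    """
    return int(math.floor((position - origin) / spacing + 0.5))


def mm_to_voxel_index(position_mm, grid: VoxelGrid) -> tuple[int, int, int]:
    """Voxel index of the half-open interval containing a physical point."""
    if not grid.contains_mm(position_mm):
        raise ValueError(
            f"position {tuple(float(p) for p in position_mm)} mm is outside the "
            f"grid extent {[grid.extent_mm(ax) for ax in range(3)]}"
        )
    idx = tuple(
        _axis_index(float(position_mm[ax]), grid.origin[ax], grid.spacing[ax])
        for ax in range(3)
    )
    # boundary float fuzz can only land on the neighbouring index; clip to grid
    return tuple(min(max(i, 0), d - 1) for i, d in zip(idx, grid.dims))


def voxel_center_mm(index, grid: VoxelGrid) -> tuple[float, float, float]:
    """Physical position (mm) of a voxel center."""
    for ax in range(3):
        if not 0 <= int(index[ax]) < grid.dims[ax]:
            raise ValueError(f"voxel index {tuple(index)} outside grid {grid.dims}")
    return tuple(
        grid.origin[ax] + grid.spacing[ax] * int(index[ax]) for ax in range(3)
    )


@dataclass(eq=False)
class FrameSchedule:
    """Contiguous uniform temporal frames, hours since tracer administration."""

    frame_starts: np.ndarray
    frame_duration: float

    def __post_init__(self) -> None:
        self.frame_starts = np.asarray(self.frame_starts, dtype=float)
        self.frame_duration = float(self.frame_duration)
        if self.frame_starts.ndim != 1 or self.frame_starts.size == 0:
            raise ValueError("frame_starts must be a non-empty 1D sequence")
        if self.frame_duration <= 0:
            raise ValueError(f"frame duration must be > 0, got {self.frame_duration}")
        diffs = np.diff(self.frame_starts)
        if np.any(diffs <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if not np.allclose(diffs, self.frame_duration, rtol=0, atol=1e-9):
            raise ValueError("frames must be contiguous: start[i+1] = start[i] + duration")

    @classmethod
    def uniform(cls, n_frames: int, frame_duration: float = 1.0, start: float = 0.0) -> "FrameSchedule":
        return cls(start + frame_duration * np.arange(n_frames), frame_duration)

    @property
    def n_frames(self) -> int:
        return int(self.frame_starts.size)

    @property
    def midpoints(self) -> np.ndarray:
        return self.frame_starts + self.frame_duration / 2.0

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrameSchedule)
            and self.frame_duration == other.frame_duration
            and np.array_equal(self.frame_starts, other.frame_starts)
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "frame_starts_h": self.frame_starts.tolist(),
                    "frame_duration_h": self.frame_duration,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "FrameSchedule":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(np.asarray(obj["frame_starts_h"], dtype=float), obj["frame_duration_h"])


@dataclass(eq=False)
class DynamicImage:
    """4D dynamic volume of activity per voxel (MBq) per frame.

    Voxel values are activities, not concentrations, so ROI sums are direct
    activities in MBq.
    """

    grid: VoxelGrid
    frames: FrameSchedule
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.grid.dims + (self.frames.n_frames,)
        if self.values.shape != expected:
            raise ValueError(
                f"value array shape {self.values.shape} does not match "
                f"grid dims + n_frames {expected}"
            )
        if np.any(self.values < 0):
            raise ValueError("voxel activities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.n_frames

    def frame_totals(self) -> np.ndarray:
        """Total activity (MBq) in the field of view per frame."""
        return self.values.sum(axis=(0, 1, 2))


@dataclass(eq=False)
class LabelVolume:
    """Integer structure labels on a grid, with a legend code → (plant, region).

    Stands in for the CT structural image: region boundaries are identified
    in CT space and carried here as a voxelized partition.  Regions are drawn
    from {solution, root, stem, leaf, reference, background}; the default
    phantom merges solution and roots into a single "root" pool because the
    root-side signal observable in the images includes the beaker solution.
    """

    grid: VoxelGrid
    labels: np.ndarray
    legend: dict[int, tuple[str, str]]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer codes")
        if self.labels.shape != self.grid.dims:
            raise ValueError(
                f"label shape {self.labels.shape} does not match grid {self.grid.dims}"
            )
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"label codes missing from legend: {sorted(missing)}")

    def codes_for(self, plant_id: str | None = None, region: str | None = None) -> list[int]:
        return sorted(
            code
            for code, (pid, reg) in self.legend.items()
            if (plant_id is None or pid == plant_id) and (region is None or reg == region)
        )

    def mask_for(self, plant_id: str | None = None, region: str | None = None) -> np.ndarray:
        codes = self.codes_for(plant_id, region)
        return np.isin(self.labels, codes)

    def plant_ids(self) -> list[str]:
        return sorted({pid for pid, reg in self.legend.values() if reg not in ("background", "reference")})


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_nifti(img) -> VoxelGrid:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return VoxelGrid(img.shape[:3], zooms, origin)


def save_dynamic_image(image: DynamicImage, path) -> None:
    """Write a 4D NIfTI-1 file; values stored as float64 so loading round-trips bit-exactly."""
    nii = nib.Nifti1Image(image.values.astype(np.float64), _affine(image.grid))
    nii.header.set_xyzt_units("mm")
    nib.save(nii, str(path))


def load_dynamic_image(path, schedule: FrameSchedule) -> DynamicImage:
    """Read a 4D NIfTI-1 dynamic series; the frame schedule comes from its sidecar."""
    if not os.path.exists(str(path)):
        raise FileNotFoundError(f"missing file: {path}")
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"non-4D image: {path} has {img.ndim} dimensions")
    if img.shape[3] != schedule.n_frames:
        raise ValueError(
            f"frame-count mismatch: file has {img.shape[3]} volumes, "
            f"schedule has {schedule.n_frames} frames"
        )
    # C-contiguous so reductions run in the same order as on freshly built arrays
    values = np.ascontiguousarray(np.asarray(img.dataobj, dtype=np.float64))
    return DynamicImage(_grid_from_nifti(img), schedule, values)


def save_label_volume(volume: LabelVolume, path) -> None:
    """Write labels as int32 NIfTI-1 plus a ``<path>.legend.json`` sidecar."""
    nii = nib.Nifti1Image(volume.labels.astype(np.int32), _affine(volume.grid))
    nii.header.set_xyzt_units("mm")
    nib.save(nii, str(path))
    legend = {str(code): list(entry) for code, entry in volume.legend.items()}
    with open(str(path) + ".legend.json", "w") as fh:
        json.dump(legend, fh, indent=2)


def load_label_volume(path) -> LabelVolume:
    if not os.path.exists(str(path)):
        raise FileNotFoundError(f"missing file: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"non-3D label image: {path} has {img.ndim} dimensions")
    with open(str(path) + ".legend.json") as fh:
        raw = json.load(fh)
    legend = {int(code): tuple(entry) for code, entry in raw.items()}
    labels = np.asarray(img.dataobj).astype(np.int32)
    return LabelVolume(_grid_from_nifti(img), labels, legend)
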