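"""CT-guided rectangular-prism ROIs in PET voxel space.

Plant anatomy is hard to delineate in the PET images themselves, so region
boundaries (roots, leaves, optionally the stem) are identified as heights in
the CT image, measured from the bottom of the beaker, and converted to PET
voxel indices using the voxel dimensions.  Laterally each plant is bounded
by its isolation cylinder, so every ROI is an axis-aligned 3D rectangular
prism; all prisms of one plant share identical x/y bounds.

Conversion conventions
----------------------
* Vertical (z): region heights partition the plant column.  A region
  spanning [z_bottom, z_top) mm maps to slices ``index(z_bottom) ..
  index(z_top) − 1`` under the half-open voxel convention, so a boundary
  voxel is assigned to the upper region and two touching regions never share
  a slice.
* Lateral (x/y): the cylinder bounding box maps to the inclusive index range
  ``index(min) .. index(max)``, which covers every voxel whose center can
  fall inside the cylinder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .imaging_io import VoxelGrid, _axis_index

__all__ = [
    "RegionHeights",
    "PlantROI",
    "rois_from_heights",
    "roi_mask",
    "roi_from_label_mask",
    "rois_to_json",
    "rois_from_json",
    "heights_from_json",
]


@dataclass(frozen=True)
class RegionHeights:
    """Per-plant region boundaries in mm above the beaker bottom."""

    plant_id: str
    regions: dict[str, tuple[float, float]]  # region -> (z_bottom_mm, z_top_mm)

    def __post_init__(self) -> None:
        for region, (z0, z1) in self.regions.items():
            if z1 <= z0:
                raise ValueError(
                    f"{self.plant_id}/{region}: z_top ({z1}) must exceed z_bottom ({z0})"
                )
        spans = sorted(self.regions.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"{self.plant_id}: regions overlap in z")


@dataclass(frozen=True)
class PlantROI:
    """Axis-aligned prism in PET voxel indices, inclusive bounds."""

    plant_id: str
    region: str
    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]

    def __post_init__(self) -> None:
        for axis in (self.x, self.y, self.z):
            if axis[1] < axis[0] or axis[0] < 0:
                raise ValueError(f"empty or negative ROI bounds: {self}")

    @property
    def n_voxels(self) -> int:
        return (
            (self.x[1] - self.x[0] + 1)
            * (self.y[1] - self.y[0] + 1)
            * (self.z[1] - self.z[0] + 1)
        )

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (
            slice(self.x[0], self.x[1] + 1),
            slice(self.y[0], self.y[1] + 1),
            slice(self.z[0], self.z[1] + 1),
        )

    def within(self, grid: VoxelGrid) -> bool:
        return (
            self.x[1] < grid.dims[0]
            and self.y[1] < grid.dims[1]
            and self.z[1] < grid.dims[2]
        )


def _check_axis_extent(value: float, grid: VoxelGrid, axis: int, what: str) -> None:
    lo, hi = grid.extent_mm(axis)
    if not lo <= value <= hi:
        raise ValueError(f"{what} {value} mm is outside the grid extent [{lo}, {hi}] mm")


def rois_from_heights(
    heights: list[RegionHeights],
    lateral_bounds_mm: dict[str, tuple[tuple[float, float], tuple[float, float]]],
    ct_grid: VoxelGrid,
    pet_grid: VoxelGrid,
) -> list[PlantROI]:
    """Convert CT-space region heights and cylinder bounds to PET prisms.

    ``lateral_bounds_mm`` maps plant_id to ((x_min, x_max), (y_min, y_max))
    in mm.  Heights and lateral bounds must fall inside both grids' extents.
    """
    rois: list[PlantROI] = []
    for h in heights:
        if h.plant_id not in lateral_bounds_mm:
            raise ValueError(f"no lateral bounds for plant {h.plant_id!r}")
        (xmin, xmax), (ymin, ymax) = lateral_bounds_mm[h.plant_id]
        for grid in (ct_grid, pet_grid):
            _check_axis_extent(xmin, grid, 0, "lateral bound")
            _check_axis_extent(xmax, grid, 0, "lateral bound")
            _check_axis_extent(ymin, grid, 1, "lateral bound")
            _check_axis_extent(ymax, grid, 1, "lateral bound")
        x0 = _axis_index(xmin, pet_grid.origin[0], pet_grid.spacing[0])
        x1 = _axis_index(xmax, pet_grid.origin[0], pet_grid.spacing[0])
        y0 = _axis_index(ymin, pet_grid.origin[1], pet_grid.spacing[1])
        y1 = _axis_index(ymax, pet_grid.origin[1], pet_grid.spacing[1])
        x0, x1 = max(x0, 0), min(x1, pet_grid.dims[0] - 1)
        y0, y1 = max(y0, 0), min(y1, pet_grid.dims[1] - 1)
        for region, (zb, zt) in h.regions.items():
            for grid in (ct_grid, pet_grid):
                _check_axis_extent(zb, grid, 2, f"{h.plant_id}/{region} height")
                _check_axis_extent(zt, grid, 2, f"{h.plant_id}/{region} height")
            z0 = _axis_index(zb, pet_grid.origin[2], pet_grid.spacing[2])
            z1 = _axis_index(zt, pet_grid.origin[2], pet_grid.spacing[2]) - 1
            z0 = max(z0, 0)
            z1 = min(z1, pet_grid.dims[2] - 1)
            if z1 < z0:
                raise ValueError(
                    f"empty prism after conversion: {h.plant_id}/{region} "
                    f"heights [{zb}, {zt}] mm span no PET slice"
                )
            rois.append(PlantROI(h.plant_id, region, (x0, x1), (y0, y1), (z0, z1)))
    return rois


def roi_mask(roi: PlantROI, grid: VoxelGrid) -> np.ndarray:
    """Boolean membership array for a prism on a grid."""
    if not roi.within(grid):
        raise ValueError(f"grid mismatch: ROI {roi} exceeds grid dims {grid.dims}")
    mask = np.zeros(grid.dims, dtype=bool)
    mask[roi.slices] = True
    return mask


def roi_from_label_mask(mask: np.ndarray, plant_id: str, region: str) -> PlantROI:
    """Tightest prism enclosing the True voxels of a label mask."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError(f"empty label mask for {plant_id}/{region}")
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    return PlantROI(
        plant_id,
        region,
        (int(lo[0]), int(hi[0])),
        (int(lo[1]), int(hi[1])),
        (int(lo[2]), int(hi[2])),
    )


def rois_to_json(rois: list[PlantROI], path) -> None:
    payload = [
        {
            "plant_id": r.plant_id,
            "region": r.region,
            "x": list(r.x),
            "y": list(r.y),
            "z": list(r.z),
        }
        for r in rois
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def rois_from_json(path) -> list[PlantROI]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        PlantROI(r["plant_id"], r["region"], tuple(r["x"]), tuple(r["y"]), tuple(r["z"]))
        for r in payload
    ]


def heights_from_json(path) -> tuple[list[RegionHeights], dict]:
    """Read region heights plus lateral bounds from one JSON document.

    Format::

        {
          "heights": [{"plant_id": "p1", "region": "roots", "z_mm": [0, 60]}, ...],
          "lateral_bounds_mm": {"p1": {"x_mm": [a, b], "y_mm": [c, d]}, ...}
        }
    """
    with open(path) as fh:
        obj = json.load(fh)
    by_plant: dict[str, dict[str, tuple[float, float]]] = {}
    for row in obj["heights"]:
        by_plant.setdefault(row["plant_id"], {})[row["region"]] = tuple(row["z_mm"])
    heights = [RegionHeights(pid, regions) for pid, regions in by_plant.items()]
    lateral = {
        pid: (tuple(b["x_mm"]), tuple(b["y_mm"]))
        for pid, b in obj["lateral_bounds_mm"].items()
    }
    return heights, lateral
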