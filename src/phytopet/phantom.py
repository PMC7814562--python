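"""Synthetic 4D plant-PET phantom: scene, ²²Na kinetics, attenuation, noise.

The phantom emulates the study conditions of a continuous multi-day scan of
four hydroponic plant groupings imaged simultaneously — high/low nutrient
crossed with presence/absence of the cation-channel inhibitor BaCl₂ — plus a
constant-activity reference source, on a clinical PET/CT-like voxel grid.

Transport model
---------------
Each grouping is a two-pool compartment system.  The root-side pool merges
the beaker solution and the roots (that is what the root ROI of the images
contains), and the shoot pool holds the leaves.  Transfer follows

    dA_leaf/dt = k(t) · A_pool(t),      A_pool = A_total − A_leaf,

with a piecewise-constant rate

    k(t) = k_base · f_nutrient · f_inhibitor · (1 ± a_diurnal),

taking the ``+`` branch when the phase-advanced clock ``t + phase_advance``
falls in a light interval of the 12 h/8 h light schedule.  The closed form

    A_leaf(t) = A_total · (1 − exp(−∫₀ᵗ k(s) ds))

is evaluated exactly by accumulating the integral over light/dark segments.
Physical decay (half-life 2.605 y) is applied at render time, not inside the
compartment bookkeeping, so pool + leaf always sums to the administered dose.

Attenuation is a per-voxel multiplicative survival fraction obtained by
casting rays laterally (±x) through attenuating material; it validates the
correction arithmetic of the analysis, not scanner physics.  Counting noise
is Poisson on expected detected counts with a single scalar sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .decay import NA22_HALF_LIFE_Y, decay_factor
from .imaging_io import DynamicImage, FrameSchedule, LabelVolume, VoxelGrid

__all__ = [
    "LightSchedule",
    "KineticParams",
    "CompartmentSeries",
    "GeometryParams",
    "PhantomSpec",
    "AttenuationMap",
    "GroundTruth",
    "SyntheticDataset",
    "GROUPING_ORDER",
    "uptake_rate_at",
    "simulate_kinetics",
    "build_geometry",
    "render_frames",
    "build_attenuation_map",
    "apply_attenuation",
    "correct_attenuation",
    "add_counting_noise",
    "generate_dataset",
    "default_phantom_spec",
]

#: Grouping order as arranged in the scanner field of view, left to right.
GROUPING_ORDER = (
    "high_no_inhibitor",
    "high_inhibitor",
    "low_no_inhibitor",
    "low_inhibitor",
)


@dataclass(frozen=True)
class LightSchedule:
    """Periodic light/dark schedule (hours).

    The growth protocol uses a 12 h day / 8 h night timer, i.e. a 20-h cycle
    that drifts against the 24-h clock; the periods are therefore free
    parameters rather than fractions of a day.
    """

    period_light: float = 12.0
    period_dark: float = 8.0
    t0: float = 0.0  # start of the first light interval

    def __post_init__(self) -> None:
        if self.period_light <= 0 or self.period_dark <= 0:
            raise ValueError("light and dark periods must both be > 0")

    @property
    def cycle(self) -> float:
        return self.period_light + self.period_dark

    def is_light(self, t_h):
        """Boolean (array) — does time ``t_h`` fall in a light interval?"""
        phase = (np.asarray(t_h, dtype=float) - self.t0) % self.cycle
        return phase < self.period_light

    def transitions_between(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Sorted light↔dark transition times strictly inside (t_lo, t_hi)."""
        n_lo = int(np.floor((t_lo - self.t0) / self.cycle)) - 1
        n_hi = int(np.ceil((t_hi - self.t0) / self.cycle)) + 1
        pts = []
        for n in range(n_lo, n_hi + 1):
            for offset in (0.0, self.period_light):
                t = self.t0 + n * self.cycle + offset
                if t_lo < t < t_hi:
                    pts.append(t)
        return np.asarray(sorted(pts))

    def dark_intervals(self, t_lo: float, t_hi: float) -> list[tuple[float, float]]:
        """Dark intervals clipped to [t_lo, t_hi], for plot shading."""
        out = []
        n = int(np.floor((t_lo - self.t0) / self.cycle)) - 1
        while True:
            d0 = self.t0 + n * self.cycle + self.period_light
            d1 = d0 + self.period_dark
            if d0 >= t_hi:
                break
            if d1 > t_lo:
                out.append((max(d0, t_lo), min(d1, t_hi)))
            n += 1
        return out

    def to_dict(self) -> dict:
        return {
            "period_light_h": self.period_light,
            "period_dark_h": self.period_dark,
            "t0_h": self.t0,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "LightSchedule":
        return cls(obj["period_light_h"], obj["period_dark_h"], obj.get("t0_h", 0.0))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LightSchedule":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class KineticParams:
    """Uptake-rate model parameters for one plant grouping.

    ``f_nutrient`` ≥ 1 encodes the low-nutrient upregulation of sodium
    transport; ``f_inhibitor`` ≤ 1 encodes suppression by BaCl₂;
    ``a_diurnal`` modulates the rate up in light and down in dark;
    ``phase_advance`` shifts the rate transition earlier than the light
    transition (plants anticipating the timer).
    """

    k_base: float = 0.01           # per hour
    f_nutrient: float = 1.0        # ≥ 1 for low-nutrient plants
    f_inhibitor: float = 1.0       # ≤ 1 with BaCl₂ present
    a_diurnal: float = 0.0         # in [0, 1)
    phase_advance: float = 0.0     # hours, ≥ 0
    A_total: float = 1.0           # administered dose, MBq

    def __post_init__(self) -> None:
        if self.k_base < 0:
            raise ValueError("k_base must be >= 0")
        if self.f_nutrient <= 0 or self.f_inhibitor <= 0:
            raise ValueError("treatment factors must be > 0")
        if not 0 <= self.a_diurnal < 1:
            raise ValueError("a_diurnal must lie in [0, 1)")
        if self.phase_advance < 0:
            raise ValueError("phase_advance must be >= 0")
        if self.A_total <= 0:
            raise ValueError("administered activity must be > 0")

    @property
    def k_effective(self) -> float:
        """Treatment-scaled base rate before diurnal modulation, per hour."""
        return self.k_base * self.f_nutrient * self.f_inhibitor


def uptake_rate_at(t_h, params: KineticParams, light: LightSchedule):
    """Piecewise-constant uptake rate k(t), per hour.

    k = k_base·f_nutrient·f_inhibitor·(1 + a) when the phase-advanced clock
    ``t + phase_advance`` is in light, and ·(1 − a) otherwise.
    """
    in_light = light.is_light(np.asarray(t_h, dtype=float) + params.phase_advance)
    k = params.k_effective * np.where(in_light, 1.0 + params.a_diurnal, 1.0 - params.a_diurnal)
    return k if np.ndim(t_h) else float(k)


@dataclass(eq=False)
class CompartmentSeries:
    """Per-frame compartment bookkeeping, before physical decay."""

    t: np.ndarray        # frame midpoints, hours
    A_pool: np.ndarray   # MBq in the root-side pool (solution + roots)
    A_leaf: np.ndarray   # MBq in the shoot pool
    k_true: np.ndarray   # applied rate at each midpoint, per hour
    A_total: float       # administered dose, MBq


def _cumulative_rate_integral(query_t: np.ndarray, params: KineticParams, light: LightSchedule) -> np.ndarray:
    """∫₀ᵗ k(s) ds at each query time, accumulated over light/dark segments.

    The integrand is constant between rate transitions, which occur where the
    phase-advanced clock crosses a light↔dark boundary; the integral is
    therefore a sum of exact segment areas.
    """
    query_t = np.asarray(query_t, dtype=float)
    t_max = float(query_t.max(initial=0.0))
    # rate transitions in plant time: schedule boundaries minus the phase advance
    shifted = light.transitions_between(params.phase_advance, t_max + params.phase_advance)
    breaks = np.concatenate(([0.0], shifted - params.phase_advance, [t_max + 1.0]))
    seg_mid = (breaks[:-1] + breaks[1:]) / 2.0
    seg_k = np.asarray(uptake_rate_at(seg_mid, params, light))
    cum = np.concatenate(([0.0], np.cumsum(seg_k[:-1] * np.diff(breaks[:-1]))))
    j = np.clip(np.searchsorted(breaks, query_t, side="right") - 1, 0, len(seg_k) - 1)
    return cum[j] + seg_k[j] * (query_t - breaks[j])


def simulate_kinetics(params: KineticParams, frames: FrameSchedule, light: LightSchedule) -> CompartmentSeries:
    """Exact two-pool solution reported at frame midpoints.

    A_leaf(t) = A_total·(1 − exp(−∫₀ᵗ k)), A_pool = A_total − A_leaf; decay is
    applied later, at render time, so the two pools always sum to A_total.
    """
    t = frames.midpoints
    K = _cumulative_rate_integral(t, params, light)
    A_leaf = params.A_total * -np.expm1(-K)
    return CompartmentSeries(
        t=t,
        A_pool=params.A_total - A_leaf,
        A_leaf=A_leaf,
        k_true=np.asarray(uptake_rate_at(t, params, light)),
        A_total=params.A_total,
    )


@dataclass(frozen=True)
class GeometryParams:
    """Scene geometry in physical millimetres.

    Each grouping is a solution/root cylinder from z = 0 (beaker bottom) up
    to ``beaker_top_mm``, a thin stem column up to ``stem_top_mm``, and a
    leaf cylinder up to ``leaf_top_mm``, all sharing a lateral center.  The
    default boundary heights are aligned to PET slice boundaries so prism
    ROIs partition each plant column exactly.
    """

    centers_mm: tuple[tuple[float, float], ...]   # (x, y) per grouping
    beaker_radius_mm: float = 8.0
    beaker_top_mm: float = 32.432    # 16 slices of 2.027 mm
    stem_radius_mm: float = 2.0
    stem_top_mm: float = 48.648      # 24 slices
    leaf_radius_mm: float = 8.0
    leaf_top_mm: float = 89.188      # 44 slices
    ref_center_mm: tuple[float, float, float] = (50.88, 12.0, 15.0)
    ref_half_mm: float = 4.0
    ref_activity_MBq: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.beaker_top_mm < self.stem_top_mm < self.leaf_top_mm:
            raise ValueError("region tops must satisfy 0 < beaker < stem < leaf")
        if min(self.beaker_radius_mm, self.stem_radius_mm, self.leaf_radius_mm) <= 0:
            raise ValueError("radii must be > 0")
        if self.ref_activity_MBq <= 0:
            raise ValueError("reference activity must be > 0")


@dataclass(eq=False)
class PhantomSpec:
    """Complete description of a synthetic acquisition."""

    grid: VoxelGrid
    frames: FrameSchedule
    light: LightSchedule
    groupings: dict[str, KineticParams]
    geometry: GeometryParams
    mu_per_mm: float = 0.0096       # water-equivalent attenuation at 511 keV
    sensitivity: float | None = 1e4  # detected counts per MBq·h per voxel; None = noiseless
    stem_fraction: float = 0.0      # fraction of shoot activity rendered in the stem
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_per_mm < 0:
            raise ValueError("attenuation coefficient must be >= 0")
        if self.sensitivity is not None and self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0 (or None for noiseless)")
        if not 0 <= self.stem_fraction <= 1:
            raise ValueError("stem_fraction must lie in [0, 1]")
        if len(self.groupings) != len(self.geometry.centers_mm):
            raise ValueError("one lateral center per grouping is required")

    def to_dict(self) -> dict:
        return {
            "grid": {
                "dims": list(self.grid.dims),
                "spacing_mm": list(self.grid.spacing),
                "origin_mm": list(self.grid.origin),
            },
            "frames": {
                "n_frames": self.frames.n_frames,
                "frame_duration_h": self.frames.frame_duration,
                "start_h": float(self.frames.frame_starts[0]),
            },
            "light": self.light.to_dict(),
            "groupings": {
                name: {
                    "k_base_per_h": p.k_base,
                    "f_nutrient": p.f_nutrient,
                    "f_inhibitor": p.f_inhibitor,
                    "a_diurnal": p.a_diurnal,
                    "phase_advance_h": p.phase_advance,
                    "A_total_MBq": p.A_total,
                }
                for name, p in self.groupings.items()
            },
            "geometry": {
                "centers_mm": [list(c) for c in self.geometry.centers_mm],
                "beaker_radius_mm": self.geometry.beaker_radius_mm,
                "beaker_top_mm": self.geometry.beaker_top_mm,
                "stem_radius_mm": self.geometry.stem_radius_mm,
                "stem_top_mm": self.geometry.stem_top_mm,
                "leaf_radius_mm": self.geometry.leaf_radius_mm,
                "leaf_top_mm": self.geometry.leaf_top_mm,
                "ref_center_mm": list(self.geometry.ref_center_mm),
                "ref_half_mm": self.geometry.ref_half_mm,
                "ref_activity_MBq": self.geometry.ref_activity_MBq,
            },
            "mu_per_mm": self.mu_per_mm,
            "sensitivity": self.sensitivity,
            "stem_fraction": self.stem_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "PhantomSpec":
        g = obj["grid"]
        f = obj["frames"]
        geo = obj["geometry"]
        return cls(
            grid=VoxelGrid(tuple(g["dims"]), tuple(g["spacing_mm"]), tuple(g["origin_mm"])),
            frames=FrameSchedule.uniform(f["n_frames"], f["frame_duration_h"], f.get("start_h", 0.0)),
            light=LightSchedule.from_dict(obj["light"]),
            groupings={
                name: KineticParams(
                    k_base=p["k_base_per_h"],
                    f_nutrient=p["f_nutrient"],
                    f_inhibitor=p["f_inhibitor"],
                    a_diurnal=p["a_diurnal"],
                    phase_advance=p["phase_advance_h"],
                    A_total=p["A_total_MBq"],
                )
                for name, p in obj["groupings"].items()
            },
            geometry=GeometryParams(
                centers_mm=tuple(tuple(c) for c in geo["centers_mm"]),
                beaker_radius_mm=geo["beaker_radius_mm"],
                beaker_top_mm=geo["beaker_top_mm"],
                stem_radius_mm=geo["stem_radius_mm"],
                stem_top_mm=geo["stem_top_mm"],
                leaf_radius_mm=geo["leaf_radius_mm"],
                leaf_top_mm=geo["leaf_top_mm"],
                ref_center_mm=tuple(geo["ref_center_mm"]),
                ref_half_mm=geo["ref_half_mm"],
                ref_activity_MBq=geo["ref_activity_MBq"],
            ),
            mu_per_mm=obj["mu_per_mm"],
            sensitivity=obj["sensitivity"],
            stem_fraction=obj.get("stem_fraction", 0.0),
            seed=obj.get("seed", 0),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_phantom_spec(
    seed: int = 0,
    dims: tuple[int, int, int] = (64, 64, 48),
    spacing: tuple[float, float, float] = (1.59, 1.59, 2.027),
    n_frames: int = 72,
    doses_MBq: tuple[float, float, float, float] = (2.25, 2.09, 2.00, 2.03),
    k_base: float = 0.01,
    f_nutrient_low: float = 1.6,
    f_inhibitor_with: float = 0.5,
    a_diurnal: float = 0.4,
    phase_advance: float = 1.0,
    mu_per_mm: float = 0.0096,
    sensitivity: float | None = 1e4,
) -> PhantomSpec:
    """Four-grouping spec emulating the 72-h acquisition.

    Defaults: PET-like voxels (1.59 × 1.59 mm in-plane, 2.027 mm slices),
    72 one-hour frames, administered doses 2.25/2.09/2.00/2.03 MBq split
    across the four groupings, and a 12 h/8 h light timer starting in light.
    Coarser test grids keep the same ~102 × 102 × 97 mm field of view by
    scaling the spacing with the dims.
    """
    grid = VoxelGrid(dims, spacing, tuple(s / 2.0 for s in spacing))
    extent_x = dims[0] * spacing[0]
    extent_y = dims[1] * spacing[1]
    centers = tuple(
        (extent_x * (2 * i + 1) / 8.0, extent_y / 2.0) for i in range(4)
    )
    factors = {
        "high_no_inhibitor": (1.0, 1.0),
        "high_inhibitor": (1.0, f_inhibitor_with),
        "low_no_inhibitor": (f_nutrient_low, 1.0),
        "low_inhibitor": (f_nutrient_low, f_inhibitor_with),
    }
    groupings = {
        name: KineticParams(
            k_base=k_base,
            f_nutrient=factors[name][0],
            f_inhibitor=factors[name][1],
            a_diurnal=a_diurnal,
            phase_advance=phase_advance,
            A_total=doses_MBq[i],
        )
        for i, name in enumerate(GROUPING_ORDER)
    }
    geometry = GeometryParams(
        centers_mm=centers,
        ref_center_mm=(extent_x / 2.0, 12.0, 15.0),
    )
    return PhantomSpec(
        grid=grid,
        frames=FrameSchedule.uniform(n_frames),
        light=LightSchedule(),
        groupings=groupings,
        geometry=geometry,
        mu_per_mm=mu_per_mm,
        sensitivity=sensitivity,
        seed=seed,
    )


# Region suffix per within-grouping code offset: code = 3*i + offset.
_REGION_OFFSETS = {1: "root", 2: "stem", 3: "leaf"}
REFERENCE_CODE = 99


def build_geometry(spec: PhantomSpec) -> LabelVolume:
    """Voxelize the scene into a disjoint label partition.

    Voxels are assigned by center: a voxel belongs to a cylinder when its
    center lies within the lateral radius and the half-open z interval of
    that region.  Groupings must be laterally disjoint and the reference
    source disjoint from all of them.
    """
    grid = spec.grid
    geo = spec.geometry
    xc = grid.axis_coords(0)[:, None, None]
    yc = grid.axis_coords(1)[None, :, None]
    zc = grid.axis_coords(2)[None, None, :]
    labels = np.zeros(grid.dims, dtype=np.int32)
    legend: dict[int, tuple[str, str]] = {0: ("none", "background")}

    z_bands = {
        "root": (0.0, geo.beaker_top_mm),
        "stem": (geo.beaker_top_mm, geo.stem_top_mm),
        "leaf": (geo.stem_top_mm, geo.leaf_top_mm),
    }
    radii = {
        "root": geo.beaker_radius_mm,
        "stem": geo.stem_radius_mm,
        "leaf": geo.leaf_radius_mm,
    }
    if geo.leaf_top_mm >= grid.extent_mm(2)[1]:
        raise ValueError("geometry exceeds grid: leaf top above the z extent")

    for i, (name, _params) in enumerate(spec.groupings.items()):
        cx, cy = geo.centers_mm[i]
        r_max = max(radii.values())
        if not (
            grid.extent_mm(0)[0] <= cx - r_max and cx + r_max < grid.extent_mm(0)[1]
            and grid.extent_mm(1)[0] <= cy - r_max and cy + r_max < grid.extent_mm(1)[1]
        ):
            raise ValueError(f"geometry exceeds grid: grouping {name!r} cylinder out of lateral extent")
        lateral_sq = (xc - cx) ** 2 + (yc - cy) ** 2
        for offset, region in _REGION_OFFSETS.items():
            code = 3 * i + offset
            r = radii[region]
            z0, z1 = z_bands[region]
            mask = (lateral_sq <= r * r) & (zc >= z0) & (zc < z1)
            if np.any(labels[mask] != 0):
                raise ValueError(f"overlapping groupings at {name!r}/{region}")
            labels[mask] = code
            legend[code] = (name, region)

    rx, ry, rz = geo.ref_center_mm
    ref_mask = (
        (np.abs(xc - rx) <= geo.ref_half_mm)
        & (np.abs(yc - ry) <= geo.ref_half_mm)
        & (np.abs(zc - rz) <= geo.ref_half_mm)
    )
    if not np.any(ref_mask):
        raise ValueError("geometry exceeds grid: reference source contains no voxels")
    if np.any(labels[ref_mask] != 0):
        raise ValueError("reference source overlaps a plant grouping")
    labels[ref_mask] = REFERENCE_CODE
    legend[REFERENCE_CODE] = ("reference", "reference")
    return LabelVolume(grid, labels, legend)


def render_frames(
    labels: LabelVolume,
    series: dict[str, CompartmentSeries],
    spec: PhantomSpec,
) -> DynamicImage:
    """Noiseless forward projection of the compartments onto the voxel grid.

    At each frame the compartment activities, decayed to the frame midpoint,
    are spread uniformly over their voxels; the reference source is rendered
    at its constant (decayed) activity; background stays zero.
    """
    t_mid = spec.frames.midpoints
    d = decay_factor(t_mid)
    values = np.zeros(labels.grid.dims + (spec.frames.n_frames,))

    for name in spec.groupings:
        if name not in series:
            raise ValueError(f"no compartment series for grouping {name!r}")
        cs = series[name]
        if cs.t.size != t_mid.size or not np.allclose(cs.t, t_mid):
            raise ValueError(f"series frames for {name!r} do not match the spec frames")
        shoot = {"leaf": (1.0 - spec.stem_fraction) * cs.A_leaf}
        if spec.stem_fraction > 0:
            shoot["stem"] = spec.stem_fraction * cs.A_leaf
        pools = {"root": cs.A_pool, **shoot}
        for region, activity in pools.items():
            mask = labels.mask_for(name, region)
            n = int(mask.sum())
            if n == 0:
                raise ValueError(f"grouping {name!r} has no {region} voxels")
            values[mask, :] = activity * d / n

    ref_mask = labels.mask_for("reference", "reference")
    n_ref = int(ref_mask.sum())
    values[ref_mask, :] = spec.geometry.ref_activity_MBq * d / n_ref
    return DynamicImage(labels.grid, spec.frames, values)


@dataclass(eq=False)
class AttenuationMap:
    """Per-voxel photon survival fraction in (0, 1]."""

    grid: VoxelGrid
    factor: np.ndarray

    def __post_init__(self) -> None:
        self.factor = np.asarray(self.factor, dtype=float)
        if self.factor.shape != self.grid.dims:
            raise ValueError("attenuation factor shape does not match the grid")
        if np.any(self.factor <= 0) or np.any(self.factor > 1):
            raise ValueError("attenuation factors must lie in (0, 1]")


def build_attenuation_map(labels: LabelVolume, mu_per_mm: float) -> AttenuationMap:
    """Survival fractions by lateral ray casting through attenuating material.

    Attenuating material is the solution/root pool (water-filled beakers);
    everything else is treated as air.  For each voxel the water-equivalent
    path is summed along +x and −x to the lateral grid faces — counting half
    the voxel's own thickness when the voxel itself attenuates — and the
    smaller of the two paths sets factor = exp(−mu · path_mm).
    """
    if mu_per_mm < 0:
        raise ValueError("attenuation coefficient must be >= 0")
    material = labels.mask_for(region="root").astype(float)
    sx = labels.grid.spacing[0]
    cum = np.cumsum(material, axis=0)
    total = cum[-1:, :, :]
    path_minus = (cum - material) + 0.5 * material          # voxels toward -x face
    path_plus = (total - cum) + 0.5 * material              # voxels toward +x face
    path_mm = sx * np.minimum(path_minus, path_plus)
    return AttenuationMap(labels.grid, np.exp(-mu_per_mm * path_mm))


def apply_attenuation(image: DynamicImage, attn: AttenuationMap) -> DynamicImage:
    """Voxelwise attenuation of every frame."""
    if image.grid != attn.grid:
        raise ValueError("grid mismatch between image and attenuation map")
    return DynamicImage(image.grid, image.frames, image.values * attn.factor[..., None])


def correct_attenuation(image: DynamicImage, attn: AttenuationMap) -> DynamicImage:
    """Exact inverse of :func:`apply_attenuation` (division by the same map)."""
    if image.grid != attn.grid:
        raise ValueError("grid mismatch between image and attenuation map")
    return DynamicImage(image.grid, image.frames, image.values / attn.factor[..., None])


def add_counting_noise(image: DynamicImage, sensitivity: float | None, seed: int) -> DynamicImage:
    """Poisson counting noise at a scalar sensitivity (counts per MBq·h per voxel).

    Each voxel-frame activity v becomes Poisson(v·sensitivity·Δt)/(sensitivity·Δt);
    ``sensitivity=None`` (or inf) returns a noiseless copy.  Deterministic
    given the seed.
    """
    if sensitivity is None or np.isinf(sensitivity):
        return DynamicImage(image.grid, image.frames, image.values.copy())
    if sensitivity <= 0:
        raise ValueError("sensitivity must be > 0")
    scale = sensitivity * image.frames.frame_duration
    rng = np.random.default_rng(seed)
    counts = rng.poisson(image.values * scale)
    return DynamicImage(image.grid, image.frames, counts / scale)


@dataclass(eq=False)
class GroundTruth:
    """Bookkeeping attached to a synthetic dataset."""

    series: dict[str, CompartmentSeries]
    params: dict[str, KineticParams]
    doses_MBq: dict[str, float]
    reference_activity_MBq: float
    noiseless: DynamicImage


@dataclass(eq=False)
class SyntheticDataset:
    """Paired corrected/uncorrected dynamic images with full ground truth."""

    pet_corrected: DynamicImage
    pet_uncorrected: DynamicImage
    labels: LabelVolume
    attenuation: AttenuationMap
    truth: GroundTruth


def generate_dataset(spec: PhantomSpec) -> SyntheticDataset:
    """Full forward simulation.

    The measured (uncorrected) image is Poisson noise applied to the
    attenuated noiseless render; the corrected image divides the *same*
    realization by the true attenuation map, mirroring CT-based correction
    with a perfectly known map.  Changing the seed changes the noise but
    never the underlying truth series.
    """
    labels = build_geometry(spec)
    series = {
        name: simulate_kinetics(params, spec.frames, spec.light)
        for name, params in spec.groupings.items()
    }
    noiseless = render_frames(labels, series, spec)
    attn = build_attenuation_map(labels, spec.mu_per_mm)
    attenuated = apply_attenuation(noiseless, attn)
    measured = add_counting_noise(attenuated, spec.sensitivity, spec.seed)
    corrected = correct_attenuation(measured, attn)
    truth = GroundTruth(
        series=series,
        params=dict(spec.groupings),
        doses_MBq={name: p.A_total for name, p in spec.groupings.items()},
        reference_activity_MBq=spec.geometry.ref_activity_MBq,
        noiseless=noiseless,
    )
    return SyntheticDataset(corrected, measured, labels, attn, truth)
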