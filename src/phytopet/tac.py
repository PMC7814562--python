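"""Time-activity curves: extraction, decay correction, normalization, rates.

The analysis chain mirrors the quantitative image analysis of the study:
ROI activity is the sum over the prism's voxels at each frame; per-plant
relative radioactivity divides each region by the plant's total at the same
frame; rates of change are first central differences on the uniform 1-h
frame grid (one-sided at the endpoints); and the per-frame uptake-rate
estimate divides the leaf rate by the root-side ratio, inverting the
two-pool transport model dR_leaf/dt = k·R_pool.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .decay import NA22_HALF_LIFE_Y, decay_correction_factor
from .imaging_io import DynamicImage
from .roi import PlantROI

__all__ = [
    "TAC",
    "RelativeTAC",
    "RateCurve",
    "UptakeRateEstimate",
    "extract_tac",
    "decay_correct",
    "normalize",
    "rate_of_change",
    "estimate_uptake_rate",
    "curves_to_dataframe",
]


@dataclass(eq=False)
class TAC:
    """Absolute ROI activity per frame, MBq."""

    plant_id: str
    region: str
    t: np.ndarray          # frame midpoints, hours
    A: np.ndarray          # MBq
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.t.shape != self.A.shape or self.t.ndim != 1:
            raise ValueError("t and A must be 1D arrays of equal length")
        if np.any(self.A < 0):
            raise ValueError("ROI activities must be non-negative")


@dataclass(eq=False)
class RelativeTAC:
    """Region activity as a fraction of the plant total at each frame."""

    plant_id: str
    region: str
    t: np.ndarray
    R: np.ndarray
    denominator_regions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.t.shape != self.R.shape or self.t.ndim != 1:
            raise ValueError("t and R must be 1D arrays of equal length")
        if np.any(self.R < -1e-12) or np.any(self.R > 1 + 1e-12):
            raise ValueError("ratios must lie in [0, 1]")


@dataclass(eq=False)
class RateCurve:
    """First-difference derivative of a relative TAC, per hour."""

    plant_id: str
    region: str
    t: np.ndarray
    dRdt: np.ndarray
    endpoint_method: str = "one_sided_first_difference"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dRdt = np.asarray(self.dRdt, dtype=float)
        if self.t.shape != self.dRdt.shape or self.t.ndim != 1:
            raise ValueError("t and dRdt must be 1D arrays of equal length")


@dataclass(eq=False)
class UptakeRateEstimate:
    """Per-frame uptake-rate estimate k̂ at interior frames, per hour.

    ``valid`` flags frames where the root-side ratio exceeded the floor ε;
    k̂ is NaN elsewhere.
    """

    plant_id: str
    t: np.ndarray
    k_hat: np.ndarray
    valid: np.ndarray
    eps: float


def extract_tac(image: DynamicImage, roi: PlantROI) -> TAC:
    """Sum the prism's voxels at every frame."""
    if not roi.within(image.grid):
        raise ValueError(f"grid mismatch: ROI {roi} exceeds image grid {image.grid.dims}")
    A = image.values[roi.slices].sum(axis=(0, 1, 2))
    return TAC(roi.plant_id, roi.region, image.frames.midpoints, A, decay_corrected=False)


def decay_correct(
    tac: TAC,
    half_life_y: float = NA22_HALF_LIFE_Y,
    t_ref_h: float = 0.0,
) -> TAC:
    """Refer activities to ``t_ref_h`` by multiplying with 2^((t − t_ref)/T½)."""
    if half_life_y <= 0:
        raise ValueError(f"non-positive half-life: {half_life_y}")
    factor = decay_correction_factor(tac.t - t_ref_h, half_life_y)
    return TAC(tac.plant_id, tac.region, tac.t, tac.A * factor, decay_corrected=True)


def normalize(tacs: list[TAC]) -> list[RelativeTAC]:
    """Per-frame ratios R_region = A_region / Σ_regions A for one plant.

    All TACs must belong to the same plant and share the frame schedule; the
    denominator is the sum over the supplied regions, recorded on each
    result so the composition of the plant total is auditable.
    """
    if not tacs:
        raise ValueError("no TACs to normalize")
    plant = tacs[0].plant_id
    t = tacs[0].t
    for tc in tacs[1:]:
        if tc.plant_id != plant:
            raise ValueError(f"mixed plants in normalize: {plant!r} vs {tc.plant_id!r}")
        if tc.t.shape != t.shape or not np.allclose(tc.t, t):
            raise ValueError("TACs must share the frame schedule")
    total = np.sum([tc.A for tc in tacs], axis=0)
    zero = np.nonzero(total <= 0)[0]
    if zero.size:
        raise ValueError(f"zero total activity at frame {int(zero[0])}")
    regions = tuple(sorted(tc.region for tc in tacs))
    return [
        RelativeTAC(plant, tc.region, t, tc.A / total, denominator_regions=regions)
        for tc in tacs
    ]


def rate_of_change(rel: RelativeTAC) -> RateCurve:
    """First central differences at interior frames, one-sided at the ends."""
    n = rel.t.size
    if n < 3:
        raise ValueError(f"need at least 3 frames for a rate curve, got {n}")
    steps = np.diff(rel.t)
    h = steps[0]
    if not np.allclose(steps, h, rtol=0, atol=1e-9):
        raise ValueError("non-uniform frame spacing")
    dRdt = np.empty(n)
    dRdt[1:-1] = (rel.R[2:] - rel.R[:-2]) / (2.0 * h)
    dRdt[0] = (rel.R[1] - rel.R[0]) / h
    dRdt[-1] = (rel.R[-1] - rel.R[-2]) / h
    return RateCurve(rel.plant_id, rel.region, rel.t, dRdt)


def estimate_uptake_rate(
    rate_leaf: RateCurve,
    rel_root: RelativeTAC,
    eps: float = 0.05,
) -> UptakeRateEstimate:
    """k̂(t) = dR_leaf/dt / R_root at interior frames.

    Frames where the root-side ratio has fallen to ≤ ε are flagged invalid
    (the estimator blows up as the pool empties) and carry NaN.
    """
    if rate_leaf.plant_id != rel_root.plant_id:
        raise ValueError("leaf rate and root ratio must belong to the same plant")
    if rate_leaf.t.shape != rel_root.t.shape or not np.allclose(rate_leaf.t, rel_root.t):
        raise ValueError("leaf rate and root ratio must share frames")
    interior = slice(1, -1)
    t = rate_leaf.t[interior]
    denom = rel_root.R[interior]
    valid = denom > eps
    if not np.any(valid):
        raise ValueError(f"no evaluable frames: root ratio never exceeds eps={eps}")
    k_hat = np.full(t.shape, np.nan)
    k_hat[valid] = rate_leaf.dRdt[interior][valid] / denom[valid]
    return UptakeRateEstimate(rate_leaf.plant_id, t, k_hat, valid, eps)


def uptake_rate_curve(est: UptakeRateEstimate) -> RateCurve:
    """Full-length rate curve carrying k̂, NaN at endpoints and invalid frames.

    The uptake-rate estimate is trend-free under constant kinetics (the
    pool-depletion envelope divides out), which makes it the right series
    for the circular-shift light/dark test; the endpoint frames, where no
    central difference exists, are NaN and are skipped by that test.
    """
    n = est.t.size + 2
    t = np.empty(n)
    h = est.t[1] - est.t[0] if est.t.size > 1 else 1.0
    t[1:-1] = est.t
    t[0] = est.t[0] - h
    t[-1] = est.t[-1] + h
    values = np.concatenate(([np.nan], est.k_hat, [np.nan]))
    return RateCurve(est.plant_id, "uptake_rate", t, values)


def curves_to_dataframe(curves: list) -> pd.DataFrame:
    """Tidy table (plant_id, region, kind, frame, t_h, value) for CSV export."""
    rows = []
    for c in curves:
        if isinstance(c, TAC):
            kind, values = ("tac_decay_corrected" if c.decay_corrected else "tac"), c.A
        elif isinstance(c, RelativeTAC):
            kind, values = "ratio", c.R
        elif isinstance(c, RateCurve):
            kind, values = "rate", c.dRdt
        else:
            raise TypeError(f"unsupported curve type: {type(c).__name__}")
        for i, (t, v) in enumerate(zip(c.t, values)):
            rows.append(
                {
                    "plant_id": c.plant_id,
                    "region": c.region,
                    "kind": kind,
                    "frame": i,
                    "t_h": t,
                    "value": v,
                }
            )
    return pd.DataFrame(rows, columns=["plant_id", "region", "kind", "frame", "t_h", "value"])
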