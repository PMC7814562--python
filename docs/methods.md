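# Methods

This note documents the models, conventions and design choices behind
`phytopet`: what the synthetic phantom emulates, how the analysis chain is
defined numerically, and what the validation on synthetic data does and does
not demonstrate about real scanner data.

## Study conditions emulated by the phantom

The phantom reproduces the conditions of a continuous multi-day dynamic
PET/CT acquisition of hydroponic plants on a clinical scanner:

* **Four plant groupings scanned simultaneously**, arranged left to right as
  high nutrient without inhibitor, high nutrient with BaCl₂, low nutrient
  without inhibitor, low nutrient with BaCl₂. Default administered doses are
  2.25, 2.09, 2.00 and 2.03 MBq of ²²Na divided across the four beakers.
* **72 contiguous one-hour frames**, each voxel value an activity in MBq
  (not a concentration), so ROI sums are direct activities.
* **PET-like voxels** of 1.59 × 1.59 mm in-plane and 2.027 mm slice
  thickness on a 64 × 64 × 48 default grid (~102 × 102 × 97 mm field of
  view); CT-space inputs are treated as a 0.98 mm isotropic grid over the
  same extent. Coarser test grids halve the resolution but keep the field of
  view, so all physical geometry is unchanged.
* **A 12 h day / 8 h night light timer** starting in light. Note the 20-h
  cycle is taken verbatim as configured periods and deliberately not forced
  to a 24-h day.
* **A constant-activity reference source** (default 1 MBq) in the field of
  view, used by the drift QC.
* **²²Na physical decay** with half-life 2.605 y, under the fixed convention
  1 y = 365.25 d = 8766 h (the 72-h decay factor is ≈ 0.9978, a 0.22 %
  effect, modelled exactly).

## Transport model

Each grouping is a two-pool compartment system. The root-side pool merges
the beaker solution and roots because that is what the root ROI of the
images physically contains; the observable root-side signal is therefore the
merged pool, and a finer solution → root → shoot chain is intentionally out
of scope. Transfer to the shoot pool follows

    dA_leaf/dt = k(t)·A_pool,  A_pool = A_total − A_leaf,  A_leaf(0) = 0,

with the piecewise-constant rate

    k(t) = k_base · f_nutrient · f_inhibitor · (1 + a_diurnal)   (light)
         = k_base · f_nutrient · f_inhibitor · (1 − a_diurnal)   (dark),

where the light/dark state is read from the phase-advanced clock
`t + phase_advance`, so a positive `phase_advance` makes the rate transition
anticipate the light transition. The solution is computed in closed form,
`A_leaf(t) = A_total·(1 − exp(−∫₀ᵗ k))`, with the integral accumulated
exactly over the light/dark segments; the test suite verifies agreement with
an independent high-order ODE integration to better than 1e−8 relative.
Decay is applied only at render time, so pool + leaf equals the administered
dose at every frame by construction.

Default parameters (all configurable):

| parameter | default | meaning |
|---|---|---|
| `k_base` | 0.01 /h | baseline uptake-rate constant |
| `f_nutrient` | 1.0 high / 1.6 low | low-nutrient upregulation of uptake |
| `f_inhibitor` | 1.0 without / 0.5 with | BaCl₂ suppression of uptake |
| `a_diurnal` | 0.4 | relative light/dark rate modulation |
| `phase_advance` | 1.0 h | anticipation of the light transition |
| `sensitivity` | 1e4 counts/(MBq·h·voxel) | Poisson counting statistics |
| `mu_per_mm` | 0.0096 /mm | water-equivalent attenuation at 511 keV |

The treatment factors are calibration choices that produce curve shapes
qualitatively matching upregulated uptake under nutrient deprivation and
suppressed uptake under channel inhibition; they are configuration, not
measured values. With the default sensitivity, a plant ROI collects on the
order of 2×10⁴ expected counts per frame and the reference source 10⁴.

**Stem activity.** The stem region exists in the scene but renders no
activity by default (`stem_fraction = 0`): the analysis concerns roots and
leaves, and the in-transit stem content is negligible on the hour scale.

**Attenuation** is a per-voxel multiplicative survival fraction obtained by
casting rays along ±x through attenuating material (the water-filled
beakers), taking the shorter of the two lateral paths and counting half the
thickness of an attenuating voxel itself. This validates the correction
*arithmetic* and the consequences of omitting it — the reproducible core of
comparing corrected/uncorrected totals against a known dose — and makes no
claim about line-of-response physics, scatter or randoms. The "corrected"
image divides the measured (noisy, attenuated) image by the true map, i.e.
correction with a perfectly known attenuation map; real CT-derived maps add
registration and conversion errors the phantom does not model, which is why
a real scanner can slightly overestimate the truth while the phantom cannot.

**Counting noise** is Poisson on expected detected counts with a single
scalar sensitivity, applied to the attenuated image; one realization serves
both image variants so that correction acts on the same measurement.

## Analysis conventions

* **Voxel model.** A voxel covers the half-open physical interval centred on
  its centre; a position exactly on a boundary belongs to the higher index.
  This makes mm → index total and lets stacked regions partition the plant
  column with no double counting.
* **ROIs** are axis-aligned prisms: vertical bounds from region heights
  (measured from the beaker bottom, converted to PET slices under the
  half-open rule so a boundary slice goes to the upper region), lateral
  bounds from the isolation-cylinder bounding box (inclusive, so the prism
  covers every voxel whose centre can lie in the cylinder). All prisms of
  one plant share x/y bounds exactly. The default phantom geometry aligns
  region boundaries with PET slice edges so the prisms partition each plant
  column exactly; arbitrary heights simply inherit the boundary rule.
* **Frame timestamps** are frame midpoints (start + duration/2).
* **Decay correction** refers activities to tracer administration (t = 0).
  Ratios are insensitive to it, but absolute totals and the reference-drift
  check require it.
* **Rates** are first central differences at interior frames and one-sided
  first differences at the two endpoints, tagged as such.
* **Uptake-rate estimate.** `k̂(t) = (dR_leaf/dt)/R_root` inverts the
  two-pool model frame by frame. Frames where `R_root ≤ ε` (default 0.05)
  are flagged invalid and excluded — the estimator diverges as the pool
  empties. Central differencing biases `k̂` by the factor `sinh(kh)/(kh)`
  (≈ 2×10⁻⁵ relative at k = 0.01/h, h = 1 h), negligible against noise.
* **Normalization denominator** is the sum of the plant's analyzed regions
  (roots + leaves by default, + stem when defined); the composition is
  recorded on every output so the meaning of "total" is auditable.

## Diurnal inference

Uptake-rate series are autocorrelated, so frame-label permutation would be
anticonservative. The null instead rotates the light mask through all
`n_frames` circular shifts (exhaustive, no sampling, no seed), computing
`D = mean(series | light) − mean(series | dark)` over interior frames for
each rotation; `p = #{s: |D_s| ≥ |D_obs|}/n`, two-sided, with the identity
shift counting itself so `p ≥ 1/n` (1/72 ≈ 0.014 at 72 frames).

The series tested is `k̂`, not the raw leaf rate curve. The raw `dR/dt`
carries the deterministic pool-depletion envelope (it decays as the pool
empties even at constant k), and that trend dominates the shift distribution:
measured on null phantoms, the plain-rate test's p-values concentrated far
from uniform (never below 0.36; rejection rate 0 at the 5 % level) and on
diurnal phantoms the trend cost most of the power. `k̂` divides the envelope
out and is flat under the null, restoring calibration: measured type-I rate
0.04 at p ≤ 0.05 over 100 null phantoms and power 1.0 over 20 diurnal
phantoms at default noise.

Transition frames — whose central-difference window straddles a light/dark
boundary — mix the two rates. They stay in the test statistic (the test is
about the alignment, and every rotation is affected equally) but are
excluded when estimating the light/dark rate *ratio*, which on noiseless
data then recovers `(1+a)/(1−a)` to a few parts in 10⁴.

**Anticipation** is reported descriptively, not tested: `D` is recomputed
with the mask advanced by δ ∈ {0, 0.5, …, 4} h and the scan's argmax is the
anticipation estimate. Frame-midpoint classification quantizes the scan to
half-frame steps, so a 1-h generated advance appears as a plateau over
δ ∈ {0.5, 1.0}.

## Quality control and validation

* **Attenuation-correction validation** compares, per grouping, the
  decay-corrected whole-grouping prism total (beaker included) at the final
  frame against the administered dose, for both image variants. With the
  exact map the corrected estimate matches the dose to float precision
  noiselessly (< 1 % is asserted); the uncorrected estimate falls strictly
  below the dose whenever any activity sits inside attenuating material.
* **Reference drift.** The reference TAC is decay-corrected and its maximum
  relative deviation from its mean is compared to a threshold (default 5 %).
  The comparison is boundary-inclusive with a 1e−9 relative guard so that an
  exactly-threshold drift (e.g. a symmetric 10 % ramp, whose maximum
  deviation is exactly half its span) deterministically fails.

## Problem sizes

Simulation-heavy checks run on a half-resolution grid (32 × 32 × 24 voxels
at 3.18 × 3.18 × 4.054 mm) that preserves the physical field of view and
geometry, with the full conservation check run once at the default
64 × 64 × 48 grid; ensembles reuse one noiseless render and redraw only the
Poisson noise per seed. These sizes were chosen so the whole validation
cycle completes in minutes on a single core while every check still runs at
the full 72-frame duration.

## What passing tests do and do not show

The phantom validates the *analysis*: geometry conversion, conservation,
estimator consistency, test calibration and the correction arithmetic. It
does not model scanner physics (line-of-response attenuation, scatter,
randoms, PSF/TOF reconstruction, partial-volume spill between thin plant
tissues and background), plant growth over the scan, spatial heterogeneity
within a compartment, or calibration bias of real scanners. Agreement on the
phantom therefore certifies the pipeline's correctness given its model
assumptions, not the accuracy of any particular scanner's output.

## Known limitations

* The two-pool model has no efflux (shoot → root return) and no explicit
  stem compartment; `k̂` is an instantaneous transfer-rate estimate, not a
  compartmental fit.
* The diurnal test needs enough frames for a meaningful shift distribution
  (p ≥ 1/n); short series cannot reach conventional significance.
* ROIs are rectangular prisms by design; anatomical segmentation and
  partial-volume correction are out of scope.
* Attenuation correction uses the simulation's own map; mis-registration
  and CT-to-511-keV conversion errors are not modelled.
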