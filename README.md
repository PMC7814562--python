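# phytopet

Quantitative analysis of continuous multi-day dynamic PET/CT scans of whole
plants, built around sodium-22 (²²Na, half-life 2.605 y) transport imaging in
hydroponically grown plants on a clinical scanner. The package covers the
full analysis chain — CT-guided prism ROIs, time-activity curves, per-plant
normalization, uptake-rate estimation, diurnal light/dark inference and
attenuation-correction validation — plus a synthetic 4D phantom generator so
every stage can be exercised and validated without scanner data.

It is aimed at plant physiologists and imaging scientists who want to
quantify ion-transport dynamics from dynamic PET series (NIfTI-1) and at
method developers who need a controlled 4D ground truth.

## The model

Each plant grouping is a two-pool compartment system: a root-side pool
`A_pool` (beaker solution + roots, which is what the root ROI of the images
contains) feeding a shoot pool `A_leaf`,

```
dA_leaf/dt = k(t) · A_pool(t),   A_pool = A_total − A_leaf,
k(t) = k_base · f_nutrient · f_inhibitor · (1 ± a_diurnal),
```

where the rate takes the `+` branch when the phase-advanced clock
`t + phase_advance` falls in a light interval of the 12 h day / 8 h night
timer. `f_nutrient ≥ 1` encodes the low-nutrient upregulation of sodium
uptake, `f_inhibitor ≤ 1` the suppression by the cation-channel inhibitor
BaCl₂, and `phase_advance` lets the rate transition anticipate the light
transition. The solution is evaluated in closed form,
`A_leaf(t) = A_total·(1 − exp(−∫₀ᵗ k))`, with the integral accumulated
exactly over light/dark segments.

On the analysis side, ROI activity is the voxel sum of an axis-aligned prism
whose vertical bounds come from region heights measured in CT space; the
relative radioactivity `R_region(t) = A_region / Σ_regions A` is differenced
centrally to a rate curve, and the per-frame uptake rate is recovered as
`k̂ = (dR_leaf/dt) / R_root`. Light/dark differences in `k̂` are tested with
an exhaustive circular-shift permutation of the light mask, which preserves
the autocorrelation of both the series and the mask.

## Worked example

```python
import phytopet as pp

# four-grouping synthetic acquisition: 72 one-hour frames, 12 h/8 h light timer
spec = pp.default_phantom_spec(seed=1)
result = pp.run_pipeline(pp.RunConfig(out_dir="out", phantom_spec=spec, seed=1))

print(result.ac.table[["grouping", "ground_truth_MBq", "est_with_MBq", "est_without_MBq"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))
for plant, res in result.diurnal.items():
    print(f"{plant}: D={res.D:+.5f}/h, p={res.p:.3f}")
print(f"reference drift: {result.drift.max_rel_dev:.2%} (pass={result.drift.passed})")
```

prints

```
         grouping  ground_truth_MBq  est_with_MBq  est_without_MBq
high_no_inhibitor              2.25          2.26             2.20
   high_inhibitor              2.09          2.09             1.85
 low_no_inhibitor              2.00          1.99             1.90
    low_inhibitor              2.03          2.04             1.98
high_no_inhibitor: D=+0.00689/h, p=0.014
high_inhibitor: D=+0.00324/h, p=0.028
low_no_inhibitor: D=+0.01133/h, p=0.028
low_inhibitor: D=+0.00510/h, p=0.028
reference drift: 2.04% (pass=True)
```

Reading the output: with the (exactly known) attenuation map applied in the
correction, the estimated total radioactivity per grouping recovers the
administered dose to within noise, while the uncorrected estimates fall
strictly below it — photons emitted inside the water-filled beakers are
absorbed on the way out. Every grouping shows a positive light−dark
difference `D` in the uptake rate with permutation `p ≤ 0.05` (the minimum
attainable p over 72 circular shifts is 1/72 ≈ 0.014), and the
constant-activity reference source stays within the 5 % drift threshold.
`out/` also receives tidy CSV curves, the uptake-rate table, an anticipation
phase scan, ratio/rate figure panels with dark-period shading, and a run
manifest.

The same analysis runs on saved data (`pet.nii.gz` + `frames.json` +
`rois.json` + `light.json`) through `pp.RunConfig(pet_path=..., ...)`, or
from the shell:

```
phytopet simulate --out out/ --seed 1
phytopet analyze --pet out/pet_corrected.nii.gz --schedule out/frames.json \
    --rois out/rois.json --light out/light.json --out reanalysis/
phytopet validate-ac --seed 1
phytopet qc --pet out/pet_corrected.nii.gz --schedule out/frames.json --rois out/rois.json
```

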