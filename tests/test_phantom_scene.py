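import dataclasses

import numpy as np
import pytest

import phytopet as pp
from phytopet.decay import decay_factor
from phytopet.imaging_io import FrameSchedule, LabelVolume, VoxelGrid
from phytopet.phantom import (
    AttenuationMap,
    add_counting_noise,
    apply_attenuation,
    build_attenuation_map,
    build_geometry,
    correct_attenuation,
    generate_dataset,
    render_frames,
    simulate_kinetics,
)

from conftest import coarse_spec


class TestGeometry:
    def test_legend_has_all_regions(self):
        labels = build_geometry(coarse_spec())
        regions = [entry for entry in labels.legend.values()]
        assert len(labels.legend) == 4 * 3 + 2  # 4 groupings x 3 regions + ref + background
        assert sum(1 for _, reg in regions if reg == "root") == 4
        assert sum(1 for _, reg in regions if reg == "leaf") == 4
        assert ("reference", "reference") in regions

    def test_cylinder_volume_close_to_analytic(self):
        # fine in-plane sampling: r = 8 mm is ~5 voxels at 1.59 mm
        spec = pp.default_phantom_spec()
        labels = build_geometry(spec)
        vol = labels.mask_for("high_no_inhibitor", "root").sum() * labels.grid.voxel_volume_mm3
        geo = spec.geometry
        analytic = np.pi * geo.beaker_radius_mm**2 * geo.beaker_top_mm
        assert vol == pytest.approx(analytic, rel=0.05)

    def test_labels_partition_the_volume(self):
        labels = build_geometry(coarse_spec())
        assert set(np.unique(labels.labels)) <= set(labels.legend)
        # by construction a single integer code per voxel; regions disjoint
        n_labeled = (labels.labels > 0).sum()
        n_by_region = sum(
            labels.mask_for(pid, reg).sum()
            for code, (pid, reg) in labels.legend.items()
            if code != 0
        )
        assert n_labeled == n_by_region

    def test_overlapping_groupings_rejected(self):
        spec = coarse_spec()
        geo = dataclasses.replace(
            spec.geometry, centers_mm=(spec.geometry.centers_mm[0],) * 4
        )
        with pytest.raises(ValueError, match="overlap"):
            build_geometry(dataclasses.replace(spec, geometry=geo))

    def test_geometry_exceeding_grid_rejected(self):
        spec = coarse_spec()
        centers = list(spec.geometry.centers_mm)
        centers[0] = (1.0, centers[0][1])  # cylinder would leave the grid
        geo = dataclasses.replace(spec.geometry, centers_mm=tuple(centers))
        with pytest.raises(ValueError, match="exceeds grid"):
            build_geometry(dataclasses.replace(spec, geometry=geo))


class TestRendering:
    def test_frame_totals_conserve_decayed_activity(self, diurnal_noiseless):
        spec = diurnal_noiseless.spec
        admin = sum(spec.groupings[g].A_total for g in spec.groupings)
        admin += spec.geometry.ref_activity_MBq
        expected = admin * decay_factor(spec.frames.midpoints)
        totals = diurnal_noiseless.noiseless.frame_totals()
        assert np.allclose(totals, expected, rtol=1e-12)

    def test_zero_activity_compartment_renders_to_zero(self):
        spec = coarse_spec(sensitivity=None)
        zero = dataclasses.replace(spec.groupings["high_no_inhibitor"], k_base=0.0)
        spec.groupings["high_no_inhibitor"] = zero
        labels = build_geometry(spec)
        series = {n: simulate_kinetics(p, spec.frames, spec.light) for n, p in spec.groupings.items()}
        img = render_frames(labels, series, spec)
        assert not img.values[labels.mask_for("high_no_inhibitor", "leaf")].any()

    def test_rendering_is_linear_in_dose(self):
        spec = coarse_spec(sensitivity=None, n_frames=6)
        spec2 = coarse_spec(sensitivity=None, n_frames=6,
                            doses_MBq=(4.50, 4.18, 4.00, 4.06))
        geo2 = dataclasses.replace(spec2.geometry, ref_activity_MBq=2.0)
        spec2 = dataclasses.replace(spec2, geometry=geo2)
        labels = build_geometry(spec)
        s1 = {n: simulate_kinetics(p, spec.frames, spec.light) for n, p in spec.groupings.items()}
        s2 = {n: simulate_kinetics(p, spec2.frames, spec2.light) for n, p in spec2.groupings.items()}
        img1 = render_frames(labels, s1, spec)
        img2 = render_frames(labels, s2, spec2)
        assert np.allclose(img2.values, 2.0 * img1.values, rtol=1e-12)


class TestAttenuation:
    def test_zero_mu_means_no_attenuation(self):
        labels = build_geometry(coarse_spec())
        attn = build_attenuation_map(labels, 0.0)
        assert np.all(attn.factor == 1.0)

    def test_empty_path_voxel_has_unit_factor(self):
        labels = build_geometry(coarse_spec())
        attn = build_attenuation_map(labels, 0.0096)
        # top corner voxel: nothing but air laterally
        assert attn.factor[0, 0, -1] == 1.0

    def test_hand_computed_line_phantom(self):
        # 5-voxel line, material in voxels 1 and 2; mu = 0.1/mm, 2 mm voxels.
        grid = VoxelGrid((5, 1, 1), (2.0, 1.0, 1.0))
        labels = LabelVolume(
            grid,
            np.array([0, 1, 1, 0, 0]).reshape(5, 1, 1),
            {0: ("none", "background"), 1: ("p1", "root")},
        )
        attn = build_attenuation_map(labels, 0.1)
        # paths (in voxel widths): 0, 0.5, 0.5 (shorter side), 0, 0
        expected = np.exp(-0.1 * 2.0 * np.array([0.0, 0.5, 0.5, 0.0, 0.0]))
        assert np.allclose(attn.factor[:, 0, 0], expected, rtol=1e-12)

    def test_attenuate_then_correct_is_identity(self, diurnal_noiseless):
        img = diurnal_noiseless.noiseless
        attn = diurnal_noiseless.attenuation
        back = correct_attenuation(apply_attenuation(img, attn), attn)
        # multiply-then-divide by the same factor: exact up to one rounding step
        assert np.allclose(back.values, img.values, rtol=1e-14, atol=0.0)

    def test_uniform_half_factor_halves_totals(self):
        spec = coarse_spec(sensitivity=None, n_frames=4)
        labels = build_geometry(spec)
        series = {n: simulate_kinetics(p, spec.frames, spec.light) for n, p in spec.groupings.items()}
        img = render_frames(labels, series, spec)
        attn = AttenuationMap(spec.grid, np.full(spec.grid.dims, 0.5))
        assert np.allclose(
            apply_attenuation(img, attn).frame_totals(), 0.5 * img.frame_totals()
        )

    def test_factor_bounds_enforced(self):
        grid = VoxelGrid((2, 2, 2), (1, 1, 1))
        with pytest.raises(ValueError):
            AttenuationMap(grid, np.zeros(grid.dims))


class TestCountingNoise:
    def _unit_image(self, value=1.0):
        grid = VoxelGrid((1, 1, 1), (1, 1, 1))
        return pp.DynamicImage(grid, FrameSchedule.uniform(1), np.full((1, 1, 1, 1), value))

    def test_same_seed_reproduces(self, diurnal_noiseless):
        img = diurnal_noiseless.attenuated
        a = add_counting_noise(img, 1e4, 5)
        b = add_counting_noise(img, 1e4, 5)
        assert np.array_equal(a.values, b.values)

    def test_zero_stays_zero(self):
        img = self._unit_image(0.0)
        assert add_counting_noise(img, 100.0, 0).values[0, 0, 0, 0] == 0.0

    def test_noise_is_unbiased(self):
        img = self._unit_image(1.0)
        means = [add_counting_noise(img, 100.0, s).values[0, 0, 0, 0] for s in range(200)]
        assert abs(np.mean(means) - 1.0) < 3.0 / np.sqrt(200 * 100)

    def test_none_sensitivity_is_noiseless_copy(self):
        img = self._unit_image(1.0)
        out = add_counting_noise(img, None, 0)
        assert np.array_equal(out.values, img.values)
        assert out.values is not img.values


class TestGenerateDataset:
    def test_noiseless_leaf_tac_matches_kinetics(self, diurnal_noiseless):
        # end-to-end: corrected image == noiseless render, leaf ROI sum == A_leaf * decay
        spec = diurnal_noiseless.spec
        ds = generate_dataset(spec)
        roi = [r for r in diurnal_noiseless.rois
               if r.plant_id == "low_no_inhibitor" and r.region == "leaves"][0]
        tac = pp.extract_tac(ds.pet_corrected, roi)
        cs = ds.truth.series["low_no_inhibitor"]
        expected = cs.A_leaf * decay_factor(cs.t)
        assert np.allclose(tac.A, expected, rtol=1e-10)

    def test_seed_changes_noise_not_truth(self):
        spec_a = coarse_spec(n_frames=6)
        spec_b = dataclasses.replace(coarse_spec(n_frames=6), seed=1)
        ds_a = generate_dataset(spec_a)
        ds_b = generate_dataset(spec_b)
        for name in spec_a.groupings:
            assert np.array_equal(
                ds_a.truth.series[name].A_leaf, ds_b.truth.series[name].A_leaf
            )
        assert not np.array_equal(ds_a.pet_uncorrected.values, ds_b.pet_uncorrected.values)

    def test_corrected_and_uncorrected_share_grid_and_frames(self):
        ds = generate_dataset(coarse_spec(n_frames=4))
        assert ds.pet_corrected.grid == ds.pet_uncorrected.grid
        assert ds.pet_corrected.frames == ds.pet_uncorrected.frames

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = coarse_spec()
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = pp.PhantomSpec.from_yaml(path)
        assert back.grid == spec.grid
        assert back.groupings == spec.groupings
        assert back.geometry == spec.geometry
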