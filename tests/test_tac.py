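import math

import numpy as np
import pytest

import phytopet as pp
from phytopet.imaging_io import DynamicImage, FrameSchedule, VoxelGrid
from phytopet.roi import PlantROI
from phytopet.tac import (
    RelativeTAC,
    TAC,
    RateCurve,
    decay_correct,
    estimate_uptake_rate,
    extract_tac,
    normalize,
    rate_of_change,
    uptake_rate_curve,
)

from conftest import plant_analysis
from oracles import prism_sum_loop

GRID = VoxelGrid((10, 8, 12), (1.59, 1.59, 2.027))


def _random_image(seed=0, n_frames=6):
    rng = np.random.default_rng(seed)
    return DynamicImage(GRID, FrameSchedule.uniform(n_frames), rng.random(GRID.dims + (n_frames,)))


class TestExtractTac:
    def test_whole_grid_roi_gives_frame_totals(self):
        img = _random_image()
        roi = PlantROI("p", "all", (0, 9), (0, 7), (0, 11))
        assert np.allclose(extract_tac(img, roi).A, img.frame_totals())

    def test_matches_triple_loop_on_random_prisms(self):
        img = _random_image(1)
        rng = np.random.default_rng(2)
        for _ in range(20):
            lo = [int(rng.integers(0, d - 1)) for d in GRID.dims]
            hi = [int(rng.integers(lo[ax], GRID.dims[ax])) for ax in range(3)]
            roi = PlantROI("p", "r", (lo[0], hi[0]), (lo[1], hi[1]), (lo[2], hi[2]))
            assert np.allclose(extract_tac(img, roi).A, prism_sum_loop(img.values, roi), rtol=1e-13)

    def test_zero_image_gives_zero_tac(self):
        img = DynamicImage(GRID, FrameSchedule.uniform(3), np.zeros(GRID.dims + (3,)))
        roi = PlantROI("p", "r", (0, 3), (0, 3), (0, 3))
        assert not extract_tac(img, roi).A.any()

    def test_additive_over_disjoint_prisms(self):
        img = _random_image(3)
        lower = PlantROI("p", "a", (0, 9), (0, 7), (0, 5))
        upper = PlantROI("p", "b", (0, 9), (0, 7), (6, 11))
        union = PlantROI("p", "u", (0, 9), (0, 7), (0, 11))
        assert np.allclose(
            extract_tac(img, lower).A + extract_tac(img, upper).A,
            extract_tac(img, union).A,
            rtol=1e-13,
        )

    def test_roi_outside_grid_rejected(self):
        img = _random_image()
        with pytest.raises(ValueError, match="grid mismatch"):
            extract_tac(img, PlantROI("p", "r", (0, 20), (0, 3), (0, 3)))


class TestDecayCorrect:
    def test_reference_time_is_unchanged(self):
        tac = TAC("p", "r", np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        out = decay_correct(tac, t_ref_h=0.0)
        assert out.A[0] == 1.0
        assert out.decay_corrected

    def test_72h_na22_factor(self):
        # independent evaluation: exp(ln2 * 72 / (2.605 * 8766))
        expected = math.exp(math.log(2.0) * 72.0 / (2.605 * 8766.0))
        tac = TAC("p", "r", np.array([72.0]), np.array([1.0]))
        assert decay_correct(tac).A[0] == pytest.approx(expected, abs=1e-9)
        assert decay_correct(tac).A[0] == pytest.approx(1.002188, abs=5e-7)

    def test_correction_and_inverse_restore_input(self):
        rng = np.random.default_rng(0)
        t = np.arange(10.0)
        tac = TAC("p", "r", t, rng.random(10) + 0.1)
        once = decay_correct(tac, t_ref_h=0.0)
        undone = once.A / (2.0 ** (t / (2.605 * 8766.0)))
        assert np.allclose(undone, tac.A, rtol=1e-14)

    def test_non_positive_half_life_rejected(self):
        tac = TAC("p", "r", np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="half-life"):
            decay_correct(tac, half_life_y=0.0)


class TestNormalize:
    def _pair(self, roots, leaves):
        t = np.arange(float(len(roots)))
        return [
            TAC("p", "roots", t, np.asarray(roots, dtype=float)),
            TAC("p", "leaves", t, np.asarray(leaves, dtype=float)),
        ]

    def test_ratio_arithmetic(self):
        rels = {r.region: r for r in normalize(self._pair([1.2], [0.3]))}
        assert rels["roots"].R[0] == pytest.approx(0.8)
        assert rels["leaves"].R[0] == pytest.approx(0.2)

    def test_single_region_ratio_is_one(self):
        rels = normalize([TAC("p", "roots", np.arange(3.0), np.array([2.0, 1.0, 0.5]))])
        assert np.allclose(rels[0].R, 1.0)

    @pytest.mark.parametrize("c", [0.1, 3.0, 1e6])
    def test_scale_invariance(self, c):
        base = normalize(self._pair([1.2, 1.0], [0.3, 0.5]))
        scaled = normalize(
            [TAC(t.plant_id, t.region, t.t, c * t.A) for t in self._pair([1.2, 1.0], [0.3, 0.5])]
        )
        for a, b in zip(base, scaled):
            assert np.allclose(a.R, b.R, rtol=1e-12)

    def test_zero_total_reports_frame_index(self):
        with pytest.raises(ValueError, match="frame 1"):
            normalize(self._pair([1.0, 0.0], [0.5, 0.0]))

    def test_mixed_plants_rejected(self):
        t = np.arange(2.0)
        with pytest.raises(ValueError, match="mixed plants"):
            normalize([TAC("a", "roots", t, t + 1), TAC("b", "leaves", t, t + 1)])

    def test_denominator_composition_recorded(self):
        rels = normalize(self._pair([1.0], [1.0]))
        assert rels[0].denominator_regions == ("leaves", "roots")


class TestRateOfChange:
    def _rel(self, t, R):
        return RelativeTAC("p", "leaves", np.asarray(t, float), np.asarray(R, float))

    def test_central_difference_exact_for_quadratic(self):
        t = np.arange(11.0)
        rate = rate_of_change(self._rel(t, (t / 10.0) ** 2))
        assert np.allclose(rate.dRdt[1:-1], 2.0 * t[1:-1] / 100.0, rtol=1e-12)

    def test_three_point_example(self):
        rate = rate_of_change(self._rel([0.0, 1.0, 2.0], [0.0, 0.1, 0.4]))
        assert rate.dRdt[1] == pytest.approx(0.2)

    def test_constant_ratio_has_zero_rate(self):
        rate = rate_of_change(self._rel(np.arange(5.0), np.full(5, 0.3)))
        assert np.all(rate.dRdt == 0.0)

    def test_endpoints_use_one_sided_differences(self):
        rate = rate_of_change(self._rel([0.0, 1.0, 2.0], [0.0, 0.1, 0.4]))
        assert rate.dRdt[0] == pytest.approx(0.1)
        assert rate.dRdt[-1] == pytest.approx(0.3)
        assert rate.endpoint_method == "one_sided_first_difference"

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            rate_of_change(self._rel([0.0, 1.0], [0.0, 0.1]))

    def test_non_uniform_spacing_rejected(self):
        rel = RelativeTAC("p", "r", np.array([0.0, 1.0, 2.5]), np.array([0.0, 0.1, 0.2]))
        with pytest.raises(ValueError, match="non-uniform"):
            rate_of_change(rel)


class TestPlantInvariants:
    def test_ratios_sum_to_one_and_rates_to_zero(self, diurnal_noiseless):
        img = diurnal_noiseless.corrected(0)  # sensitivity None -> noiseless
        res = plant_analysis(img, diurnal_noiseless.rois, "high_no_inhibitor")
        R_sum = sum(rel.R for rel in res["rels"].values())
        assert np.allclose(R_sum, 1.0, atol=1e-12)
        rate_sum = sum(rc.dRdt for rc in res["rates"].values())
        assert np.allclose(rate_sum[1:-1], 0.0, atol=1e-12)

    def test_total_tac_constant_after_decay_correction(self, diurnal_noiseless):
        img = diurnal_noiseless.corrected(0)
        res = plant_analysis(img, diurnal_noiseless.rois, "low_inhibitor")
        total = sum(t.A for t in res["tacs"])
        assert np.max(np.abs(total - total.mean())) / total.mean() < 1e-10

    def test_root_ratio_falls_and_leaf_ratio_rises(self, diurnal_noiseless):
        img = diurnal_noiseless.corrected(0)
        res = plant_analysis(img, diurnal_noiseless.rois, "low_no_inhibitor")
        assert np.all(np.diff(res["rels"]["roots"].R) <= 1e-15)
        assert np.all(np.diff(res["rels"]["leaves"].R) >= -1e-15)


class TestUptakeRateEstimate:
    def test_recovers_constant_rate_within_one_percent(self, constant_k_noiseless):
        img = constant_k_noiseless.corrected(0)
        res = plant_analysis(img, constant_k_noiseless.rois, "high_no_inhibitor")
        k_true = constant_k_noiseless.spec.groupings["high_no_inhibitor"].k_base
        assert np.nanmedian(res["est"].k_hat) == pytest.approx(k_true, rel=0.01)

    def test_constant_leaf_ratio_gives_zero_estimate(self):
        t = np.arange(6.0)
        rate = rate_of_change(RelativeTAC("p", "leaves", t, np.full(6, 0.2)))
        rel_root = RelativeTAC("p", "roots", t, np.full(6, 0.8))
        est = estimate_uptake_rate(rate, rel_root)
        assert np.all(est.k_hat == 0.0)

    def test_low_root_ratio_frames_flagged(self):
        t = np.arange(5.0)
        rate = rate_of_change(RelativeTAC("p", "leaves", t, np.linspace(0.9, 0.99, 5)))
        R_root = np.array([0.1, 0.06, 0.04, 0.03, 0.01])
        est = estimate_uptake_rate(rate, RelativeTAC("p", "roots", t, R_root))
        assert list(est.valid) == [True, False, False]
        assert np.isnan(est.k_hat[1])

    def test_no_evaluable_frames_rejected(self):
        t = np.arange(4.0)
        rate = rate_of_change(RelativeTAC("p", "leaves", t, np.full(4, 0.99)))
        rel_root = RelativeTAC("p", "roots", t, np.full(4, 0.01))
        with pytest.raises(ValueError, match="no evaluable frames"):
            estimate_uptake_rate(rate, rel_root)

    def test_uptake_rate_curve_pads_endpoints(self):
        t = np.arange(6.0)
        rate = rate_of_change(RelativeTAC("p", "leaves", t, np.linspace(0.0, 0.5, 6)))
        est = estimate_uptake_rate(rate, RelativeTAC("p", "roots", t, np.linspace(1.0, 0.5, 6)))
        curve = uptake_rate_curve(est)
        assert curve.t.size == 6
        assert np.isnan(curve.dRdt[0]) and np.isnan(curve.dRdt[-1])
        assert np.allclose(curve.dRdt[1:-1], est.k_hat, equal_nan=True)
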