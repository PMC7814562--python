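import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phytopet as pp
from phytopet.phantom import (
    add_counting_noise,
    apply_attenuation,
    build_attenuation_map,
    build_geometry,
    correct_attenuation,
    render_frames,
    simulate_kinetics,
)
from phytopet.pipeline import phantom_rois

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

# Coarse grid for simulation-heavy tests: same ~102 x 102 x 97 mm field of
# view as the default spec, at half resolution in every axis.
COARSE = dict(dims=(32, 32, 24), spacing=(3.18, 3.18, 4.054))


def coarse_spec(**kwargs):
    return pp.default_phantom_spec(**{**COARSE, **kwargs})


class PhantomEnsemble:
    """Noiseless forward model computed once; per-seed noisy realizations on demand."""

    def __init__(self, spec):
        self.spec = spec
        self.labels = build_geometry(spec)
        self.series = {
            name: simulate_kinetics(p, spec.frames, spec.light)
            for name, p in spec.groupings.items()
        }
        self.noiseless = render_frames(self.labels, self.series, spec)
        self.attenuation = build_attenuation_map(self.labels, spec.mu_per_mm)
        self.attenuated = apply_attenuation(self.noiseless, self.attenuation)
        self.rois = phantom_rois(spec)

    def corrected(self, seed):
        noisy = add_counting_noise(self.attenuated, self.spec.sensitivity, seed)
        return correct_attenuation(noisy, self.attenuation)


def plant_analysis(image, rois, plant_id, eps=0.05):
    """Decay-corrected TACs -> ratios -> rates -> k-hat for one plant."""
    plant_rois = [r for r in rois if r.plant_id == plant_id]
    tacs = [pp.decay_correct(pp.extract_tac(image, r)) for r in plant_rois]
    rels = {r.region: r for r in pp.normalize(tacs)}
    rates = {reg: pp.rate_of_change(rel) for reg, rel in rels.items()}
    est = pp.estimate_uptake_rate(rates["leaves"], rels["roots"], eps)
    return {"tacs": tacs, "rels": rels, "rates": rates, "est": est}


@pytest.fixture(scope="session")
def diurnal_noiseless():
    """Coarse four-grouping phantom, diurnal modulation on, no noise, no anticipation."""
    spec = coarse_spec(phase_advance=0.0, sensitivity=None)
    return PhantomEnsemble(spec)


@pytest.fixture(scope="session")
def constant_k_noiseless():
    """Coarse phantom with constant kinetics (no diurnal modulation), no noise."""
    spec = coarse_spec(a_diurnal=0.0, phase_advance=0.0, sensitivity=None)
    return PhantomEnsemble(spec)


@pytest.fixture(scope="session")
def default_noisy_ensemble():
    """Coarse phantom at default study conditions (diurnal + anticipation + noise)."""
    return PhantomEnsemble(coarse_spec())


@pytest.fixture(scope="session")
def null_noisy_ensemble():
    """Coarse phantom with a_diurnal = 0 and Poisson noise, for calibration checks."""
    return PhantomEnsemble(coarse_spec(a_diurnal=0.0, phase_advance=0.0))
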