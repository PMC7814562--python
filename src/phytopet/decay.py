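"""Physical decay of the sodium-22 tracer.

²²Na has a half-life of 2.605 years, so over a multi-day scan the decay is a
sub-percent effect (≈0.22 % over 72 h), but it is modelled exactly: the
phantom decays rendered activity to each frame midpoint, and the analysis
side applies the inverse correction so that activities refer to the
administration time.

The year convention is fixed here as 1 y = 365.25 d = 8766 h.
"""

from __future__ import annotations

import numpy as np

NA22_HALF_LIFE_Y: float = 2.605
HOURS_PER_YEAR: float = 8766.0


def half_life_hours(half_life_y: float = NA22_HALF_LIFE_Y) -> float:
    """Half-life in hours for a half-life given in years."""
    if half_life_y <= 0:
        raise ValueError(f"non-positive half-life: {half_life_y}")
    return half_life_y * HOURS_PER_YEAR


def decay_factor(t_h, half_life_y: float = NA22_HALF_LIFE_Y):
    """Surviving activity fraction 2^(-t/T½) at time ``t_h`` hours."""
    return 2.0 ** (-np.asarray(t_h, dtype=float) / half_life_hours(half_life_y))


def decay_correction_factor(dt_h, half_life_y: float = NA22_HALF_LIFE_Y):
    """Multiplier 2^(Δt/T½) referring a measurement at Δt back to t = 0."""
    return 2.0 ** (np.asarray(dt_h, dtype=float) / half_life_hours(half_life_y))
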