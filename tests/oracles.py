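"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's own integration code paths: the
light/dark state is recomputed from first principles and the two-pool
transport ODE is integrated numerically segment by segment with a
high-order adaptive solver.
"""

import numpy as np
from scipy.integrate import solve_ivp


def ode_leaf_activity(k_base, f_nutrient, f_inhibitor, a_diurnal, phase_advance,
                      A_total, period_light, period_dark, t0, t_eval):
    """Numerically integrated A_leaf(t) for the piecewise-constant rate model.

    dA_leaf/dt = k(t)·(A_total − A_leaf), with k switching between
    k_eff·(1 ± a) at the light/dark boundaries of the phase-advanced clock.
    The discontinuity times are enumerated and the solver restarts at each,
    so the adaptive integrator never steps across a jump.
    """
    k_eff = k_base * f_nutrient * f_inhibitor
    cycle = period_light + period_dark

    def rate(t):
        phase = (t + phase_advance - t0) % cycle
        return k_eff * (1.0 + a_diurnal if phase < period_light else 1.0 - a_diurnal)

    t_end = float(np.max(t_eval))
    breaks = {0.0}
    n_lo = int(np.floor((phase_advance - t0) / cycle)) - 2
    n_hi = int(np.ceil((t_end + phase_advance - t0) / cycle)) + 2
    for n in range(n_lo, n_hi + 1):
        base = t0 + n * cycle - phase_advance
        for b in (base, base + period_light):
            if 0.0 < b < t_end:
                breaks.add(b)
    breaks = sorted(breaks) + [t_end]

    t_eval = np.asarray(t_eval, dtype=float)
    out = np.empty(t_eval.shape)
    A = 0.0
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        if hi <= lo:
            continue
        k_seg = rate((lo + hi) / 2.0)
        sel = (t_eval > lo) & (t_eval <= hi)
        pts = np.sort(t_eval[sel])
        sol = solve_ivp(
            lambda t, y: [k_seg * (A_total - y[0])],
            (lo, hi),
            [A],
            method="DOP853",
            rtol=1e-12,
            atol=1e-14,
            t_eval=np.unique(np.concatenate([pts, [hi]])),
        )
        for t in pts:
            out[np.isclose(t_eval, t)] = sol.y[0][np.isclose(sol.t, t)][0]
        A = sol.y[0][-1]
    if np.any(np.isclose(t_eval, 0.0)):
        out[np.isclose(t_eval, 0.0)] = 0.0
    return out


def prism_sum_loop(values, roi):
    """Triple-loop accumulation of a prism's voxels, per frame."""
    n_frames = values.shape[3]
    acc = np.zeros(n_frames)
    for i in range(roi.x[0], roi.x[1] + 1):
        for j in range(roi.y[0], roi.y[1] + 1):
            for k in range(roi.z[0], roi.z[1] + 1):
                acc += values[i, j, k, :]
    return acc


def region_slices_brute(z_bottom, z_top, origin_z, spacing_z, n_slices):
    """Slices owned by a region [z_bottom, z_top) under the half-open voxel rule.

    A slice belongs to the region iff its upper physical edge lies in
    (z_bottom, z_top]; this reproduces "boundary voxel goes to the upper
    region" without using the package's index arithmetic.
    """
    owned = []
    for i in range(n_slices):
        upper_edge = origin_z + i * spacing_z + spacing_z / 2.0
        if z_bottom < upper_edge <= z_top:
            owned.append(i)
    return owned
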