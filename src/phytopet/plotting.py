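"""Ratio and rate-of-change panels with dark-period shading."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .phantom import LightSchedule

_COLORS = {
    "high_no_inhibitor": "tab:red",
    "high_inhibitor": "tab:purple",
    "low_no_inhibitor": "tab:blue",
    "low_inhibitor": "tab:green",
}


def _shade_dark(ax, light: LightSchedule, t_lo: float, t_hi: float) -> None:
    for d0, d1 in light.dark_intervals(t_lo, t_hi):
        ax.axvspan(d0, d1, color="0.85", zorder=0)


def _panel(curves, value_attr: str, ylabel: str, light: LightSchedule, path) -> None:
    regions = sorted({c.region for c in curves})
    fig, axes = plt.subplots(1, len(regions), figsize=(5.5 * len(regions), 4.0), squeeze=False)
    for ax, region in zip(axes[0], regions):
        sel = [c for c in curves if c.region == region]
        t_lo = min(float(c.t[0]) for c in sel)
        t_hi = max(float(c.t[-1]) for c in sel)
        _shade_dark(ax, light, t_lo, t_hi)
        for c in sel:
            ax.plot(c.t, getattr(c, value_attr), label=c.plant_id,
                    color=_COLORS.get(c.plant_id))
        ax.set_title(region)
        ax.set_xlabel("time since administration (h)")
        ax.set_ylabel(ylabel)
    axes[0][-1].legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_ratio_curves(rel_tacs, light: LightSchedule, path) -> None:
    """Relative radioactivity vs time, one panel per region, dark shaded."""
    _panel(rel_tacs, "R", "radioactivity ratio", light, path)


def plot_rate_curves(rate_curves, light: LightSchedule, path) -> None:
    """Rate of change of the ratio vs time, one panel per region."""
    _panel(rate_curves, "dRdt", "d(ratio)/dt (per h)", light, path)
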