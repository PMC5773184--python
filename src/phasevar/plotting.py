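"""Minimal circular phase plots: mean vectors with angular-SD arcs."""

from __future__ import annotations

import numpy as np

from .circular import TWO_PI, circular_summary

__all__ = ["circular_phase_plot"]


def circular_phase_plot(phases, ax=None, color="C0", label=None, points=True):
    """Draw a circular plot of a phase sample.

    Each phase appears as a point on the unit circle; the thick arrow is
    the mean vector (length = resultant length r, so shorter arrows mean
    more dispersion) and the arc spans +/- one angular SD around the mean.
    Phase zero points up and phase increases clockwise, the usual
    convention for cycle-fraction dials.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    summ = circular_summary(phases)
    ang = TWO_PI * np.asarray(phases, dtype=float)
    if points:
        ax.plot(ang, np.ones_like(ang), "o", ms=4, alpha=0.6, color=color)
    mean_ang = TWO_PI * summ.mean_phase
    ax.annotate(
        "",
        xy=(mean_ang, summ.r),
        xytext=(0.0, 0.0),
        arrowprops={"arrowstyle": "-|>", "lw": 2, "color": color},
    )
    arc = np.linspace(mean_ang - summ.sd_rad, mean_ang + summ.sd_rad, 64)
    ax.plot(arc, np.full_like(arc, 1.05), "-", lw=2, color="black")
    ax.set_rlim(0, 1.12)
    ax.set_xticks(TWO_PI * np.arange(0, 1, 0.25))
    ax.set_xticklabels(["0", "0.25", "0.5", "0.75"])
    ax.set_yticklabels([])
    if label:
        ax.set_title(f"{label} (mean {summ.mean_phase:.3f}, r={summ.r:.3f})")
    return ax
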