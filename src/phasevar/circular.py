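"""Circular statistics on phases expressed as cycle fractions.

Phases live on the unit circle and are handled as fractions of a cycle
(1.0 = one full cycle = 2*pi radians).  Dispersion is quantified by the
mean resultant length ``r`` of the sample's unit vectors and the angular
variance ``s^2 = 2(1 - r)`` (radians squared), with phase-unit equivalents
obtained by dividing the variance by ``4*pi^2`` and the SD by ``2*pi``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * np.pi
FOUR_PI_SQ = 4.0 * np.pi**2

__all__ = [
    "CircularSummary",
    "angular_variance",
    "center_phase",
    "circular_mean",
    "circular_mean_difference",
    "circular_summary",
    "period_cv",
    "wrap_phase",
]


def wrap_phase(phi):
    """Reduce phase fractions modulo 1 into ``[0, 1)``."""
    return np.mod(phi, 1.0)


def center_phase(phi):
    """Canonicalize phase fractions to the centered interval ``(-0.5, 0.5]``.

    The centered convention keeps the sign of small leads/lags, so a target
    that slightly precedes its reference reads as a small negative phase
    instead of a value just below 1.
    """
    phi = np.asarray(phi, dtype=float)
    c = np.mod(phi, 1.0)
    c = np.where(c > 0.5, c - 1.0, c)
    if c.ndim == 0:
        return float(c)
    return c


def circular_mean_difference(a, b):
    """Circular difference ``a - b`` canonicalized to ``(-0.5, 0.5]``.

    This is the Delta-Delta-phi primitive: it is zero when the two phase
    differences are identical and respects the wrap-around of the circle
    (0.95 - 0.05 -> -0.10, not +0.90).
    """
    return center_phase(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass(frozen=True)
class CircularSummary:
    """Vector-summation summary of a circular sample.

    Attributes
    ----------
    n : int
        Sample size.
    mean_phase : float
        Mean vector phase as a fraction in ``[0, 1)``.
    r : float
        Mean resultant length in ``[0, 1]``; 1 means all phases coincide.
    var_rad : float
        Angular variance ``s^2 = 2(1 - r)`` in radians squared.
    var_phase : float
        Angular variance in phase units squared (``var_rad / (4 pi^2)``).
    sd_rad, sd_phase : float
        Angular standard deviation ``s = sqrt(s^2)`` in radians and in
        phase units (``sd_rad / (2 pi)``).
    """

    n: int
    mean_phase: float
    r: float
    var_rad: float
    var_phase: float
    sd_rad: float
    sd_phase: float

    @property
    def mean_phase_centered(self) -> float:
        return center_phase(self.mean_phase)


def circular_summary(phases) -> CircularSummary:
    """Summarize a sample of phase fractions by vector summation.

    Each phase ``phi`` is mapped to the unit vector at angle ``2*pi*phi``;
    the mean vector's direction gives the mean phase and its norm the
    resultant length ``r``.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("circular_summary requires at least one phase")
    ang = TWO_PI * phases
    c = float(np.mean(np.cos(ang)))
    s = float(np.mean(np.sin(ang)))
    r = min(float(np.hypot(c, s)), 1.0)
    mean_phase = float(np.mod(np.arctan2(s, c) / TWO_PI, 1.0))
    var_rad = 2.0 * (1.0 - r)
    sd_rad = float(np.sqrt(var_rad))
    return CircularSummary(
        n=int(phases.size),
        mean_phase=mean_phase,
        r=r,
        var_rad=var_rad,
        var_phase=var_rad / FOUR_PI_SQ,
        sd_rad=sd_rad,
        sd_phase=sd_rad / TWO_PI,
    )


def circular_mean(phases) -> float:
    """Mean vector phase of a sample, as a fraction in ``[0, 1)``."""
    return circular_summary(phases).mean_phase


def angular_variance(phases, axis=None):
    """Angular variance ``2(1 - r)`` in phase units squared.

    Vectorized over ``axis`` so resampling procedures can evaluate many
    samples at once; with ``axis=None`` the input is flattened.
    """
    ang = TWO_PI * np.asarray(phases, dtype=float)
    c = np.mean(np.cos(ang), axis=axis)
    s = np.mean(np.sin(ang), axis=axis)
    r = np.minimum(np.hypot(c, s), 1.0)
    return 2.0 * (1.0 - r) / FOUR_PI_SQ


def period_cv(periods) -> float:
    """Coefficient of variation (sample SD / mean) of cycle periods.

    Uses the n-1 denominator for the SD, the standard choice at the small
    per-recording sample sizes this is applied to.
    """
    periods = np.asarray(periods, dtype=float)
    if periods.size < 2:
        raise ValueError("period_cv requires at least two periods")
    if np.any(periods <= 0):
        raise ValueError("periods must be strictly positive")
    return float(np.std(periods, ddof=1) / np.mean(periods))
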