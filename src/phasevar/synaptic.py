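"""Spike-triggered averaging of synaptic currents and strength comparison.

Unitary IPSC amplitudes are estimated by averaging a voltage-clamp
current trace in windows aligned on presynaptic spike times, subtracting
a pre-trigger baseline per window.  Peak currents convert to
conductances via the driving force (g = I / (V_hold - E_rev), reversal
potential -62 mV), and per-side proportional strengths
g_front / (g_front + g_middle) cancel clamp-quality scale factors so the
two body sides can be compared with a paired test against a side-
scrambled null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "STAResult",
    "SideComparisonResult",
    "bilateral_strength_test",
    "proportional_strength",
    "spike_triggered_average",
    "to_conductance",
]


@dataclass
class STAResult:
    """Spike-triggered average of a clamp current and its peak amplitude."""

    lags: np.ndarray  # seconds relative to trigger
    waveform: np.ndarray  # baseline-subtracted mean current, pA
    peak_pA: float  # signed extremum within the post-trigger window
    n_triggers: int
    n_bursts: int
    contaminated_fraction: float = 0.0  # windows containing other-unit spikes


def spike_triggered_average(
    times: np.ndarray,
    current: np.ndarray,
    triggers: np.ndarray,
    window_s: float = 0.2,
    baseline_s: float = 0.05,
    n_bursts: int | None = None,
    min_bursts: int = 10,
    allow_few_bursts: bool = False,
    other_spikes: np.ndarray | None = None,
) -> STAResult:
    """Baseline-subtracted spike-triggered average of a current trace.

    Segments ``[trigger - baseline_s, trigger + window_s]`` are averaged
    after subtracting each segment's pre-trigger mean; triggers whose
    window overlaps a trace edge are dropped.  ``n_bursts`` is the number
    of presynaptic bursts the triggers came from; fewer than
    ``min_bursts`` is refused unless ``allow_few_bursts`` (amplitudes
    from few bursts are unreliable).  If ``other_spikes`` (spike times of
    other presynaptic units) is given, the fraction of windows containing
    such spikes is reported and a warning raised when kernels may
    overlap.
    """
    times = np.asarray(times, dtype=float)
    current = np.asarray(current, dtype=float)
    triggers = np.asarray(triggers, dtype=float)
    if times.size != current.size:
        raise ValueError("times and current must have equal length")
    if triggers.size == 0:
        raise ValueError("no trigger spikes")
    dt = float(times[1] - times[0])
    n_pre = int(np.round(baseline_s / dt))
    n_post = int(np.round(window_s / dt))
    if n_bursts is None:
        # conservative burst count from >=1 s gaps between triggers
        n_bursts = int(np.sum(np.diff(np.sort(triggers)) >= 1.0)) + 1
    if n_bursts < min_bursts and not allow_few_bursts:
        raise ValueError(
            f"only {n_bursts} bursts of triggers (< {min_bursts}); amplitude "
            "estimates from so few bursts are unreliable "
            "(pass allow_few_bursts=True to override)"
        )
    idx = np.round((triggers - times[0]) / dt).astype(int)
    keep = (idx - n_pre >= 0) & (idx + n_post < times.size)
    idx = idx[keep]
    if idx.size == 0:
        raise ValueError("all trigger windows overlap the trace edges")
    offs = np.arange(-n_pre, n_post + 1)
    seg = current[idx[:, None] + offs[None, :]]
    baseline = seg[:, :n_pre].mean(axis=1, keepdims=True) if n_pre > 0 else 0.0
    seg = seg - baseline
    wave = seg.mean(axis=0)
    lags = offs * dt
    post = wave[lags >= 0]
    peak = float(post[np.argmax(np.abs(post))])
    contaminated = 0.0
    if other_spikes is not None and np.asarray(other_spikes).size:
        other = np.asarray(other_spikes, dtype=float)
        trig = times[0] + idx * dt
        lo = np.searchsorted(other, trig - baseline_s)
        hi = np.searchsorted(other, trig + window_s)
        contaminated = float(np.mean(hi > lo))
        if contaminated > 0:
            warnings.warn(
                f"{contaminated:.0%} of STA windows contain spikes of another "
                "presynaptic unit; amplitudes may mix kernels",
                stacklevel=2,
            )
    return STAResult(
        lags=lags,
        waveform=wave,
        peak_pA=peak,
        n_triggers=int(idx.size),
        n_bursts=int(n_bursts),
        contaminated_fraction=contaminated,
    )


def to_conductance(
    peak_pA: float,
    holding_mV: float,
    reversal_mV: float = -62.0,
    holding_error_mV: float = 5.0,
) -> tuple[float, tuple[float, float]]:
    """Convert a peak current to a conductance, g = I / (V_hold - E_rev).

    Units: pA / mV = nS.  Returns ``(g, (g_lo, g_hi))`` where the band
    propagates the stated accuracy of the holding potential (default
    +/- 5 mV); if the band includes a zero driving force the upper limit
    is infinite.
    """
    drive = holding_mV - reversal_mV
    if drive == 0.0:
        raise ValueError("holding potential equals the reversal potential")
    g = peak_pA / drive
    d_lo, d_hi = drive - holding_error_mV, drive + holding_error_mV
    if d_lo <= 0.0 <= d_hi:
        # the driving-force uncertainty includes zero: g is unbounded above
        finite = [abs(peak_pA) / abs(d) for d in (d_lo, d_hi) if d != 0.0]
        band = (min(finite, default=0.0), np.inf)
    else:
        vals = sorted(abs(peak_pA) / abs(d) for d in (d_lo, d_hi))
        band = (vals[0], vals[1])
    return float(g), (float(band[0]), float(band[1]))


def proportional_strength(g_front: float, g_middle: float) -> float:
    """Front unit's share of the summed input, g4 / (g4 + g7).

    Exactly invariant under common scaling of both conductances, which
    cancels differences in voltage-clamp recording quality.
    """
    if g_front < 0 or g_middle < 0:
        raise ValueError("conductances must be nonnegative")
    total = g_front + g_middle
    if total == 0:
        raise ValueError("proportional strength undefined when both inputs are zero")
    return float(g_front / total)


@dataclass(frozen=True)
class SideComparisonResult:
    """Paired test of left vs right proportional strengths with scrambled null."""

    n: int
    t: float
    p: float
    mean_left: float
    mean_right: float
    scrambled_mean_p: float
    n_scramble: int


def _paired_t_rows(left: np.ndarray, right_rows: np.ndarray):
    """Vectorized paired t p-values for many right-side pairings."""
    d = left[None, :] - right_rows
    n = left.size
    sd = d.std(axis=1, ddof=1)
    mean = d.mean(axis=1)
    p = np.ones(d.shape[0])
    ok = sd > 0
    tstat = np.zeros(d.shape[0])
    tstat[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df=n - 1)
    return tstat, p


def bilateral_strength_test(
    left,
    right,
    n_scramble: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> SideComparisonResult:
    """Do the two sides differ in proportional synaptic strength?

    Paired t-test on the original per-animal left/right pairing, plus the
    mean paired-t p-value over ``n_scramble`` pairings in which each
    animal's right side is replaced by the right side of a different
    animal.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError("left and right must be paired 1-D arrays of equal length")
    n = left.size
    if n < 5:
        raise ValueError("bilateral comparison requires at least 5 paired animals")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t_obs, p_obs = _paired_t_rows(left, right[None, :])
    perm = np.argsort(rng.random((n_scramble, n)), axis=1)
    inv = np.argsort(perm, axis=1)
    shift = rng.integers(1, n, size=(n_scramble, 1))
    J = np.take_along_axis(perm, (inv + shift) % n, axis=1)
    _, p_scr = _paired_t_rows(left, right[J])
    return SideComparisonResult(
        n=n,
        t=float(t_obs[0]),
        p=float(p_obs[0]),
        mean_left=float(left.mean()),
        mean_right=float(right.mean()),
        scrambled_mean_p=float(p_scr.mean()),
        n_scramble=n_scramble,
    )
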