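"""Burst grouping and per-cycle phase extraction from spike trains and traces.

A channel's spike train is grouped into bursts by an interburst-interval
criterion; the middle spike (by count) of each burst is the phase marker.
Cycle periods run from middle spike to middle spike of the reference
channel, and the phase of a target event inside a reference cycle is

    phi = (t_i - t_r) / T_r   (mod 1)

with ``t_r`` the reference marker opening the cycle and ``T_r`` that
cycle's period.  For constriction-like sampled signals the phase marker is
the maximum rate of rise (MRR) of the smoothed signal within each beat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .circular import center_phase

__all__ = [
    "Burst",
    "BurstSeries",
    "PhaseSeries",
    "SpikeTrain",
    "group_bursts",
    "mrr_phase_markers",
    "pair_cycles",
    "phase_of",
]


@dataclass
class SpikeTrain:
    """Spike times (seconds) of one recorded channel."""

    channel: str
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError(f"channel {self.channel}: spike times must be 1-D")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"channel {self.channel}: spike times must be strictly increasing"
            )
        if self.times.size and self.times[0] < 0:
            raise ValueError(f"channel {self.channel}: spike times must be nonnegative")


@dataclass
class Burst:
    """One burst: its spikes and the middle spike used as phase marker."""

    spikes: np.ndarray
    middle: float
    index: int

    @property
    def n_spikes(self) -> int:
        return int(self.spikes.size)


@dataclass
class BurstSeries:
    """Ordered bursts of one channel; periods run middle-to-middle."""

    channel: str
    bursts: list[Burst] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bursts)

    @property
    def middles(self) -> np.ndarray:
        return np.array([b.middle for b in self.bursts], dtype=float)

    @property
    def periods(self) -> np.ndarray:
        """Middle-spike-to-middle-spike intervals; one fewer than bursts."""
        return np.diff(self.middles)


@dataclass
class PhaseSeries:
    """Per-cycle phase differences of a target channel vs its reference.

    ``dphi`` is stored in the centered convention ``(-0.5, 0.5]``; cycles
    of the reference that contained zero or multiple target markers are
    listed in ``skipped`` and carry no phase value.
    """

    reference: str
    target: str
    cycles: np.ndarray
    dphi: np.ndarray
    skipped: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    side: str | None = None
    level: str | None = None

    def __len__(self) -> int:
        return int(self.cycles.size)


def middle_spike_index(n: int) -> int:
    """0-based index of the middle spike for an ``n``-spike burst.

    For odd ``n`` this is the central spike; for even ``n`` the earlier of
    the two central spikes (1-based index ``ceil(n/2)``).
    """
    if n < 1:
        raise ValueError("burst must contain at least one spike")
    return (n - 1) // 2


def group_bursts(
    train: SpikeTrain,
    ibi_threshold: float = 1.0,
    min_spikes: int = 3,
) -> BurstSeries:
    """Group a spike train into bursts and mark middle spikes.

    Consecutive spikes separated by less than ``ibi_threshold`` seconds
    belong to one burst; a gap of at least ``ibi_threshold`` starts a new
    one.  Groups with fewer than ``min_spikes`` spikes are discarded as
    stray spikes.
    """
    if train.times.size < 1:
        raise ValueError(f"channel {train.channel}: no spikes to group")
    if ibi_threshold <= 0:
        raise ValueError("ibi_threshold must be positive")
    gaps = np.diff(train.times)
    boundaries = np.nonzero(gaps >= ibi_threshold)[0] + 1
    groups = np.split(train.times, boundaries)
    bursts: list[Burst] = []
    for g in groups:
        if g.size < min_spikes:
            continue
        bursts.append(
            Burst(spikes=g, middle=float(g[middle_spike_index(g.size)]), index=len(bursts))
        )
    if not bursts:
        warnings.warn(
            f"channel {train.channel}: no burst with >= {min_spikes} spikes survived",
            stacklevel=2,
        )
    return BurstSeries(channel=train.channel, bursts=bursts)


def phase_of(t_i, t_r, T_r):
    """Phase of event time ``t_i`` within the reference cycle ``(t_r, T_r)``.

    Returns ``(t_i - t_r) / T_r`` reduced modulo 1 into ``[0, 1)``.
    Accepts scalars or broadcastable arrays.
    """
    T_r = np.asarray(T_r, dtype=float)
    if np.any(T_r <= 0):
        raise ValueError("reference period T_r must be positive")
    out = np.mod((np.asarray(t_i, dtype=float) - np.asarray(t_r, dtype=float)) / T_r, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def pair_cycles(
    reference: BurstSeries,
    target: BurstSeries,
    side: str | None = None,
    level: str | None = None,
) -> PhaseSeries:
    """Match target phase markers to reference cycles and compute phases.

    Reference cycle ``k`` is the half-open interval ``[m_k, m_{k+1})``
    between consecutive reference middle spikes, so every instant belongs
    to exactly one cycle.  A cycle with exactly one target marker yields a
    phase via :func:`phase_of`; cycles with zero or multiple target
    markers are flagged and skipped.
    """
    if len(reference) < 2:
        raise ValueError(
            f"reference channel {reference.channel} has fewer than two bursts"
        )
    ref_m = reference.middles
    periods = reference.periods
    n_cycles = ref_m.size - 1
    tgt_m = target.middles
    idx = np.searchsorted(ref_m, tgt_m, side="right") - 1
    in_span = (idx >= 0) & (idx < n_cycles)
    counts = np.bincount(idx[in_span], minlength=n_cycles)
    good = counts == 1
    skipped = np.nonzero(~good)[0].astype(int)
    # one target marker per good cycle
    sel = in_span.copy()
    sel[in_span] = good[idx[in_span]]
    cyc = idx[sel]
    phi = phase_of(tgt_m[sel], ref_m[cyc], periods[cyc])
    return PhaseSeries(
        reference=reference.channel,
        target=target.channel,
        cycles=cyc.astype(int),
        dphi=center_phase(np.atleast_1d(phi)),
        skipped=skipped,
        side=side,
        level=level,
    )


def _dominant_period_samples(values: np.ndarray) -> float:
    """Rough cycle length (in samples) from the dominant Fourier component."""
    x = values - np.mean(values)
    spec = np.abs(np.fft.rfft(x))
    if spec.size < 2:
        return float(values.size)
    k = int(np.argmax(spec[1:])) + 1
    return values.size / k


def mrr_phase_markers(
    times,
    values,
    smoothing: int = 5,
    min_rel_height: float = 0.5,
) -> np.ndarray:
    """Per-beat times of the maximum rate of rise of a sampled signal.

    The signal is smoothed with a ``smoothing``-sample moving average, the
    first derivative taken, and one MRR event extracted per beat cycle as a
    peak of the derivative exceeding ``min_rel_height`` of the derivative's
    maximum, with peaks separated by at least half the dominant cycle
    length.  A flat trace yields no events and a warning.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    if times.size < 4:
        raise ValueError("trace too short")
    dt = np.diff(times)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("trace must be uniformly sampled")
    dt = float(dt[0])
    if smoothing > 1:
        kernel = np.ones(smoothing) / smoothing
        sm = np.convolve(values, kernel, mode="same")
    else:
        sm = values
    dy = np.gradient(sm, dt)
    top = float(np.max(dy))
    scale = float(np.max(np.abs(values)))
    if scale == 0.0 or top <= 0.0 or np.ptp(values) < 1e-12 * max(scale, 1.0):
        warnings.warn("flat trace: no constriction events detected", stacklevel=2)
        return np.array([], dtype=float)
    distance = max(1, int(0.5 * _dominant_period_samples(values)))
    peaks, _ = find_peaks(dy, height=min_rel_height * top, distance=distance)
    # refine each peak to the centroid of the derivative's half-height lobe:
    # exact for a symmetric rise and averages out sampling noise
    events = []
    for p in peaks:
        half = 0.5 * dy[p]
        lo = p
        while lo > 0 and dy[lo - 1] > half:
            lo -= 1
        hi = p
        while hi < dy.size - 1 and dy[hi + 1] > half:
            hi += 1
        w = dy[lo : hi + 1] - half
        events.append(float(np.sum(times[lo : hi + 1] * w) / np.sum(w)))
    return np.asarray(events)
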