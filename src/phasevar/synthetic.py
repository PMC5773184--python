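"""Hierarchical synthetic recordings with known phase-variability structure.

The generator emulates a bilaterally symmetric, episodically switching
rhythmic motor system: on each side a front and a rear unit burst once
per cycle at two network levels ("cpg"-like interneurons and "motor"-like
motor neurons), the two sides always express complementary coordinations
(one peristaltic, one synchronous), and the whole system switches sides
simultaneously every 15-60 cycles.

Per-cycle intersegmental phase differences are built hierarchically:

    dphi = mu(level, coordination)            fixed coordination target
         + A(animal)                          population component
         + S(animal, side)                    bilateral component
         + R(animal, side, episode)           repetition component
         + eps(cycle)                         cycle-to-cycle noise

with every component an independent wrapped-normal draw.  The config's
variance parameters are calibrated so that the *measured* angular
variances of the analysis pipeline's four estimators converge exactly to
the configured values (see :func:`wrapped_sigma2`): the wrapped-normal
relation r = exp(-sigma^2/2) makes angular variance 2(1 - r) slightly
smaller than the underlying normal variance, and the calibration inverts
that relation, including for the differences (Delta-Delta-phi) that the
repetition and bilateral estimators use.

Also provided: constriction-like sampled traces whose per-beat maximum
rate of rise realizes a target phase, and voltage-clamp current traces
with known synaptic conductances for spike-triggered-average testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .circular import FOUR_PI_SQ, center_phase, wrap_phase

LEVELS = ("cpg", "motor")
COORDS = ("peristaltic", "synchronous")

__all__ = [
    "AnimalRecording",
    "GeneratorConfig",
    "GroundTruth",
    "generate_clamp_trace",
    "generate_constriction_traces",
    "generate_population",
    "generate_switch_cycle_means",
    "wrapped_sigma2",
]


def wrapped_sigma2(s2_phase: float) -> float:
    """Underlying normal variance giving a target angular variance.

    For a wrapped normal with underlying variance ``sigma^2`` (radians
    squared) the resultant length is ``r = exp(-sigma^2/2)``, so the
    angular variance is ``2(1 - exp(-sigma^2/2))``.  Inverting,
    ``sigma^2 = -2 ln(1 - s^2/2)``.  Both input and output are in phase
    units squared.  Raises if the requested dispersion is too large for a
    unimodal wrapped-normal sample (``s^2 >= 2`` rad^2).
    """
    if s2_phase < 0:
        raise ValueError("angular variance must be nonnegative")
    s2_rad = s2_phase * FOUR_PI_SQ
    if s2_rad >= 2.0:
        raise ValueError(
            f"angular variance {s2_phase} phase^2 = {s2_rad:.3f} rad^2 is too "
            "large for unimodal wrapped-normal sampling (limit 2 rad^2)"
        )
    return float(-2.0 * np.log1p(-s2_rad / 2.0)) / FOUR_PI_SQ


def _lookup(value, level: str, coordination: str) -> float:
    """Resolve a scalar-or-mapping config entry for (level, coordination)."""
    if isinstance(value, Mapping):
        for key in ((level, coordination), level, coordination):
            if key in value:
                return float(value[key])
        raise KeyError(f"no entry for ({level}, {coordination}) in {value!r}")
    return float(value)


def _default_dphi_mean() -> dict:
    # peristaltic means follow the reported per-level averages (0.23 CPG
    # pattern, 0.13 motor pattern); synchronous coordination is a small lead
    return {
        ("cpg", "peristaltic"): 0.23,
        ("cpg", "synchronous"): 0.02,
        ("motor", "peristaltic"): 0.13,
        ("motor", "synchronous"): 0.02,
    }


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic population.

    Variance components are angular variances in phase units squared, as
    the analysis pipeline measures them.  Defaults follow the reported
    per-level values for the peristaltic CPG and motor patterns
    (population ~0.0038/0.0020, bilateral ~0.0051/0.0021, repetition
    ~0.0015/0.0008) and a cycle-to-cycle component of 0.001.
    """

    n_animals: int = 12
    period_mean: float = 8.0  # s; beat periods span roughly 4-13 s
    period_cv: float = 0.03  # observed timing-network CV is below 5%
    cycles_per_episode: tuple[int, int] = (15, 60)
    n_switch_cycles: int = 2
    dphi_mean: dict = field(default_factory=_default_dphi_mean)
    var_population: float | dict = field(
        default_factory=lambda: {"cpg": 0.0038, "motor": 0.0020}
    )
    var_bilateral: float | dict = field(
        default_factory=lambda: {"cpg": 0.0051, "motor": 0.0021}
    )
    var_repetition: float | dict = field(
        default_factory=lambda: {"cpg": 0.0015, "motor": 0.0008}
    )
    var_cycle: float | dict = 0.001
    spikes_per_burst: int = 9
    burst_duty_cycle: float = 0.5
    # constriction-trace parameters
    trace_fs: float = 50.0  # Hz
    trace_snr: float = 200.0  # amplitude / noise SD; np.inf for noise-free
    trace_amplitude: float = 1.0
    beat_dphi_mean: dict = field(
        default_factory=lambda: {"peristaltic": 0.21, "synchronous": 0.02}
    )
    seed: int | None = None

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not 0.0 <= self.period_cv <= 0.2:
            raise ValueError("period_cv must lie in [0, 0.2]")
        lo, hi = self.cycles_per_episode
        if not (1 <= lo <= hi):
            raise ValueError("cycles_per_episode must be an increasing range >= 1")
        if self.n_switch_cycles < 1:
            raise ValueError("n_switch_cycles must be >= 1")
        if self.spikes_per_burst < 1:
            raise ValueError("spikes_per_burst must be >= 1")
        if not 0.0 < self.burst_duty_cycle < 1.0:
            raise ValueError("burst_duty_cycle must lie in (0, 1)")
        for level in LEVELS:
            for coord in COORDS:
                mu = _lookup(self.dphi_mean, level, coord)
                if not 0.0 <= mu < 1.0:
                    raise ValueError(f"dphi_mean[{level},{coord}]={mu} outside [0,1)")
                for name in ("var_population", "var_bilateral", "var_repetition", "var_cycle"):
                    if _lookup(getattr(self, name), level, coord) < 0:
                        raise ValueError(f"{name} must be nonnegative")
        self.component_sigma2()  # raises on inconsistent variance settings

    def component_sigma2(self) -> dict:
        """Underlying normal variances per (level, coordination).

        Calibrated so the pipeline's estimators recover the configured
        angular variances:

        * cycle noise: ``u_eps = ginv(var_cycle)``;
        * repetition draw R: the repetition estimator measures the angular
          variance of ``R1 - R2``, so ``u_R = ginv(var_repetition) / 2``;
        * side draw S: the raw bilateral difference carries ``2 u_S + 2
          u_R``, and the estimator subtracts the repetition variance, so
          ``u_S = (ginv(var_bilateral + var_repetition) - ginv(var_repetition)) / 2``;
        * animal draw A: the population estimator sees ``u_A + u_S + u_R``,
          so ``u_A = ginv(var_population) - u_S - u_R``.

        Raises ``ValueError`` when ``u_A`` would be negative, i.e. when the
        bilateral and repetition components already exceed the requested
        population variance.
        """
        g = wrapped_sigma2
        out = {}
        for level in LEVELS:
            for coord in COORDS:
                t_pop = _lookup(self.var_population, level, coord)
                t_bil = _lookup(self.var_bilateral, level, coord)
                t_rep = _lookup(self.var_repetition, level, coord)
                t_cyc = _lookup(self.var_cycle, level, coord)
                u_rep = g(t_rep) / 2.0
                u_side = (g(t_bil + t_rep) - g(t_rep)) / 2.0
                u_animal = g(t_pop) - u_side - u_rep
                if u_animal < -1e-15:
                    raise ValueError(
                        f"inconsistent variance components for ({level}, {coord}): "
                        f"var_population={t_pop} is smaller than the contribution "
                        "of the bilateral and repetition components "
                        f"(needs >= ~{(t_bil + t_rep) / 2:.4g})"
                    )
                out[(level, coord)] = {
                    "animal": max(u_animal, 0.0),
                    "side": u_side,
                    "episode": u_rep,
                    "cycle": g(t_cyc),
                }
        return out


@dataclass
class AnimalRecording:
    """One synthetic animal: spike times per channel plus the channel map."""

    animal: int
    spikes: dict[str, np.ndarray]
    channel_map: pd.DataFrame  # columns: channel, side, level, role


@dataclass
class GroundTruth:
    """Generator-side labels for every downstream quantity.

    ``episodes``: one row per (animal, side, episode) with coordination,
    cycle range and switch-cycle index.  ``cycle_dphi``: realized
    per-cycle phase differences (centered).  ``episode_targets``: the
    noise-free per-episode target phase (mu + A + S + R, centered).
    """

    episodes: pd.DataFrame
    cycle_dphi: pd.DataFrame
    episode_targets: pd.DataFrame
    config: GeneratorConfig


def _channel_name(animal: int, side: str, level: str, role: str) -> str:
    return f"a{animal:03d}_{side}_{level}_{role}"


def _burst_spikes(middles: np.ndarray, n_spikes: int, isi: float) -> np.ndarray:
    """Spikes placed symmetrically around each middle at uniform intervals.

    With an odd spike count the middle spike is realized exactly, so
    middle-spike recovery by the burst grouper is bit-exact.
    """
    mid_idx = (n_spikes - 1) // 2
    offsets = (np.arange(n_spikes) - mid_idx) * isi
    return (middles[:, None] + offsets[None, :]).ravel()


def generate_population(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[list[AnimalRecording], GroundTruth]:
    """Generate a labeled synthetic population of bilateral recordings.

    Each animal carries eight channels (two sides x two levels x
    front/rear).  Front channels define the cycle grid; rear middle
    spikes realize the hierarchical per-cycle phase differences relative
    to the front channel's own middle-spike times and periods, so on
    noise-free settings the analysis recovers the targets exactly.  The
    two sides swap coordinations simultaneously at every episode
    boundary.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sig2 = config.component_sigma2()
    n_ep = 2 * config.n_switch_cycles
    lo, hi = config.cycles_per_episode
    isi = config.burst_duty_cycle * config.period_mean / max(config.spikes_per_burst - 1, 1)
    if isi >= 1.0:
        raise ValueError(
            "intra-burst interspike interval >= 1 s would merge with the "
            "interburst-interval criterion; increase spikes_per_burst or "
            "reduce burst_duty_cycle"
        )

    recordings: list[AnimalRecording] = []
    ep_rows, cyc_rows, tgt_rows = [], [], []

    for a in range(config.n_animals):
        ep_len = rng.integers(lo, hi + 1, size=n_ep)
        n_cyc = int(ep_len.sum())
        bounds = np.concatenate([[0], np.cumsum(ep_len)])
        periods = rng.normal(
            config.period_mean, config.period_cv * config.period_mean, size=n_cyc + 1
        )
        periods = np.clip(periods, 0.25 * config.period_mean, None)
        t0 = config.period_mean  # headroom so a leading rear burst stays at t >= 0
        starts = t0 + np.concatenate([[0.0], np.cumsum(periods[:-1])])  # n_cyc+1 markers

        left_first = COORDS[int(rng.integers(0, 2))]
        coord_of = {"L": {}, "R": {}}
        for e in range(n_ep):
            cl = COORDS[(COORDS.index(left_first) + e) % 2]
            coord_of["L"][e] = cl
            coord_of["R"][e] = COORDS[1 - COORDS.index(cl)]
        ep_of_cycle = np.repeat(np.arange(n_ep), ep_len)

        A = {
            (lv, co): rng.normal(0.0, np.sqrt(sig2[(lv, co)]["animal"]))
            for lv in LEVELS
            for co in COORDS
        }
        spikes: dict[str, np.ndarray] = {}
        chan_rows = []
        for side in ("L", "R"):
            S = {
                (lv, co): rng.normal(0.0, np.sqrt(sig2[(lv, co)]["side"]))
                for lv in LEVELS
                for co in COORDS
            }
            for lv_i, level in enumerate(LEVELS):
                # front channel: its own middle-spike grid (motor level offset
                # by a fixed fraction of the cycle; irrelevant to dphi)
                front_m = starts + (0.0 if level == "cpg" else 0.08 * periods)
                front_T = np.diff(front_m)
                rear_targets = np.empty(n_cyc)
                for e in range(n_ep):
                    co = coord_of[side][e]
                    mu = _lookup(config.dphi_mean, level, co)
                    R = rng.normal(0.0, np.sqrt(sig2[(level, co)]["episode"]))
                    sl = slice(bounds[e], bounds[e + 1])
                    eps = rng.normal(0.0, np.sqrt(sig2[(level, co)]["cycle"]), ep_len[e])
                    target_mean = mu + A[(level, co)] + S[(level, co)] + R
                    rear_targets[sl] = target_mean + eps
                    tgt_rows.append(
                        {
                            "animal": a,
                            "side": side,
                            "level": level,
                            "episode": e,
                            "coordination": co,
                            "target_dphi": center_phase(target_mean),
                        }
                    )
                # place rear bursts with the centered phase so a slight lead
                # puts the burst just before its reference marker (it is then
                # matched to the preceding half-open cycle, where it measures
                # as the same point on the circle)
                rear_m = front_m[:-1] + center_phase(rear_targets) * front_T
                for role, middles in (("front", front_m), ("rear", rear_m)):
                    name = _channel_name(a, side, level, role)
                    s = _burst_spikes(middles, config.spikes_per_burst, isi)
                    if np.any(np.diff(s) <= 0):
                        # extreme phase jitter can interleave adjacent bursts;
                        # a unit's spike train is ordered in time regardless
                        s = np.unique(s)
                    spikes[name] = s
                    chan_rows.append(
                        {"channel": name, "side": side, "level": level, "role": role}
                    )
                cyc_rows.append(
                    pd.DataFrame(
                        {
                            "animal": a,
                            "side": side,
                            "level": level,
                            "cycle": np.arange(n_cyc),
                            "episode": ep_of_cycle,
                            "dphi": center_phase(rear_targets),
                        }
                    )
                )
            for e in range(n_ep):
                ep_rows.append(
                    {
                        "animal": a,
                        "side": side,
                        "episode": e,
                        "coordination": coord_of[side][e],
                        "start_cycle": int(bounds[e]),
                        "n_cycles": int(ep_len[e]),
                        "switch_cycle": e // 2 + 1,
                    }
                )
        recordings.append(
            AnimalRecording(animal=a, spikes=spikes, channel_map=pd.DataFrame(chan_rows))
        )

    truth = GroundTruth(
        episodes=pd.DataFrame(ep_rows),
        cycle_dphi=pd.concat(cyc_rows, ignore_index=True),
        episode_targets=pd.DataFrame(tgt_rows),
        config=replace(config),
    )
    return recordings, truth


def generate_switch_cycle_means(
    n_animals: int,
    mean_dphi: float = 0.2,
    sd_animal: float = 0.05,
    sd_episode: float = 0.02,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal mean phases for two switch cycles, means-level shortcut.

    Draws ``m_k = mu + A_i + R_{i,k}`` (wrapped) with animal SD
    ``sd_animal`` and per-switch-cycle SD ``sd_episode`` in phase units.
    With ``sd_animal = 0`` the two cycles are exchangeable across animals
    (animal identity carries no information), the null case for
    calibrating the scrambling test.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    A = rng.normal(0.0, sd_animal, n_animals)
    m1 = wrap_phase(mean_dphi + A + rng.normal(0.0, sd_episode, n_animals))
    m2 = wrap_phase(mean_dphi + A + rng.normal(0.0, sd_episode, n_animals))
    return m1, m2


def generate_constriction_traces(
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    n_cycles: int = 30,
    coordination: str = "peristaltic",
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], pd.DataFrame]:
    """Constriction-like sampled traces with known MRR times.

    Returns one trace per (side, segment in front/rear) plus a table of
    ground-truth MRR times and per-cycle phase targets.  Each beat is a
    half-cosine rise (maximum derivative exactly at mid-rise, the MRR
    marker) followed by a half-cosine relaxation.
    """
    config.validate()
    if coordination not in COORDS:
        raise ValueError(f"unknown coordination {coordination!r}")
    if config.trace_amplitude <= 0:
        raise ValueError("no constriction: trace amplitude must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.trace_fs
    rise = 0.25 * config.period_mean
    if fs * rise < 8:
        raise ValueError(
            "sampling rate too low to localize the maximum rate of rise; "
            f"need >= 8 samples on the {rise:.2f} s rise, got {fs * rise:.1f}"
        )
    periods = rng.normal(config.period_mean, config.period_cv * config.period_mean, n_cycles + 1)
    periods = np.clip(periods, 0.25 * config.period_mean, None)
    starts = 2.0 + np.concatenate([[0.0], np.cumsum(periods[:-1])])
    total = starts[-1] + 2.0 * config.period_mean
    t = np.arange(0.0, total, 1.0 / fs)

    u_cyc = wrapped_sigma2(_lookup(config.var_cycle, "motor", coordination))
    mu = _lookup(config.beat_dphi_mean, "beat", coordination)

    traces: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    rows = []
    for side in ("L", "R"):
        front_mrr = starts + 0.1 * np.concatenate([periods[:-1], periods[-1:]])
        dphi = mu + rng.normal(0.0, np.sqrt(u_cyc), n_cycles)
        rear_mrr = front_mrr[:-1] + wrap_phase(dphi) * np.diff(front_mrr)
        for seg, mrr in (("front", front_mrr), ("rear", rear_mrr)):
            y = np.zeros_like(t)
            for m, T in zip(mrr, np.full(len(mrr), config.period_mean)):
                r0 = m - rise / 2.0
                decay = 0.5 * T
                in_rise = (t >= r0) & (t < r0 + rise)
                y[in_rise] += 0.5 * (1.0 - np.cos(np.pi * (t[in_rise] - r0) / rise))
                in_decay = (t >= r0 + rise) & (t < r0 + rise + decay)
                y[in_decay] += 0.5 * (
                    1.0 + np.cos(np.pi * (t[in_decay] - r0 - rise) / decay)
                )
            y *= config.trace_amplitude
            if np.isfinite(config.trace_snr):
                y = y + rng.normal(0.0, config.trace_amplitude / config.trace_snr, y.size)
            traces[f"{side}_{seg}"] = (t, y)
            for k, m in enumerate(mrr):
                rows.append({"side": side, "segment": seg, "cycle": k, "mrr_time": float(m)})
        for k in range(n_cycles):
            rows.append(
                {
                    "side": side,
                    "segment": "dphi",
                    "cycle": k,
                    "mrr_time": np.nan,
                    "dphi": center_phase(dphi[k]),
                }
            )
    return traces, pd.DataFrame(rows)


def generate_clamp_trace(
    spike_times: Mapping[str, np.ndarray],
    strengths_nS: Mapping[str, float],
    holding_mV: float = -42.0,
    reversal_mV: float = -62.0,
    noise_sd_pA: float = 0.0,
    fs: float = 2000.0,
    tau_s: float = 0.02,
    duration_s: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Voltage-clamp current trace from known synaptic conductances.

    Every presynaptic spike contributes an alpha-function IPSC kernel
    ``(t/tau) exp(1 - t/tau)`` (unit peak) scaled by ``g * (V_hold -
    E_rev)``; currents are in pA with g in nS and potentials in mV.
    Overlapping kernels sum.  Returns ``(t, I)``.
    """
    if holding_mV == reversal_mV:
        raise ValueError("holding potential must differ from the reversal potential")
    for unit, g in strengths_nS.items():
        if g < 0:
            raise ValueError(f"negative conductance for unit {unit!r}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    drive = holding_mV - reversal_mV
    all_spikes = np.concatenate([np.asarray(s, float) for s in spike_times.values()])
    if duration_s is None:
        duration_s = (all_spikes.max() if all_spikes.size else 0.0) + 12.0 * tau_s
    t = np.arange(0.0, duration_s, 1.0 / fs)
    current = np.zeros_like(t)
    kern_t = np.arange(0.0, 12.0 * tau_s, 1.0 / fs)
    kernel = (kern_t / tau_s) * np.exp(1.0 - kern_t / tau_s)
    for unit, times in spike_times.items():
        amp = strengths_nS[unit] * drive
        if amp == 0.0:
            continue
        for ts in np.asarray(times, float):
            i0 = int(np.round(ts * fs))
            if i0 >= t.size:
                continue
            i1 = min(i0 + kernel.size, t.size)
            current[i0:i1] += amp * kernel[: i1 - i0]
    if noise_sd_pA > 0:
        current = current + rng.normal(0.0, noise_sd_pA, current.size)
    return t, current
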