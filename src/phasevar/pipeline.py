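"""End-to-end analysis pipeline: spikes -> phases -> episodes -> variances.

Stage order: burst grouping and cycle pairing per channel pair,
coordination-episode segmentation per animal, per-episode circular
summaries, then the population / repetition / bilateral statistics and
the variance-component decomposition per level and coordination.  All
randomness (bootstrap, scrambling) derives from one seed through named
substreams, so every table is reproducible independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bursts import SpikeTrain, group_bursts, pair_cycles
from .circular import center_phase, period_cv
from .episodes import classify_episodes
from .io import RunConfig, read_spike_table, write_manifest, write_report
from .variability import (
    bilateral_test,
    compare_levels,
    cycle_to_cycle_variance,
    estimate_variance_components,
    outlier_screen,
    population_variance,
    repetition_test,
)

__all__ = ["PipelineResult", "analyze_spikes", "run_pipeline", "substreams"]


def substreams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """Named independent random substreams derived from one root seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


@dataclass
class PipelineResult:
    """Report bundle: tidy tables plus the run manifest."""

    cycle_dphi: pd.DataFrame
    episodes: pd.DataFrame
    cycle_means: pd.DataFrame
    population: pd.DataFrame
    repetition: pd.DataFrame
    bilateral: pd.DataFrame
    components: pd.DataFrame
    level_comparisons: pd.DataFrame
    period_stats: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "cycle_dphi": self.cycle_dphi,
            "episodes": self.episodes,
            "cycle_means": self.cycle_means,
            "population": self.population,
            "repetition": self.repetition,
            "bilateral": self.bilateral,
            "components": self.components,
            "level_comparisons": self.level_comparisons,
            "period_stats": self.period_stats,
        }


def _phase_series_for(spikes, chmap, animal, side, level, cfg, log):
    ref_ch = tgt_ch = None
    for ch, info in chmap.items():
        if info["animal"] == animal and info["side"] == side and info["level"] == level:
            if info["role"] == "front":
                ref_ch = ch
            else:
                tgt_ch = ch
    if ref_ch is None or tgt_ch is None:
        return None
    for ch in (ref_ch, tgt_ch):
        if ch not in spikes:
            raise ValueError(f"channel {ch!r} referenced by channel_map not found in spike table")
    ref = group_bursts(SpikeTrain(ref_ch, spikes[ref_ch]), cfg.ibi_threshold, cfg.min_spikes)
    tgt = group_bursts(SpikeTrain(tgt_ch, spikes[tgt_ch]), cfg.ibi_threshold, cfg.min_spikes)
    ps = pair_cycles(ref, tgt, side=side, level=level)
    if ps.skipped.size:
        log.append(
            f"animal {animal} {side}/{level}: skipped {ps.skipped.size} cycles "
            "with zero or multiple target markers"
        )
    return ps, ref


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full analysis described by ``cfg`` and return all tables.

    Reads the spike table from disk, analyzes it, and writes the report
    tables and a manifest to ``cfg.out_dir`` when set.
    """
    spikes = read_spike_table(cfg.spike_table)
    result = analyze_spikes(spikes, cfg)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in result.tables().items():
            write_report(out / f"{name}.tsv", table)
        write_manifest(out / "manifest.json", result.manifest)
    return result


def analyze_spikes(spikes: dict, cfg: RunConfig) -> PipelineResult:
    """Analyze per-channel spike times already in memory (core pipeline)."""
    cfg.validate()
    rngs = substreams(cfg.seed, ["bootstrap", "repetition", "bilateral"])
    log: list[str] = []
    chmap = cfg.channel_map
    animals = sorted({info["animal"] for info in chmap.values()})
    levels = sorted({info["level"] for info in chmap.values()})

    cycle_rows, ep_rows, mean_rows, period_rows = [], [], [], []
    for animal in animals:
        series = {}
        ref_series = {}
        for side in ("L", "R"):
            for level in levels:
                got = _phase_series_for(spikes, chmap, animal, side, level, cfg, log)
                if got is not None:
                    series[(side, level)], ref_series[(side, level)] = got
        # classification uses the first level with both sides present
        cls_level = next(
            (lv for lv in levels if ("L", lv) in series and ("R", lv) in series), None
        )
        if cls_level is None:
            log.append(f"animal {animal}: no bilateral level; skipped")
            continue
        episet = classify_episodes(
            series[("L", cls_level)],
            series[("R", cls_level)],
            threshold=cfg.classification_threshold,
            hysteresis=cfg.hysteresis,
        )
        ref = ref_series[("L", cls_level)]
        periods = ref.periods
        period_rows.append(
            {
                "animal": animal,
                "n_periods": periods.size,
                "mean_period": float(np.mean(periods)),
                "period_cv": period_cv(periods),
            }
        )
        for level in levels:
            for side in ("L", "R"):
                if (side, level) not in series:
                    continue
                ps = series[(side, level)]
                lookup = dict(zip(ps.cycles.tolist(), ps.dphi.tolist()))
                for k, ep in enumerate(episet.for_side(side)):
                    cycles = [c for c in ep.cycles if c in lookup]
                    dphi = np.array([lookup[c] for c in cycles])
                    ep2 = type(ep)(
                        side=ep.side,
                        coordination=ep.coordination,
                        start_cycle=ep.start_cycle,
                        end_cycle=ep.end_cycle,
                        cycles=np.asarray(cycles, dtype=int),
                        dphi=dphi,
                    )
                    ep_rows.append(
                        {
                            "animal": animal,
                            "side": side,
                            "level": level,
                            "episode": k,
                            "coordination": ep.coordination,
                            "start_cycle": ep.start_cycle,
                            "end_cycle": ep.end_cycle,
                            "n_cycles": ep2.n_cycles,
                        }
                    )
                    for c, d in zip(ep2.cycles, ep2.dphi):
                        cycle_rows.append(
                            {
                                "animal": animal,
                                "side": side,
                                "level": level,
                                "cycle": int(c),
                                "episode": k,
                                "coordination": ep.coordination,
                                "dphi": float(d),
                            }
                        )
                    with warnings.catch_warnings(record=True) as wlog:
                        warnings.simplefilter("always")
                        summ = cycle_to_cycle_variance(ep2, min_cycles=cfg.min_episode_cycles)
                    for w in wlog:
                        log.append(f"animal {animal} {side}/{level}: {w.message}")
                    if summ is None:
                        continue
                    mean_rows.append(
                        {
                            "animal": animal,
                            "side": side,
                            "level": level,
                            "coordination": ep.coordination,
                            "episode": k,
                            "switch_cycle": k // 2 + 1,
                            "mean_dphi": center_phase(summ.mean_phase),
                            "cycle_var": summ.var_phase,
                            "n_cycles": summ.n,
                        }
                    )

    cycle_dphi = pd.DataFrame(cycle_rows)
    episodes = pd.DataFrame(ep_rows)
    cycle_means = pd.DataFrame(mean_rows)
    period_stats = pd.DataFrame(period_rows)

    coords = sorted(cycle_means["coordination"].unique()) if len(cycle_means) else []
    pop_rows, rep_rows, bil_rows, comp_rows = [], [], [], []
    excluded: list[str] = []
    for level in levels:
        for coord in coords:
            sub = cycle_means[
                (cycle_means["level"] == level) & (cycle_means["coordination"] == coord)
            ]
            if sub.empty:
                continue
            pop_sel = sub[(sub["side"] == "L") & (sub["switch_cycle"] == 1)]
            means = pop_sel.set_index("animal")["mean_dphi"]
            if len(means) >= 4:
                flags = outlier_screen(means.to_numpy())
                if flags.any():
                    bad = means.index[flags].tolist()
                    excluded.append(
                        f"{level}/{coord}: animals {bad} outside 1.5*IQR; excluded"
                    )
                    means = means[~flags]
            if len(means) >= 3:
                pv = population_variance(
                    means.to_numpy(),
                    n_boot=cfg.n_boot,
                    ci=cfg.ci_level,
                    rng=rngs["bootstrap"],
                    method=cfg.ci_method,
                )
                pop_rows.append(
                    {
                        "level": level,
                        "coordination": coord,
                        "side": "L",
                        "n": pv.n,
                        "mean_dphi": pv.mean_dphi,
                        "var_phase": pv.var_phase,
                        "ci_lo": pv.ci_lo,
                        "ci_hi": pv.ci_hi,
                        "ci_level": pv.ci_level,
                        "n_boot": pv.n_boot,
                        "method": pv.method,
                    }
                )
            piv = sub[sub["side"] == "L"].pivot_table(
                index="animal", columns="switch_cycle", values="mean_dphi"
            )
            if 1 in piv.columns and 2 in piv.columns and len(piv[[1, 2]].dropna()) >= 5:
                both = piv[[1, 2]].dropna()
                res = repetition_test(
                    both[1].to_numpy(),
                    both[2].to_numpy(),
                    n_scramble=cfg.n_scramble,
                    rng=rngs["repetition"],
                    pairing=cfg.pairing,
                )
                rep_rows.append(
                    {
                        "level": level,
                        "coordination": coord,
                        "side": "L",
                        "n": res.n_pairs,
                        "observed_var": res.observed,
                        "mean_abs_ddphi": res.mean_abs_ddphi,
                        "null_mean": res.null_mean,
                        "null_sd": res.null_sd,
                        "z": res.z,
                        "p_lower": res.p_lower,
                        "p_two_sided": res.p_two_sided,
                    }
                )
            pivlr = sub[sub["switch_cycle"] == 1].pivot_table(
                index="animal", columns="side", values="mean_dphi"
            )
            if (
                "L" in pivlr.columns
                and "R" in pivlr.columns
                and len(pivlr[["L", "R"]].dropna()) >= 5
            ):
                both = pivlr[["L", "R"]].dropna()
                res = bilateral_test(
                    both["L"].to_numpy(),
                    both["R"].to_numpy(),
                    n_scramble=cfg.n_scramble,
                    rng=rngs["bilateral"],
                    pairing=cfg.pairing,
                )
                bil_rows.append(
                    {
                        "level": level,
                        "coordination": coord,
                        "n": res.n_pairs,
                        "observed_var": res.observed,
                        "mean_abs_ddphi": res.mean_abs_ddphi,
                        "null_mean": res.null_mean,
                        "null_sd": res.null_sd,
                        "z": res.z,
                        "p_lower": res.p_lower,
                        "p_two_sided": res.p_two_sided,
                    }
                )
            try:
                comp = estimate_variance_components(cycle_means, level, coord)
                comp_rows.append({"level": level, "coordination": coord, **comp})
            except ValueError as exc:
                log.append(f"{level}/{coord}: variance components unavailable ({exc})")

    cmp_rows = []
    if len(levels) >= 2 and len(cycle_means):
        for coord in coords:
            sub = cycle_means[
                (cycle_means["coordination"] == coord)
                & (cycle_means["side"] == "L")
                & (cycle_means["switch_cycle"] == 1)
            ]
            piv = sub.pivot_table(index="animal", columns="level", values="mean_dphi")
            for i, lv_a in enumerate(levels):
                for lv_b in levels[i + 1 :]:
                    if lv_a not in piv.columns or lv_b not in piv.columns:
                        continue
                    both = piv[[lv_a, lv_b]].dropna()
                    if len(both) < 2:
                        continue
                    res = compare_levels(
                        both[lv_a].to_numpy(), both[lv_b].to_numpy(), paired=True
                    )
                    cmp_rows.append(
                        {
                            "coordination": coord,
                            "level_a": lv_a,
                            "level_b": lv_b,
                            "n": len(both),
                            "mean_a": res.mean_a,
                            "mean_b": res.mean_b,
                            "t": res.t,
                            "p": res.p,
                            "paired": True,
                        }
                    )

    manifest = {
        "phasevar_version": __version__,
        "seed": cfg.seed,
        "n_boot": cfg.n_boot,
        "n_scramble": cfg.n_scramble,
        "ci_level": cfg.ci_level,
        "ci_method": cfg.ci_method,
        "pairing": cfg.pairing,
        "classification_threshold": cfg.classification_threshold,
        "hysteresis": cfg.hysteresis,
        "ibi_threshold": cfg.ibi_threshold,
        "min_spikes": cfg.min_spikes,
        "min_episode_cycles": cfg.min_episode_cycles,
        "n_animals": len(animals),
        "levels": levels,
        "exclusions": excluded,
        "log": log,
    }
    result = PipelineResult(
        cycle_dphi=cycle_dphi,
        episodes=episodes,
        cycle_means=cycle_means,
        population=pd.DataFrame(pop_rows),
        repetition=pd.DataFrame(rep_rows),
        bilateral=pd.DataFrame(bil_rows),
        components=pd.DataFrame(comp_rows),
        level_comparisons=pd.DataFrame(cmp_rows),
        period_stats=period_stats,
        manifest=manifest,
    )
    return result
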