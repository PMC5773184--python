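"""Delimited-text readers/writers and run configuration.

All on-disk formats are plain tab-separated text:

* spike tables: columns ``channel`` (string id) and ``time`` (seconds),
  times strictly increasing within a channel;
* traces: columns ``time`` and ``value``;
* report tables: tidy tables with a fixed documented column order.

Run configuration is YAML; see :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RunConfig",
    "load_config",
    "read_spike_table",
    "read_trace",
    "simulate_to_dir",
    "write_report",
    "write_spike_table",
    "write_trace",
]

FLOAT_FMT = "%.12g"  # report tables
FULL_FMT = "%.17g"  # raw data: lossless float round-trip


def write_spike_table(path, spikes: dict[str, np.ndarray]) -> None:
    """Write spike times as a two-column (channel, time) TSV."""
    rows = []
    for channel in sorted(spikes):
        t = np.asarray(spikes[channel], dtype=float)
        rows.append(pd.DataFrame({"channel": channel, "time": t}))
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["channel", "time"])
    df.to_csv(path, sep="\t", index=False, float_format=FULL_FMT)


def read_spike_table(path) -> dict[str, np.ndarray]:
    """Read a (channel, time) TSV into per-channel spike-time arrays.

    Malformed rows and non-increasing times are rejected with the
    offending line number; an empty file yields an empty dict with a
    warning.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if not text or (len(text) == 1 and not text[0].strip()):
        warnings.warn(f"{path}: empty spike table", stacklevel=2)
        return {}
    header = text[0].split("\t")
    if header[:2] != ["channel", "time"]:
        raise ValueError(f"{path}:1: expected header 'channel\\ttime', got {text[0]!r}")
    out: dict[str, list[float]] = {}
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
        channel, t_str = parts
        try:
            t = float(t_str)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad time value {t_str!r}") from exc
        times = out.setdefault(channel, [])
        if times and t <= times[-1]:
            raise ValueError(
                f"{path}:{lineno}: spike times of channel {channel!r} not strictly increasing"
            )
        times.append(t)
    return {ch: np.asarray(ts, dtype=float) for ch, ts in out.items()}


def write_trace(path, times: np.ndarray, values: np.ndarray) -> None:
    """Write a sampled signal as a two-column (time, value) TSV."""
    pd.DataFrame({"time": times, "value": values}).to_csv(
        path, sep="\t", index=False, float_format=FULL_FMT
    )


def read_trace(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (time, value) TSV; empty file yields empty arrays with a warning."""
    path = Path(path)
    if path.stat().st_size == 0:
        warnings.warn(f"{path}: empty trace file", stacklevel=2)
        return np.array([]), np.array([])
    try:
        df = pd.read_csv(path, sep="\t", dtype={"time": float, "value": float})
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: malformed trace file: {exc}") from exc
    if list(df.columns[:2]) != ["time", "value"]:
        raise ValueError(f"{path}: expected columns 'time' and 'value'")
    return df["time"].to_numpy(), df["value"].to_numpy()


def write_report(path, table: pd.DataFrame, columns: list[str] | None = None) -> None:
    """Write a tidy report table with a fixed column order."""
    if columns is not None:
        table = table[columns]
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    ``channel_map`` assigns each channel id its animal, side ('L'/'R'),
    level (e.g. 'cpg', 'motor') and role ('front' = phase reference,
    'rear' = target).
    """

    spike_table: str | None = None
    channel_map: dict[str, dict] = field(default_factory=dict)
    out_dir: str | None = None
    ibi_threshold: float = 1.0
    min_spikes: int = 3
    classification_threshold: float | str = "auto"
    hysteresis: int = 3
    min_episode_cycles: int = 7
    n_boot: int = 10_000
    n_scramble: int = 10_000
    ci_level: float = 0.95
    ci_method: str = "studentized"
    pairing: str = "derangement"
    seed: int = 0

    def validate(self) -> None:
        if not self.channel_map:
            raise ValueError("channel_map must not be empty")
        for ch, info in self.channel_map.items():
            for key in ("animal", "side", "level", "role"):
                if key not in info:
                    raise ValueError(f"channel {ch!r}: channel_map entry missing {key!r}")
            if info["side"] not in ("L", "R"):
                raise ValueError(f"channel {ch!r}: side must be 'L' or 'R'")
            if info["role"] not in ("front", "rear"):
                raise ValueError(f"channel {ch!r}: role must be 'front' or 'rear'")
        thr = self.classification_threshold
        if thr != "auto" and not 0 < float(thr) < 0.5:
            raise ValueError("classification_threshold must be 'auto' or in (0, 0.5)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.hysteresis < 1:
            raise ValueError("hysteresis must be >= 1")


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _channel_map_frame(recordings) -> dict[str, dict]:
    out = {}
    for rec in recordings:
        for row in rec.channel_map.itertuples(index=False):
            out[row.channel] = {
                "animal": int(rec.animal),
                "side": row.side,
                "level": row.level,
                "role": row.role,
            }
    return out


def simulate_to_dir(config, out_dir, rng=None) -> Path:
    """Generate a synthetic population and write it as a run directory.

    The directory (named by seed) contains the spike table, ground-truth
    tables, a ready-to-use analysis config and the generator settings.
    """
    from .synthetic import generate_population

    recordings, truth = generate_population(config, rng=rng)
    out = Path(out_dir) / f"run_seed{config.seed}"
    out.mkdir(parents=True, exist_ok=True)
    spikes = {}
    for rec in recordings:
        spikes.update(rec.spikes)
    write_spike_table(out / "spikes.tsv", spikes)
    write_report(out / "truth_episodes.tsv", truth.episodes)
    write_report(out / "truth_cycle_dphi.tsv", truth.cycle_dphi)
    write_report(out / "truth_episode_targets.tsv", truth.episode_targets)
    gen_cfg = dataclasses.asdict(truth.config)
    gen_cfg["dphi_mean"] = {f"{k[0]}/{k[1]}": v for k, v in gen_cfg["dphi_mean"].items()}
    with open(out / "generator_config.yaml", "w") as fh:
        yaml.safe_dump(gen_cfg, fh, sort_keys=True)
    run_cfg = RunConfig(
        spike_table=str(out / "spikes.tsv"),
        channel_map=_channel_map_frame(recordings),
        out_dir=str(out / "analysis"),
        seed=config.seed if config.seed is not None else 0,
    )
    with open(out / "analysis_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(run_cfg), fh, sort_keys=True)
    return out


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
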