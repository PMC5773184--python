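"""Segmentation of phase series into coordination episodes and switch cycles.

The two body sides express complementary coordinations at all times: one
side runs rear-to-front peristaltic (large intersegmental phase
difference) while the other runs near-synchronous (small phase
difference), with simultaneous side-to-side switches.  Classification is
driven by the magnitude of the per-cycle phase difference relative to a
threshold placed between the two coordinations' typical values, with a
hysteresis requirement so single-cycle excursions never register as
switches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bursts import PhaseSeries

PERISTALTIC = "peristaltic"
SYNCHRONOUS = "synchronous"

__all__ = [
    "CoordinationAmbiguityError",
    "Episode",
    "EpisodeSet",
    "SwitchCycle",
    "build_switch_cycles",
    "classify_episodes",
]


class CoordinationAmbiguityError(ValueError):
    """Raised when neither side can be assigned a coordination state."""


@dataclass
class Episode:
    """A run of cycles in one coordination on one side.

    ``cycles``/``dphi`` hold only the cycles that enter statistics:
    transitional cycles around switches and cycles whose instantaneous
    label disagrees with the episode's are excluded.
    """

    side: str
    coordination: str
    start_cycle: int
    end_cycle: int  # inclusive
    cycles: np.ndarray
    dphi: np.ndarray

    @property
    def n_cycles(self) -> int:
        return int(self.cycles.size)


@dataclass
class EpisodeSet:
    """Episodes for both sides plus the accepted switch cycle indices."""

    episodes: list[Episode]
    switches: list[int]
    transitional: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def for_side(self, side: str) -> list[Episode]:
        return [e for e in self.episodes if e.side == side]


@dataclass
class SwitchCycle:
    """Two temporally adjacent episodes completing both coordinations on a side."""

    side: str
    first: Episode
    second: Episode
    index: int


def _per_cycle_state(dphi_left, dphi_right, threshold):
    """+1 if left is peristaltic, -1 if right is, 0 if ambiguous.

    With a numeric ``threshold`` a side is peristaltic when its |dphi|
    exceeds the threshold and the other side's does not.  With
    ``threshold='auto'`` the comparison is relative: the side with the
    larger |dphi| is peristaltic, which is robust to the large
    animal-to-animal spread of the per-coordination means.
    """
    state = np.zeros(np.shape(dphi_left), dtype=int)
    if threshold == "auto":
        diff = np.abs(dphi_left) - np.abs(dphi_right)
        state[diff > 0] = 1
        state[diff < 0] = -1
        return state
    lp = np.abs(dphi_left) > threshold
    rp = np.abs(dphi_right) > threshold
    state[lp & ~rp] = 1
    state[rp & ~lp] = -1
    return state


def classify_episodes(
    left: PhaseSeries,
    right: PhaseSeries,
    threshold: float | str = "auto",
    hysteresis: int = 3,
) -> EpisodeSet:
    """Label each side's cycles peristaltic or synchronous and find switches.

    Per cycle, the side whose rear segment leads/lags the front by more
    than ``threshold`` (in absolute centered phase) is peristaltic and the
    other synchronous.  ``threshold='auto'`` (default) instead compares
    the two sides directly — the side with the larger |dphi| is
    peristaltic — which tracks each animal's own contrast and needs no
    tuning.  A change of state is accepted only when sustained for at
    least ``hysteresis`` cycles; the confirming cycles after each
    accepted switch are marked transitional and excluded from episode
    statistics, as are cycles whose instantaneous label disagrees with
    the prevailing state.  A run of ambiguous cycles (both sides above or
    both below threshold) of length >= ``hysteresis`` raises
    :class:`CoordinationAmbiguityError`.
    """
    if hysteresis < 1:
        raise ValueError("hysteresis must be >= 1")
    common, il, ir = np.intersect1d(left.cycles, right.cycles, return_indices=True)
    if common.size == 0:
        raise ValueError("left and right phase series share no cycles")
    dl = left.dphi[il]
    dr = right.dphi[ir]
    if threshold != "auto":
        threshold = float(threshold)
    state = _per_cycle_state(dl, dr, threshold)

    n = common.size
    # longest run of ambiguous cycles
    run = 0
    for s in state:
        run = run + 1 if s == 0 else 0
        if run >= hysteresis:
            raise CoordinationAmbiguityError(
                f"coordination ambiguous for {run} consecutive cycles "
                f"(threshold={threshold}); check threshold against the data"
            )

    def sustained(i: int, lab: int) -> bool:
        if i + hysteresis > n:
            return False
        return bool(np.all(state[i : i + hysteresis] == lab))

    # initial state: first cycle opening a sustained run
    current = 0
    start_i = 0
    for i in range(n):
        if state[i] != 0 and sustained(i, state[i]):
            current = int(state[i])
            start_i = i
            break
    if current == 0:
        raise CoordinationAmbiguityError("no sustained coordination state found")

    transitional = list(range(start_i))
    switches_i: list[int] = []
    seg_start = [start_i]
    i = start_i
    while i < n:
        s = state[i]
        if s != 0 and s != current and sustained(i, s):
            switches_i.append(i)
            seg_start.append(i)
            # exclusion window around the switch: the confirming cycles plus
            # the final cycle of the outgoing episode, whose target marker a
            # slight lead can pull across the boundary
            transitional.extend(range(max(i - 1, 0), min(i + hysteresis, n)))
            current = s
            i += hysteresis
        else:
            i += 1

    trans_mask = np.zeros(n, dtype=bool)
    trans_mask[transitional] = True

    bounds = seg_start + [n]
    episodes: list[Episode] = []
    # reconstruct the accepted state sequence segment by segment
    seg_states: list[int] = []
    cur = int(state[bounds[0]])
    seg_states.append(cur)
    for b in bounds[1:-1]:
        cur = -cur
        seg_states.append(cur)
    for (b0, b1), seg_state in zip(zip(bounds[:-1], bounds[1:]), seg_states):
        seg = slice(b0, b1)
        keep = (~trans_mask[seg]) & (state[seg] == seg_state)
        for side, d, coord in (
            ("L", dl, PERISTALTIC if seg_state == 1 else SYNCHRONOUS),
            ("R", dr, SYNCHRONOUS if seg_state == 1 else PERISTALTIC),
        ):
            episodes.append(
                Episode(
                    side=side,
                    coordination=coord,
                    start_cycle=int(common[b0]),
                    end_cycle=int(common[b1 - 1]),
                    cycles=common[seg][keep].astype(int),
                    dphi=d[seg][keep],
                )
            )
    return EpisodeSet(
        episodes=episodes,
        switches=[int(common[i]) for i in switches_i],
        transitional=common[trans_mask].astype(int),
    )


def build_switch_cycles(
    episode_set: EpisodeSet, side: str | None = None
) -> dict[str, list[SwitchCycle]]:
    """Pair consecutive episodes per side into complete switch cycles.

    Pairs are non-overlapping and start from the first episode, so three
    episodes yield one switch cycle and the trailing episode is left as a
    remainder.  Sides with fewer than two episodes yield an empty list
    with a warning.
    """
    sides = [side] if side is not None else ["L", "R"]
    out: dict[str, list[SwitchCycle]] = {}
    for s in sides:
        eps = episode_set.for_side(s)
        if len(eps) < 2:
            warnings.warn(f"side {s}: fewer than two episodes; no switch cycle", stacklevel=2)
            out[s] = []
            continue
        out[s] = [
            SwitchCycle(side=s, first=eps[2 * k], second=eps[2 * k + 1], index=k + 1)
            for k in range(len(eps) // 2)
        ]
    return out
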