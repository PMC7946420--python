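"""ISI-based burst / non-burst classification of spike trains.

A burst episode is opened by an interspike interval (ISI) at or below the
onset threshold (default 80 ms) and extended while ISIs stay at or below the
offset threshold (default 160 ms); an ISI above the offset threshold closes
the episode.  Every spike belonging to an episode is a "burst" spike, every
other spike is "non-burst".  Labeling never crosses trial boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["BurstCriteria", "BurstLabeling", "label_bursts", "label_session", "split_by_mode"]

MODE_BURST = "burst"
MODE_NON_BURST = "non_burst"


@dataclass(frozen=True)
class BurstCriteria:
    onset_isi_max: float = 80.0
    offset_isi_min: float = 160.0

    def __post_init__(self) -> None:
        if not (0 < self.onset_isi_max <= self.offset_isi_min):
            raise ValueError("require 0 < onset_isi_max <= offset_isi_min")


@dataclass
class BurstLabeling:
    """Per-spike labels plus the (first_index, last_index) burst episodes."""

    is_burst: np.ndarray  # bool, one entry per spike
    episodes: List[Tuple[int, int]]

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.is_burst, MODE_BURST, MODE_NON_BURST)

    @property
    def n_burst(self) -> int:
        return int(self.is_burst.sum())


def label_bursts(spike_times: Sequence[float], criteria: BurstCriteria | None = None) -> BurstLabeling:
    """Label each spike of one within-trial train as burst or non-burst.

    ``spike_times`` must be strictly increasing.  Fewer than two spikes can
    never form a burst.
    """
    criteria = criteria or BurstCriteria()
    t = np.asarray(spike_times, dtype=float)
    n = t.size
    if n > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("spike times must be strictly increasing within a trial")
    is_burst = np.zeros(n, dtype=bool)
    episodes: List[Tuple[int, int]] = []
    if n < 2:
        return BurstLabeling(is_burst, episodes)
    isis = np.diff(t)
    in_burst = False
    start = -1
    for i, isi in enumerate(isis):
        if not in_burst:
            if isi <= criteria.onset_isi_max:
                in_burst = True
                start = i
        else:
            if isi > criteria.offset_isi_min:
                episodes.append((start, i))
                is_burst[start : i + 1] = True
                in_burst = False
    if in_burst:
        episodes.append((start, n - 1))
        is_burst[start:] = True
    return BurstLabeling(is_burst, episodes)


def label_session(
    spikes: pd.DataFrame,
    criteria: BurstCriteria | None = None,
    time_col: str = "spike_time_ms",
) -> pd.DataFrame:
    """Return a copy of a spike table with a ``mode`` column appended.

    Spikes are grouped per (neuron_id, trial_id); within each group they are
    labeled independently so bursts never span trials or neurons.
    """
    criteria = criteria or BurstCriteria()
    out = spikes.copy()
    modes = np.empty(len(out), dtype=object)
    for _, idx in out.groupby(["neuron_id", "trial_id"], sort=False).indices.items():
        times = out[time_col].to_numpy()[idx]
        order = np.argsort(times, kind="stable")
        lab = label_bursts(times[order], criteria)
        modes[idx[order]] = lab.labels
    out["mode"] = modes
    return out


def split_by_mode(
    spikes: pd.DataFrame,
    criteria: BurstCriteria | None = None,
    time_col: str = "spike_time_ms",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a spike table into (burst-only, non-burst-only) tables.

    Both outputs keep the input schema (minus the transient ``mode`` column)
    so every downstream rate/SDF operation accepts them unchanged.
    """
    labeled = label_session(spikes, criteria, time_col)
    burst = labeled[labeled["mode"] == MODE_BURST].drop(columns="mode").reset_index(drop=True)
    non_burst = labeled[labeled["mode"] == MODE_NON_BURST].drop(columns="mode").reset_index(drop=True)
    return burst, non_burst


def episode_table(
    spikes: pd.DataFrame,
    criteria: BurstCriteria | None = None,
    time_col: str = "spike_time_ms",
) -> pd.DataFrame:
    """Burst episodes as (neuron_id, trial_id, start_ms, end_ms, n_spikes)."""
    criteria = criteria or BurstCriteria()
    rows = []
    for (neuron_id, trial_id), grp in spikes.groupby(["neuron_id", "trial_id"], sort=True):
        times = np.sort(grp[time_col].to_numpy())
        lab = label_bursts(times, criteria)
        for a, b in lab.episodes:
            rows.append(
                {
                    "neuron_id": neuron_id,
                    "trial_id": trial_id,
                    "start_ms": times[a],
                    "end_ms": times[b],
                    "n_spikes": b - a + 1,
                }
            )
    return pd.DataFrame(rows, columns=["neuron_id", "trial_id", "start_ms", "end_ms", "n_spikes"])
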