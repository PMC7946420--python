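"""Signal-level spike-train operations.

Event alignment, stop-time truncation, Gaussian spike-density functions,
baseline rates, coverage-aware binned rates, and velocity-threshold saccade
detection.  All operations work on :class:`~spikeramp.synth.SessionData`-style
tables: a trial table and a long-format spike table.

Conventions
-----------
* times are ms; rates are spikes/s;
* intervals are half-open ``[start, end)`` except where a final bin closes a
  global maximum;
* in the value-ramp conditions, analyses use only spikes emitted before the
  trial's stop time ("truncation"), and trial averaging is coverage-aware:
  a trial contributes to a time point/bin only while its valid horizon lasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "AnalysisWindows",
    "AlignedSpikes",
    "SDF",
    "align_spikes",
    "truncate_at_stop",
    "compute_sdf",
    "baseline_rate",
    "baseline_rate_per_trial",
    "window_rate_per_trial",
    "BinnedRates",
    "bin_rates",
    "detect_saccades",
]

log = logging.getLogger(__name__)

EVENT_COLUMNS = {
    "fixation_onset": "fixation_onset_ms",
    "cs_onset": "cs_onset_ms",
    "stop_onset": "stop_onset_ms",
    "reward_onset": "reward_onset_ms",
}


@dataclass
class AnalysisWindows:
    """Analysis windows, ms relative to their respective alignment events.

    ``baseline`` is relative to fixation onset, ``tonic_fit``/``cue_response``
    to CS onset, and ``stop_response`` to stop onset.  ``periods`` split the
    tonic fit window into initial/middle/late thirds; ``value_groups`` (ml)
    partition the reward range into small/medium/large trials.
    """

    baseline: Tuple[float, float] = (-500.0, 0.0)
    tonic_fit: Tuple[float, float] = (650.0, 2450.0)
    tonic_bin: float = 200.0
    cue_response: Tuple[float, float] = (100.0, 400.0)
    stop_response: Tuple[float, float] = (150.0, 500.0)
    periods: Tuple[Tuple[float, float], ...] = (
        (650.0, 1250.0),
        (1250.0, 1850.0),
        (1850.0, 2450.0),
    )
    value_groups: Tuple[Tuple[float, float], ...] = (
        (0.1, 0.16),
        (0.16, 0.23),
        (0.23, 0.3),
    )

    def __post_init__(self) -> None:
        a, b = self.tonic_fit
        n = (b - a) / self.tonic_bin
        if abs(n - round(n)) > 1e-9:
            raise ValueError("tonic_fit length must be divisible by tonic_bin")
        if self.periods[0][0] != a or self.periods[-1][1] != b:
            raise ValueError("periods must tile the tonic_fit window")
        for (s0, e0), (s1, e1) in zip(self.periods, self.periods[1:]):
            if e0 != s1:
                raise ValueError("periods must tile the tonic_fit window")
        for (s0, e0), (s1, e1) in zip(self.value_groups, self.value_groups[1:]):
            if e0 != s1:
                raise ValueError("value_groups must tile the reward range")

    @property
    def n_tonic_bins(self) -> int:
        a, b = self.tonic_fit
        return int(round((b - a) / self.tonic_bin))

    @property
    def tonic_bin_edges(self) -> np.ndarray:
        a, b = self.tonic_fit
        return np.linspace(a, b, self.n_tonic_bins + 1)

    @property
    def tonic_bin_centers(self) -> np.ndarray:
        edges = self.tonic_bin_edges
        return 0.5 * (edges[:-1] + edges[1:])

    def value_group_of(self, reward_ml) -> np.ndarray:
        """Index of the value group for each reward (last group closed)."""
        reward = np.atleast_1d(np.asarray(reward_ml, dtype=float))
        out = np.full(reward.shape, -1, dtype=int)
        for i, (lo, hi) in enumerate(self.value_groups):
            last = i == len(self.value_groups) - 1
            mask = (reward >= lo) & ((reward <= hi) if last else (reward < hi))
            out[mask] = i
        return out


@dataclass
class AlignedSpikes:
    """Per-trial spike times relative to an alignment event.

    ``times[trial_id]`` holds the relative spike times of one trial;
    ``trials`` is the matching slice of the trial table (indexed by
    trial_id); ``horizons[trial_id]`` — when set — is the trial's valid
    horizon in relative time (used after stop truncation).
    """

    event: str
    times: Dict[int, np.ndarray]
    trials: pd.DataFrame
    n_skipped: int = 0
    horizons: Optional[Dict[int, float]] = None

    @property
    def trial_ids(self) -> list:
        return list(self.times.keys())

    @property
    def n_trials(self) -> int:
        return len(self.times)


@dataclass
class SDF:
    """Trial-averaged spike density function on a regular time grid."""

    alignment_event: str
    time_ms: np.ndarray
    rate: np.ndarray
    n_trials_per_point: np.ndarray
    kernel_sigma: float
    baseline_subtracted: bool = False
    n_trials: int = 0

    @property
    def empty(self) -> bool:
        return self.n_trials == 0

    def subtract(self, baseline: float) -> "SDF":
        return SDF(
            alignment_event=self.alignment_event,
            time_ms=self.time_ms,
            rate=self.rate - baseline,
            n_trials_per_point=self.n_trials_per_point,
            kernel_sigma=self.kernel_sigma,
            baseline_subtracted=True,
            n_trials=self.n_trials,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.time_ms, "rate": self.rate, "n_trials": self.n_trials_per_point}
        )


def _select_trials(
    trials: pd.DataFrame, conditions: Optional[Sequence[str]], cs_types: Optional[Sequence[str]]
) -> pd.DataFrame:
    sel = trials[~trials["aborted"].astype(bool)]
    if conditions is not None:
        sel = sel[sel["condition"].isin(conditions)]
    if cs_types is not None:
        sel = sel[sel["cs_type"].isin(cs_types)]
    return sel


def align_spikes(
    session,
    neuron_id,
    event: str,
    conditions: Optional[Sequence[str]] = None,
    cs_types: Optional[Sequence[str]] = None,
    spikes: Optional[pd.DataFrame] = None,
) -> AlignedSpikes:
    """Spike times of one neuron, per trial, relative to ``event``.

    Aborted trials are excluded; trials without the event timestamp (e.g.
    stop alignment of a value-fixed trial) are skipped and counted in
    ``n_skipped``.  ``spikes`` may override the session spike table (e.g. a
    burst-only table from :func:`spikeramp.bursts.split_by_mode`).
    """
    if event not in EVENT_COLUMNS:
        raise ValueError(f"unknown alignment event {event!r}")
    col = EVENT_COLUMNS[event]
    trials = _select_trials(session.trials, conditions, cs_types)
    spk = session.spikes if spikes is None else spikes
    spk = spk[spk["neuron_id"] == neuron_id]
    by_trial = {tid: grp["spike_time_ms"].to_numpy() for tid, grp in spk.groupby("trial_id")}
    times: Dict[int, np.ndarray] = {}
    kept_rows = []
    n_skipped = 0
    for row in trials.itertuples(index=False):
        anchor = getattr(row, col)
        if anchor is None or (isinstance(anchor, float) and np.isnan(anchor)):
            n_skipped += 1
            continue
        raw = by_trial.get(row.trial_id, np.empty(0))
        times[row.trial_id] = np.sort(raw) - float(anchor)
        kept_rows.append(row)
    if n_skipped:
        log.warning("align_spikes(%s): skipped %d trials without event %s", neuron_id, n_skipped, event)
    kept = pd.DataFrame(kept_rows, columns=trials.columns) if kept_rows else trials.iloc[0:0]
    return AlignedSpikes(event=event, times=times, trials=kept.set_index("trial_id", drop=False), n_skipped=n_skipped)


def truncate_at_stop(aligned: AlignedSpikes) -> AlignedSpikes:
    """Drop spikes at or after each trial's stop time; record valid horizons.

    Expects CS-onset alignment of ramp-condition trials.  Trials without a
    stop time (value-fixed) keep all spikes and an unbounded horizon.
    """
    if aligned.event != "cs_onset":
        raise ValueError("stop truncation is defined for CS-onset alignment")
    times: Dict[int, np.ndarray] = {}
    horizons: Dict[int, float] = {}
    for tid, t in aligned.times.items():
        stop = aligned.trials.at[tid, "stop_time_ms"]
        if stop is None or (isinstance(stop, float) and np.isnan(stop)):
            times[tid] = t
            horizons[tid] = np.inf
        else:
            stop = float(stop)
            times[tid] = t[t < stop]
            horizons[tid] = stop
    return AlignedSpikes(
        event=aligned.event,
        times=times,
        trials=aligned.trials,
        n_skipped=aligned.n_skipped,
        horizons=horizons,
    )


def compute_sdf(
    aligned: AlignedSpikes,
    kernel_sigma: float = 15.0,
    grid: Optional[np.ndarray] = None,
    grid_range: Optional[Tuple[float, float]] = None,
    grid_step: float = 1.0,
) -> SDF:
    """Trial-averaged SDF: each spike replaced by a unit-area Gaussian.

    Single-trial SDFs (spikes/s) are averaged pointwise over the trials whose
    valid horizon covers the point; ``n_trials_per_point`` records the count.
    A zero-trial input yields an SDF flagged ``empty`` with NaN rates.
    """
    if grid is None:
        if grid_range is None:
            raise ValueError("provide either grid or grid_range")
        grid = np.arange(grid_range[0], grid_range[1] + grid_step / 2, grid_step)
    grid = np.asarray(grid, dtype=float)
    if aligned.n_trials == 0:
        return SDF(aligned.event, grid, np.full_like(grid, np.nan), np.zeros_like(grid), kernel_sigma, n_trials=0)
    num = np.zeros_like(grid)
    cov = np.zeros_like(grid)
    norm = 1000.0 / (kernel_sigma * np.sqrt(2.0 * np.pi))
    for tid, spikes in aligned.times.items():
        horizon = np.inf if aligned.horizons is None else aligned.horizons.get(tid, np.inf)
        mask = grid <= horizon
        if spikes.size:
            z = (grid[mask, None] - spikes[None, :]) / kernel_sigma
            trial_rate = norm * np.exp(-0.5 * z * z).sum(axis=1)
            num[mask] += trial_rate
        cov += mask
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(cov > 0, num / np.maximum(cov, 1), np.nan)
    return SDF(aligned.event, grid, rate, cov, kernel_sigma, n_trials=aligned.n_trials)


def window_rate_per_trial(aligned: AlignedSpikes, window: Tuple[float, float]) -> np.ndarray:
    """Firing rate (spikes/s) in ``[start, end)`` for each aligned trial."""
    a, b = window
    if b <= a:
        raise ValueError("window must have positive length")
    width_s = (b - a) / 1000.0
    return np.array(
        [np.count_nonzero((t >= a) & (t < b)) / width_s for t in aligned.times.values()]
    )


def baseline_rate_per_trial(session, neuron_id, windows: AnalysisWindows, conditions=None, spikes=None) -> np.ndarray:
    aligned = align_spikes(session, neuron_id, "fixation_onset", conditions=conditions, spikes=spikes)
    if aligned.n_trials == 0:
        raise ValueError("no valid trials for baseline computation")
    return window_rate_per_trial(aligned, windows.baseline)


def baseline_rate(session, neuron_id, windows: AnalysisWindows, conditions=None, spikes=None) -> float:
    """Mean pre-fixation firing rate (spikes/s) across trials."""
    return float(baseline_rate_per_trial(session, neuron_id, windows, conditions, spikes).mean())


@dataclass
class BinnedRates:
    """Per-bin mean rates with their centers and coverage bookkeeping."""

    rates: np.ndarray  # spikes/s, NaN where no trial covers the bin
    centers_ms: np.ndarray
    n_trials: np.ndarray  # trials contributing per bin
    exposure_s: np.ndarray  # pooled covered duration per bin


def bin_rates(
    aligned: AlignedSpikes,
    windows: AnalysisWindows,
    coverage: str = "whole",
) -> BinnedRates:
    """Mean firing rate in each tonic-fit bin, honouring stop coverage.

    With ``coverage='whole'`` (default) a trial contributes to a bin only if
    its valid horizon covers the entire bin; with ``coverage='partial'`` a
    trial contributes its covered fraction of the bin (rate = pooled count /
    pooled covered duration).  Bins with no covering trial are NaN; if every
    bin is missing a ``ValueError`` is raised.
    """
    edges = windows.tonic_bin_edges
    centers = windows.tonic_bin_centers
    nb = windows.n_tonic_bins
    counts = np.zeros(nb)
    exposure_s = np.zeros(nb)
    n_cov = np.zeros(nb)
    if coverage not in ("whole", "partial"):
        raise ValueError("coverage must be 'whole' or 'partial'")
    for tid, t in aligned.times.items():
        horizon = np.inf if aligned.horizons is None else aligned.horizons.get(tid, np.inf)
        for k in range(nb):
            lo, hi = edges[k], edges[k + 1]
            if coverage == "whole":
                if horizon < hi:
                    continue
                dur = hi - lo
                upper = hi
            else:
                upper = min(hi, horizon)
                dur = upper - lo
                if dur <= 0:
                    continue
            last = k == nb - 1
            # half-open bins except the final bin, closed at the global max
            if last and upper == edges[-1]:
                sel = (t >= lo) & (t <= upper)
            else:
                sel = (t >= lo) & (t < upper)
            counts[k] += np.count_nonzero(sel)
            exposure_s[k] += dur / 1000.0
            n_cov[k] += 1
    if coverage == "whole":
        width_s = windows.tonic_bin / 1000.0
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(n_cov > 0, counts / np.maximum(n_cov, 1) / width_s, np.nan)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(exposure_s > 0, counts / np.where(exposure_s > 0, exposure_s, 1.0), np.nan)
    if np.all(np.isnan(rates)):
        raise ValueError("all tonic bins are missing (no trial covers any bin)")
    return BinnedRates(rates, centers.copy(), n_cov, exposure_s)


def period_rates(
    aligned: AlignedSpikes,
    windows: AnalysisWindows,
    baseline: float = 0.0,
) -> np.ndarray:
    """Pooled firing rate per initial/middle/late period, minus ``baseline``.

    Uses partial coverage (pooled counts over pooled covered durations) so
    the late period — which no trial covers in full under a continuous stop
    distribution — still receives an estimate from partially covered trials.
    Periods with zero covered duration are NaN.
    """
    out = np.full(len(windows.periods), np.nan)
    for i, (lo, hi) in enumerate(windows.periods):
        count = 0.0
        exposure = 0.0
        for tid, t in aligned.times.items():
            horizon = np.inf if aligned.horizons is None else aligned.horizons.get(tid, np.inf)
            dur = min(hi, horizon) - lo
            if dur <= 0:
                continue
            count += np.count_nonzero((t >= lo) & (t < min(hi, horizon)))
            exposure += dur / 1000.0
        if exposure > 0:
            out[i] = count / exposure - baseline
    return out


def detect_saccades(
    gaze: pd.DataFrame,
    velocity_threshold: float = 40.0,
    merge_ms: float = 50.0,
    median_window: int = 3,
) -> np.ndarray:
    """Saccade onsets (ms) from a fixed-rate gaze trace.

    Positions are median-smoothed (3 samples), angular velocity is taken by
    central differences, and the onset of each supra-threshold run is
    reported; runs separated by less than ``merge_ms`` are merged.  Sampling
    jitter above 10 % of the median interval is rejected.
    """
    if len(gaze) < 2:
        raise ValueError("need at least two gaze samples")
    t = gaze["sample_time_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("gaze timestamps must be strictly increasing")
    dt = np.diff(t)
    if np.max(np.abs(dt - np.median(dt))) > 0.1 * np.median(dt):
        raise ValueError("irregular gaze sampling (jitter exceeds 10% of the sample interval)")
    x = median_filter(gaze["x_deg"].to_numpy(dtype=float), size=median_window, mode="nearest")
    y = median_filter(gaze["y_deg"].to_numpy(dtype=float), size=median_window, mode="nearest")
    vx = np.gradient(x, t) * 1000.0  # deg/s
    vy = np.gradient(y, t) * 1000.0
    speed = np.hypot(vx, vy)
    above = speed > velocity_threshold
    if not np.any(above):
        return np.empty(0)
    idx = np.flatnonzero(above)
    run_starts = [idx[0]]
    run_ends = [idx[0]]
    for i in idx[1:]:
        if t[i] - t[run_ends[-1]] < merge_ms:
            run_ends[-1] = i
        else:
            run_starts.append(i)
            run_ends.append(i)
    return t[np.array(run_starts)]
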