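"""Synthetic sessions: spike trains, gaze, licks and choice behaviour.

The generator realises every statistical structure the analysis pipeline
assumes, with retained ground truth for parameter-recovery and white-box
tests:

* a *tonic* spike stream whose intensity follows the cued value trajectory,
  ``lambda(t) = lambda0 + g * (value(t) - value(CS onset))``.  Its point
  process depends on the neuron's tonic mode: for ``non_burst_dominant`` a
  dead-time renewal process (ISI = refractory floor + exponential, with the
  driving intensity compensated so the output rate matches ``lambda(t)``) —
  the floor exceeds the 80 ms burst-onset criterion, so tonic spikes alone
  can never open a burst; ``mixed`` uses an inhomogeneous Poisson process
  (time-rescaling) and ``burst_dominant`` a clustered gamma renewal;
* *phasic* raised-cosine intensity kernels at CS onset (scaled by the cued
  value level) and at stop onset (scaled by the fixed value, with an optional
  per-condition offset so stop responses can be net-inhibitory).  Excitatory
  kernels are sampled by Poisson thinning; inhibitory kernels are subtracted
  from the tonic intensity before sampling;
* a configurable fraction of phasic spikes seeds a burst: extra spikes with
  intra-burst ISIs below the 80 ms onset criterion;
* a 3 ms absolute dead time applied after merging all streams.

Every generated spike carries a provenance tag (``baseline`` | ``tonic`` |
``phasic`` | ``burst_member``) kept in a separate debug table; analysis
stages never read it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .task import (
    CS_UNCERTAIN,
    CS_VALUE_LEVELS,
    RAMP_CONDITIONS,
    VALUE_DECREASE,
    VALUE_FIXED,
    VALUE_INCREASE,
    TaskConfig,
    TrialSpec,
    sample_block,
    trial_value_trajectory,
)

__all__ = [
    "NeuronGroundTruth",
    "SessionData",
    "make_neuron",
    "simulate_trial_spikes",
    "simulate_population",
    "simulate_gaze",
    "simulate_licks",
    "simulate_choice_sessions",
]

TONIC_MODES = ("non_burst_dominant", "mixed", "burst_dominant")
_TONIC_SHAPE = {"mixed": 1.0, "burst_dominant": 0.6}

TAG_BASELINE = "baseline"
TAG_TONIC = "tonic"
TAG_PHASIC = "phasic"
TAG_BURST = "burst_member"

DEAD_TIME_MS = 3.0


@dataclass
class NeuronGroundTruth:
    """Generative parameters of one simulated neuron.

    Gains: ``tonic_gain_*`` are spikes/s per ml of value change in the
    corresponding ramp condition; ``cs_phasic_gain`` and ``stop_phasic_gain``
    are spikes/s of peak kernel amplitude per 0.1-ml value level.
    ``stop_phasic_offset`` is an additive peak amplitude (spikes/s) applied
    in the (value-increase, value-decrease) conditions, letting stop
    responses be net-inhibitory in one condition.
    """

    neuron_id: int
    baseline_rate: float = 4.0
    tonic_gain_increase: float = 0.0
    tonic_gain_decrease: float = 0.0
    cs_phasic_gain: float = 0.0
    stop_phasic_gain: float = 0.0
    stop_phasic_offset: Tuple[float, float] = (0.0, 0.0)
    phasic_latency: float = 100.0
    phasic_duration: float = 300.0
    burst_fraction: float = 0.0
    burst_length_mean: float = 3.0
    intra_burst_isi: Tuple[float, float] = (10.0, 60.0)
    tonic_mode: str = "non_burst_dominant"
    tonic_refractory: float = 90.0  # ISI floor (ms) of the non-burst-dominant stream
    cell_class: str = "custom"

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        if not (0.0 <= self.burst_fraction <= 1.0):
            raise ValueError("burst_fraction must be in [0, 1]")
        lo, hi = self.intra_burst_isi
        if not (0.0 < lo <= hi <= 80.0):
            raise ValueError("intra-burst ISIs must lie in (0, 80] ms")
        if self.tonic_mode not in TONIC_MODES:
            raise ValueError(f"unknown tonic_mode {self.tonic_mode!r}")
        if self.tonic_refractory <= 0:
            raise ValueError("tonic_refractory must be positive")
        for g in (
            self.tonic_gain_increase,
            self.tonic_gain_decrease,
            self.cs_phasic_gain,
            self.stop_phasic_gain,
        ):
            if not np.isfinite(g):
                raise ValueError("gains must be finite")

    def cue_level(self, trial: TrialSpec) -> float:
        """Value level (0.1-ml units) scaling the CS-onset kernel."""
        if trial.condition == VALUE_INCREASE:
            return 1.0
        if trial.condition == VALUE_DECREASE:
            return 3.0
        if trial.cs_type == CS_UNCERTAIN:
            return 2.0  # expectation of the uncertain CS
        return CS_VALUE_LEVELS[trial.cs_type]


@dataclass
class SessionData:
    """Trials + spikes (+ optional gaze/licks) for one session.

    ``ground_truth`` and ``spike_tags`` are present only for simulated data;
    no analysis stage reads them.
    """

    trials: pd.DataFrame
    spikes: pd.DataFrame
    gaze: Optional[pd.DataFrame] = None
    licks: Optional[pd.DataFrame] = None
    ground_truth: Optional[List[NeuronGroundTruth]] = None
    spike_tags: Optional[pd.DataFrame] = None
    session_id: str = "session"

    @property
    def neuron_ids(self) -> np.ndarray:
        return np.unique(self.spikes["neuron_id"].to_numpy())

    def trial_spec(self, trial_id: int) -> pd.Series:
        return self.trials.set_index("trial_id").loc[trial_id]


# ---------------------------------------------------------------------------
# spike generation
# ---------------------------------------------------------------------------

def _raised_cosine(t: np.ndarray, onset: float, latency: float, duration: float) -> np.ndarray:
    """Unit-peak smooth bump on [onset+latency, onset+latency+duration]."""
    u = (t - onset - latency) / duration
    out = np.zeros_like(t, dtype=float)
    mask = (u >= 0.0) & (u <= 1.0)
    out[mask] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u[mask]))
    return out


def _phasic_events(neuron: NeuronGroundTruth, trial: TrialSpec, config: TaskConfig) -> List[Tuple[float, float]]:
    """(event_time, peak_amplitude spikes/s) for this trial's kernels."""
    events: List[Tuple[float, float]] = []
    if neuron.cs_phasic_gain != 0.0:
        events.append((trial.cs_onset, neuron.cs_phasic_gain * neuron.cue_level(trial)))
    if trial.condition in RAMP_CONDITIONS and neuron.stop_phasic_gain != 0.0:
        level = trial.reward_ml / 0.1
        offset = neuron.stop_phasic_offset[0 if trial.condition == VALUE_INCREASE else 1]
        events.append((trial.stop_onset, neuron.stop_phasic_gain * level + offset))
    return events


def _gamma_renewal_unit_rate(rng: np.random.Generator, shape: float, total: float, burn: float = 10.0) -> np.ndarray:
    """Arrival times of a unit-rate gamma renewal process on (0, total].

    Started ``burn`` expected events before zero so the process is close to
    equilibrium at time zero.
    """
    if total <= 0:
        return np.empty(0)
    arrivals: List[float] = []
    t = -burn
    scale = 1.0 / shape
    # draw in chunks; expected number of events is burn + total
    while True:
        chunk = rng.gamma(shape, scale, size=max(16, int(1.5 * (burn + total - t))))
        for isi in chunk:
            t += isi
            if t > total:
                return np.array([a for a in arrivals])
            if t > 0:
                arrivals.append(t)


def _dead_time_renewal(
    rng: np.random.Generator,
    grid: np.ndarray,
    lam: np.ndarray,
    floor_ms: float,
    burn_ms: float = 1500.0,
) -> np.ndarray:
    """Renewal spikes with ISI = floor + Exp, output rate matched to ``lam``.

    The driving intensity is compensated, ``lam' = lam / (1 - lam * floor)``,
    so the steady-state output rate of the dead-time process equals ``lam``
    (quasi-static for slowly varying intensities).  Rates at or above
    ``1/floor`` are clamped just below the ceiling.
    """
    lam_frac = np.minimum(lam * floor_ms / 1000.0, 0.95)
    lam_drive = lam / (1.0 - lam_frac)  # spikes/s
    # prepend a constant burn-in stretch so the process starts in equilibrium
    n_burn = int(burn_ms)
    grid_ext = np.concatenate([grid[0] - burn_ms + np.arange(n_burn), grid])
    lam_ext = np.concatenate([np.full(n_burn, lam_drive[0]), lam_drive])
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (lam_ext[1:] + lam_ext[:-1]) / 1000.0)))
    total = cum[-1]
    spikes: List[float] = []
    t = grid_ext[0]
    while True:
        ready = t + floor_ms
        if ready >= grid_ext[-1]:
            break
        s0 = np.interp(ready, grid_ext, cum)
        target = s0 + rng.exponential()
        if target >= total:
            break
        t = float(np.interp(target, cum, grid_ext))
        if t >= grid[0]:
            spikes.append(t)
    return np.asarray(spikes)


def _tonic_intensity(
    neuron: NeuronGroundTruth,
    trial: TrialSpec,
    config: TaskConfig,
    inhibitory: List[Tuple[float, float]],
) -> Tuple[np.ndarray, np.ndarray]:
    """(grid, lambda(t)) of the tonic/baseline stream, clamped at zero."""
    total_ms = config.trial_duration
    gain = {
        VALUE_INCREASE: neuron.tonic_gain_increase,
        VALUE_DECREASE: neuron.tonic_gain_decrease,
        VALUE_FIXED: 0.0,
    }[trial.condition]
    grid = np.arange(0.0, total_ms + 1.0)
    lam = np.full(grid.shape, neuron.baseline_rate, dtype=float)
    if gain != 0.0:
        cs_mask = (grid >= trial.cs_onset) & (grid < trial.cs_onset + config.cs_duration)
        t_rel = grid[cs_mask] - trial.cs_onset
        v = trial_value_trajectory(config, trial, t_rel)
        v0 = trial_value_trajectory(config, trial, 0.0)
        lam[cs_mask] += gain * (np.asarray(v) - v0)
    for onset, amp in inhibitory:
        lam += amp * _raised_cosine(grid, onset, neuron.phasic_latency, neuron.phasic_duration)
    np.maximum(lam, 0.0, out=lam)
    return grid, lam


def _sample_tonic_stream(
    neuron: NeuronGroundTruth,
    trial: TrialSpec,
    config: TaskConfig,
    rng: np.random.Generator,
    inhibitory: List[Tuple[float, float]],
) -> np.ndarray:
    """Tonic/baseline spikes according to the neuron's tonic mode."""
    total_ms = config.trial_duration
    gain = {
        VALUE_INCREASE: neuron.tonic_gain_increase,
        VALUE_DECREASE: neuron.tonic_gain_decrease,
        VALUE_FIXED: 0.0,
    }[trial.condition]
    if neuron.baseline_rate == 0.0 and gain == 0.0 and not inhibitory:
        return np.empty(0)
    homogeneous = gain == 0.0 and not inhibitory
    if neuron.tonic_mode == "non_burst_dominant":
        floor = neuron.tonic_refractory
        if homogeneous:
            lam0 = neuron.baseline_rate
            frac = min(lam0 * floor / 1000.0, 0.95)
            drive_scale = (1.0 - frac) * 1000.0 / lam0  # mean of the Exp part, ms
            burn = 1500.0
            mean_isi = floor + drive_scale
            spikes: List[float] = []
            t = -burn
            while True:
                n = max(16, int(1.5 * (total_ms - t) / mean_isi))
                arr = t + np.cumsum(floor + rng.exponential(drive_scale, size=n))
                if arr[-1] <= total_ms:
                    spikes.extend(arr[arr > 0])
                    t = arr[-1]
                    continue
                arr = arr[arr <= total_ms]
                spikes.extend(arr[arr > 0])
                break
            return np.asarray(spikes)
        grid, lam = _tonic_intensity(neuron, trial, config, inhibitory)
        return _dead_time_renewal(rng, grid, lam, floor)
    shape = _TONIC_SHAPE[neuron.tonic_mode]
    if homogeneous:
        expected = neuron.baseline_rate * total_ms / 1000.0
        s = _gamma_renewal_unit_rate(rng, shape, expected)
        return s / expected * total_ms
    grid, lam = _tonic_intensity(neuron, trial, config, inhibitory)
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (lam[1:] + lam[:-1]) / 1000.0)))
    total_mass = cum[-1]
    if total_mass <= 0:
        return np.empty(0)
    s = _gamma_renewal_unit_rate(rng, shape, total_mass)
    return np.interp(s, cum, grid)


def _sample_phasic_stream(
    neuron: NeuronGroundTruth,
    excitatory: List[Tuple[float, float]],
    total_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson thinning of the excitatory kernels (peak amplitude = bound)."""
    out: List[np.ndarray] = []
    for onset, amp in excitatory:
        lo = onset + neuron.phasic_latency
        hi = min(lo + neuron.phasic_duration, total_ms)
        if hi <= lo or amp <= 0:
            continue
        n_cand = rng.poisson(amp * (hi - lo) / 1000.0)
        if n_cand == 0:
            continue
        cand = rng.uniform(lo, hi, size=n_cand)
        accept = rng.random(n_cand) < _raised_cosine(cand, onset, neuron.phasic_latency, neuron.phasic_duration)
        out.append(cand[accept])
    return np.concatenate(out) if out else np.empty(0)


def simulate_trial_spikes(
    neuron: NeuronGroundTruth,
    trial: TrialSpec,
    config: TaskConfig,
    rng: np.random.Generator,
    return_tags: bool = False,
):
    """Spike times (ms, absolute within trial) for one neuron on one trial.

    With ``return_tags=True`` also returns per-spike provenance tags.
    """
    if trial.aborted:
        raise ValueError("cannot simulate spikes for an aborted trial")
    events = _phasic_events(neuron, trial, config)
    excitatory = [(o, a) for o, a in events if a > 0]
    inhibitory = [(o, a) for o, a in events if a < 0]

    tonic = _sample_tonic_stream(neuron, trial, config, rng, inhibitory)
    phasic = _sample_phasic_stream(neuron, excitatory, config.trial_duration, rng)

    cs_on = trial.cs_onset
    cs_off = trial.cs_onset + config.cs_duration
    has_tonic_gain = (
        trial.condition == VALUE_INCREASE and neuron.tonic_gain_increase != 0.0
    ) or (trial.condition == VALUE_DECREASE and neuron.tonic_gain_decrease != 0.0)
    tonic_tags = np.where(
        (tonic >= cs_on) & (tonic < cs_off) & has_tonic_gain, TAG_TONIC, TAG_BASELINE
    )

    # burst expansion of phasic spikes
    burst_extra: List[float] = []
    if neuron.burst_fraction > 0 and phasic.size:
        seeds = phasic[rng.random(phasic.size) < neuron.burst_fraction]
        for seed in seeds:
            n_members = 2 + rng.poisson(max(neuron.burst_length_mean - 2.0, 0.0))
            isis = rng.uniform(*neuron.intra_burst_isi, size=n_members - 1)
            burst_extra.extend(seed + np.cumsum(isis))
    burst_arr = np.array(burst_extra, dtype=float)
    burst_arr = burst_arr[burst_arr <= config.trial_duration]

    times = np.concatenate([tonic, phasic, burst_arr])
    tags = np.concatenate(
        [tonic_tags, np.full(phasic.size, TAG_PHASIC), np.full(burst_arr.size, TAG_BURST)]
    )
    order = np.argsort(times, kind="stable")
    times, tags = times[order], tags[order]

    # absolute dead time: drop any spike closer than DEAD_TIME_MS to the last kept
    if times.size:
        keep = np.ones(times.size, dtype=bool)
        last = times[0]
        for i in range(1, times.size):
            if times[i] - last < DEAD_TIME_MS:
                keep[i] = False
            else:
                last = times[i]
        times, tags = times[keep], tags[keep]

    if return_tags:
        return times, tags
    return times


# ---------------------------------------------------------------------------
# population / session assembly
# ---------------------------------------------------------------------------

CELL_CLASSES = ("tonic_increaser", "tonic_decreaser", "phasic_only", "null")


def make_neuron(
    cell_class: str,
    neuron_id: int,
    rng: np.random.Generator,
    **overrides,
) -> NeuronGroundTruth:
    """Draw ground-truth parameters for one neuron of a named class."""
    params = dict(
        neuron_id=neuron_id,
        baseline_rate=float(rng.uniform(3.0, 5.0)),
        cell_class=cell_class,
    )
    if cell_class == "tonic_increaser":
        a_stop = float(rng.uniform(1.0, 2.0))
        params.update(
            tonic_gain_increase=float(rng.uniform(10.0, 20.0)),
            cs_phasic_gain=float(rng.uniform(1.0, 3.0)),
            stop_phasic_gain=a_stop,
            stop_phasic_offset=(-4.0 * a_stop, 0.0),
            burst_fraction=0.7,
        )
    elif cell_class == "tonic_decreaser":
        a_stop = float(rng.uniform(1.0, 2.0))
        params.update(
            tonic_gain_decrease=float(rng.uniform(10.0, 20.0)),
            cs_phasic_gain=float(rng.uniform(1.0, 3.0)),
            stop_phasic_gain=a_stop,
            stop_phasic_offset=(-4.0 * a_stop, 0.0),
            burst_fraction=0.7,
        )
    elif cell_class == "phasic_only":
        a_stop = float(rng.uniform(1.0, 3.0))
        params.update(
            cs_phasic_gain=float(rng.uniform(1.0, 3.0)),
            stop_phasic_gain=a_stop,
            stop_phasic_offset=(-4.0 * a_stop, 0.0),
            burst_fraction=0.7,
        )
    elif cell_class != "null":
        raise ValueError(f"unknown cell class {cell_class!r}")
    params.update(overrides)
    return NeuronGroundTruth(**params)


def build_trials(
    config: TaskConfig,
    rng: np.random.Generator,
    n_blocks: int = 1,
    block_order: Optional[Sequence[str]] = None,
) -> List[TrialSpec]:
    order = tuple(block_order) if block_order is not None else config.block_order
    trials: List[TrialSpec] = []
    block_index = 0
    for _ in range(n_blocks):
        for condition in order:
            trials.extend(
                sample_block(config, condition, rng, start_trial_id=len(trials), block_index=block_index)
            )
            block_index += 1
    return trials


def trials_to_frame(trials: Sequence[TrialSpec], session_id: str = "session") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "session_id": session_id,
            "trial_id": [t.trial_id for t in trials],
            "block_index": [t.block_index for t in trials],
            "condition": [t.condition for t in trials],
            "cs_type": [t.cs_type for t in trials],
            "stop_time_ms": [t.stop_time if t.stop_time is not None else np.nan for t in trials],
            "reward_ml": [t.reward_ml for t in trials],
            "fixation_onset_ms": [t.fixation_onset for t in trials],
            "cs_onset_ms": [t.cs_onset for t in trials],
            "stop_onset_ms": [t.stop_onset if t.stop_onset is not None else np.nan for t in trials],
            "reward_onset_ms": [t.reward_onset for t in trials],
            "aborted": [int(t.aborted) for t in trials],
        }
    )


def simulate_population(
    config: TaskConfig,
    population: Dict[str, int],
    rng: np.random.Generator,
    n_blocks: int = 1,
    block_order: Optional[Sequence[str]] = None,
    session_id: str = "sim",
    neurons: Optional[Sequence[NeuronGroundTruth]] = None,
    with_gaze: bool = False,
    with_licks: bool = False,
    lick_rate_hz: float = 0.5,
    saccades_per_trial: float = 2.0,
) -> SessionData:
    """Simulate a full session: trials shared by all neurons, spikes per neuron.

    ``population`` maps cell-class names to neuron counts; pass ``neurons``
    to use explicit ground-truth parameter sets instead.
    """
    for cls, count in population.items():
        if count < 0:
            raise ValueError("population counts must be non-negative")
        if cls not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {cls!r}")
    trials = build_trials(config, rng, n_blocks=n_blocks, block_order=block_order)
    trial_frame = trials_to_frame(trials, session_id)

    if neurons is None:
        neurons = []
        nid = 0
        for cls in CELL_CLASSES:  # fixed order for determinism
            for _ in range(population.get(cls, 0)):
                neurons.append(make_neuron(cls, nid, rng))
                nid += 1
    neurons = list(neurons)

    spike_rows_nid: List[np.ndarray] = []
    spike_rows_tid: List[np.ndarray] = []
    spike_rows_t: List[np.ndarray] = []
    tag_rows: List[np.ndarray] = []
    for neuron in neurons:
        for trial in trials:
            if trial.aborted:
                continue
            t, tags = simulate_trial_spikes(neuron, trial, config, rng, return_tags=True)
            if t.size == 0:
                continue
            spike_rows_nid.append(np.full(t.size, neuron.neuron_id))
            spike_rows_tid.append(np.full(t.size, trial.trial_id))
            spike_rows_t.append(t)
            tag_rows.append(tags)
    if spike_rows_t:
        spikes = pd.DataFrame(
            {
                "session_id": session_id,
                "neuron_id": np.concatenate(spike_rows_nid).astype(int),
                "trial_id": np.concatenate(spike_rows_tid).astype(int),
                "spike_time_ms": np.concatenate(spike_rows_t),
            }
        )
        tags = pd.DataFrame(
            {
                "neuron_id": spikes["neuron_id"],
                "trial_id": spikes["trial_id"],
                "spike_time_ms": spikes["spike_time_ms"],
                "tag": np.concatenate(tag_rows),
            }
        )
    else:
        spikes = pd.DataFrame(
            columns=["session_id", "neuron_id", "trial_id", "spike_time_ms"]
        )
        tags = pd.DataFrame(columns=["neuron_id", "trial_id", "spike_time_ms", "tag"])

    gaze = None
    if with_gaze:
        parts = []
        for trial in trials:
            if trial.aborted:
                continue
            n_sac = rng.poisson(saccades_per_trial)
            sac = []
            for _ in range(n_sac):
                onset = float(rng.uniform(trial.cs_onset, trial.reward_onset - 100.0))
                amp = float(rng.uniform(1.5, 4.0)) * (1 if rng.random() < 0.5 else -1)
                sac.append((onset, amp, 40.0))
            parts.append(simulate_gaze(trial, config, rng, saccades=sac))
        gaze = pd.concat(parts, ignore_index=True) if parts else None

    licks = None
    if with_licks:
        parts = []
        for trial in trials:
            if trial.aborted:
                continue
            onsets = simulate_licks(trial, config, lick_rate_hz, rng)
            if onsets.size:
                parts.append(pd.DataFrame({"trial_id": trial.trial_id, "lick_onset_ms": onsets}))
        licks = (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame(columns=["trial_id", "lick_onset_ms"])
        )

    return SessionData(
        trials=trial_frame,
        spikes=spikes,
        gaze=gaze,
        licks=licks,
        ground_truth=neurons,
        spike_tags=tags,
        session_id=session_id,
    )


# ---------------------------------------------------------------------------
# gaze, licks, choice
# ---------------------------------------------------------------------------

def _minimum_jerk(u: np.ndarray) -> np.ndarray:
    return 10.0 * u**3 - 15.0 * u**4 + 6.0 * u**5


def simulate_gaze(
    trial: TrialSpec,
    config: TaskConfig,
    rng: np.random.Generator,
    saccades: Sequence[Tuple[float, float, float]] = (),
    rate_hz: float = 240.0,
    noise_sd: float = 0.2,
) -> pd.DataFrame:
    """Fixation-noise gaze trace with injected vertical saccades.

    ``saccades`` is a sequence of ``(onset_ms, amplitude_deg, duration_ms)``;
    each is a minimum-jerk vertical displacement.  Onsets outside the trial
    are rejected.
    """
    step = 1000.0 / rate_hz
    t = np.arange(0.0, config.trial_duration, step)
    x = rng.normal(0.0, noise_sd, size=t.size)
    y = rng.normal(0.0, noise_sd, size=t.size)
    for onset, amplitude, duration in saccades:
        if not (0.0 <= onset and onset + duration <= config.trial_duration):
            raise ValueError(f"saccade at {onset} ms falls outside the trial")
        u = np.clip((t - onset) / duration, 0.0, 1.0)
        y += amplitude * _minimum_jerk(u)
    return pd.DataFrame(
        {"trial_id": trial.trial_id, "sample_time_ms": t, "x_deg": x, "y_deg": y}
    )


def simulate_licks(
    trial: TrialSpec,
    config: TaskConfig,
    rate_hz: float,
    rng: np.random.Generator,
    window: Optional[Tuple[float, float]] = None,
) -> np.ndarray:
    """Homogeneous Poisson lick onsets (ms), independent of neural firing."""
    if rate_hz < 0:
        raise ValueError("lick rate must be non-negative")
    lo, hi = window if window is not None else (trial.cs_onset, trial.reward_onset)
    n = rng.poisson(rate_hz * (hi - lo) / 1000.0)
    return np.sort(rng.uniform(lo, hi, size=n))


def simulate_choice_sessions(
    config: TaskConfig,
    beta0: float,
    beta1: float,
    n_trials: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Two-bar choice trials with logistic choice on the value difference.

    Values per side ~ Uniform(value_min, value_max) ml; P(choose right) =
    expit(beta0 + beta1 * (v_right - v_left)), beta1 in 1/ml.
    """
    if not (np.isfinite(beta0) and np.isfinite(beta1)):
        raise ValueError("choice coefficients must be finite")
    v_right = rng.uniform(config.value_min, config.value_max, size=n_trials)
    v_left = rng.uniform(config.value_min, config.value_max, size=n_trials)
    from scipy.special import expit

    p_right = expit(beta0 + beta1 * (v_right - v_left))
    chose_right = rng.random(n_trials) < p_right
    return pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "v_right_ml": v_right,
            "v_left_ml": v_left,
            "chose_right": chose_right.astype(int),
        }
    )
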