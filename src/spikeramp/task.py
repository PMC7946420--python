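"""Executable model of the value-ramp Pavlovian task and the two-bar choice task.

The task presents a conditioned stimulus (CS) whose cued liquid-reward value
either ramps up, ramps down, or stays fixed.  In the ramp conditions the value
changes at a constant rate (ml/s) until a random stop time drawn uniformly
from a configured window; the value at the stop time is the reward delivered
at the end of the CS period.  All times in this package are milliseconds;
within a trial, time zero is the trial start and events are stored as absolute
trial times.  Times relative to an event (CS onset, stop onset, ...) are
produced by the alignment operations in :mod:`spikeramp.processing`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "VALUE_INCREASE",
    "VALUE_DECREASE",
    "VALUE_FIXED",
    "CONDITIONS",
    "RAMP_CONDITIONS",
    "CS_RAMP",
    "CS_FIXED_SMALL",
    "CS_FIXED_MEDIUM",
    "CS_FIXED_LARGE",
    "CS_UNCERTAIN",
    "FIXED_CS_TYPES",
    "CS_VALUE_LEVELS",
    "TaskConfig",
    "TrialSpec",
    "value_at_time",
    "sample_trial",
    "sample_block",
    "expected_trial_reward",
    "expected_block_reward",
]

VALUE_INCREASE = "value_increase"
VALUE_DECREASE = "value_decrease"
VALUE_FIXED = "value_fixed"
CONDITIONS = (VALUE_FIXED, VALUE_INCREASE, VALUE_DECREASE)
RAMP_CONDITIONS = (VALUE_INCREASE, VALUE_DECREASE)

CS_RAMP = "ramp"
CS_FIXED_SMALL = "fixed_small"
CS_FIXED_MEDIUM = "fixed_medium"
CS_FIXED_LARGE = "fixed_large"
CS_UNCERTAIN = "uncertain"
FIXED_CS_TYPES = (CS_FIXED_SMALL, CS_FIXED_MEDIUM, CS_FIXED_LARGE, CS_UNCERTAIN)

#: cued value expressed in 0.1-ml levels for the value-fixed CSs (the
#: uncertain CS has no certain level; its expectation sits at level 2).
CS_VALUE_LEVELS = {CS_FIXED_SMALL: 1.0, CS_FIXED_MEDIUM: 2.0, CS_FIXED_LARGE: 3.0}


@dataclass
class TaskConfig:
    """All task constants in one validated place.

    Durations are milliseconds, reward amounts millilitres, and the ramp rate
    ml/s.  ``pre_fixation_duration`` is the recorded stretch before the
    fixation point comes on; it exists so the pre-fixation baseline window is
    covered by every trial's spike record.
    """

    ramp_rate: float = 0.082
    value_min: float = 0.1
    value_max: float = 0.3
    fixed_levels: Tuple[float, ...] = (0.1, 0.2, 0.3)
    stop_window: Tuple[float, float] = (0.0, 2450.0)
    cs_duration: float = 2850.0
    fixation_duration: float = 400.0
    pre_fixation_duration: float = 500.0
    post_reward_duration: float = 500.0
    block_size: int = 50
    cs_probabilities: Tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    uncertain_reward_interval: Tuple[float, float] = (0.1, 0.3)
    block_order: Tuple[str, ...] = (VALUE_FIXED, VALUE_INCREASE, VALUE_DECREASE)
    quantize_stop_ms: bool = False
    abort_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.value_min >= self.value_max:
            raise ValueError("value_min must be strictly below value_max")
        for name in ("cs_duration", "fixation_duration", "ramp_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.pre_fixation_duration < 0 or self.post_reward_duration < 0:
            raise ValueError("padding durations must be non-negative")
        lo, hi = self.stop_window
        if not (0.0 <= lo <= hi <= self.cs_duration):
            raise ValueError("stop_window must lie within [0, cs_duration]")
        if abs(sum(self.cs_probabilities) - 1.0) > 1e-9:
            raise ValueError("cs_probabilities must sum to 1")
        if len(self.cs_probabilities) != len(FIXED_CS_TYPES):
            raise ValueError("one probability per value-fixed CS type required")
        if not 0.0 <= self.abort_rate < 1.0:
            raise ValueError("abort_rate must be in [0, 1)")
        for cond in self.block_order:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition in block_order: {cond!r}")
        # the ramp must be able to traverse the full value range: value_min +
        # ramp_rate * stop_max should land on value_max within 1 %.
        span = self.value_min + self.ramp_rate * self.stop_window[1] / 1000.0
        if abs(span - self.value_max) > 0.01 * self.value_max:
            raise ValueError(
                "ramp rate, stop window and value range are inconsistent: "
                f"full ramp reaches {span:.4f} ml, expected {self.value_max} ml"
            )

    # -- derived event times (absolute, trial start = 0) --
    @property
    def fixation_onset(self) -> float:
        return self.pre_fixation_duration

    @property
    def cs_onset(self) -> float:
        return self.pre_fixation_duration + self.fixation_duration

    @property
    def reward_onset(self) -> float:
        return self.cs_onset + self.cs_duration

    @property
    def trial_duration(self) -> float:
        return self.reward_onset + self.post_reward_duration

    @property
    def required_fixation(self) -> float:
        """Continuous central fixation required per successful trial (ms)."""
        return self.fixation_duration + self.cs_duration

    def with_(self, **changes) -> "TaskConfig":
        return replace(self, **changes)


@dataclass
class TrialSpec:
    """One trial of the Pavlovian procedure.

    ``stop_time`` is relative to CS onset (present only in ramp conditions);
    the ``*_onset`` fields are absolute trial times in ms.
    """

    trial_id: int
    block_index: int
    condition: str
    cs_type: str
    reward_ml: float
    fixation_onset: float
    cs_onset: float
    reward_onset: float
    stop_time: Optional[float] = None
    stop_onset: Optional[float] = None
    aborted: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        has_stop = self.stop_time is not None
        if has_stop != (self.condition in RAMP_CONDITIONS):
            raise ValueError("stop_time present iff condition is a ramp condition")
        if has_stop and self.stop_onset is None:
            raise ValueError("stop_onset required when stop_time is set")


def value_at_time(config: TaskConfig, condition: str, stop_time, t):
    """Cued reward value (ml) at time ``t`` (ms after CS onset) in a ramp trial.

    The value moves from ``value_min`` (value-increase) or ``value_max``
    (value-decrease) at ``ramp_rate`` ml/s until ``min(t, stop_time)`` and is
    constant thereafter, clamped to ``[value_min, value_max]``.  Accepts
    scalars or numpy arrays for ``t``.
    """
    if condition not in RAMP_CONDITIONS:
        raise ValueError(
            f"value_at_time applies to ramp conditions, got {condition!r}"
        )
    lo, hi = config.stop_window
    if not (lo <= stop_time <= hi):
        raise ValueError(f"stop_time {stop_time} outside stop window [{lo}, {hi}]")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative (ms after CS onset)")
    if np.any(t_arr > config.cs_duration):
        raise ValueError("t exceeds the CS duration")
    elapsed_s = np.minimum(t_arr, stop_time) / 1000.0
    if condition == VALUE_INCREASE:
        v = config.value_min + config.ramp_rate * elapsed_s
    else:
        v = config.value_max - config.ramp_rate * elapsed_s
    v = np.clip(v, config.value_min, config.value_max)
    return float(v) if np.isscalar(t) or t_arr.ndim == 0 else v


def trial_value_trajectory(config: TaskConfig, trial: TrialSpec, t):
    """Cued value at ``t`` ms after CS onset for any (non-aborted) trial."""
    if trial.condition in RAMP_CONDITIONS:
        return value_at_time(config, trial.condition, trial.stop_time, t)
    out = np.full_like(np.asarray(t, dtype=float), trial.reward_ml)
    return float(out) if out.ndim == 0 else out


def sample_trial(
    config: TaskConfig,
    condition: str,
    rng: np.random.Generator,
    trial_id: int = 0,
    block_index: int = 0,
) -> TrialSpec:
    """Draw one trial: stop time ~ Uniform(stop_window) for ramp conditions,
    CS type ~ the configured probabilities for the value-fixed condition."""
    if rng is None:
        raise ValueError("an explicit seeded rng is required for sampling")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    aborted = bool(config.abort_rate > 0 and rng.random() < config.abort_rate)
    stop_time = stop_onset = None
    if condition in RAMP_CONDITIONS:
        stop_time = float(rng.uniform(*config.stop_window))
        if config.quantize_stop_ms:
            stop_time = float(round(stop_time))
        stop_onset = config.cs_onset + stop_time
        cs_type = CS_RAMP
        reward = value_at_time(config, condition, stop_time, stop_time)
    else:
        cs_type = FIXED_CS_TYPES[
            int(rng.choice(len(FIXED_CS_TYPES), p=config.cs_probabilities))
        ]
        if cs_type == CS_UNCERTAIN:
            reward = float(rng.uniform(*config.uncertain_reward_interval))
        else:
            reward = config.fixed_levels[FIXED_CS_TYPES.index(cs_type)]
    return TrialSpec(
        trial_id=trial_id,
        block_index=block_index,
        condition=condition,
        cs_type=cs_type,
        reward_ml=float(reward),
        fixation_onset=config.fixation_onset,
        cs_onset=config.cs_onset,
        reward_onset=config.reward_onset,
        stop_time=stop_time,
        stop_onset=stop_onset,
        aborted=aborted,
    )


def sample_block(
    config: TaskConfig,
    condition: str,
    rng: np.random.Generator,
    start_trial_id: int = 0,
    block_index: int = 0,
) -> list[TrialSpec]:
    return [
        sample_trial(config, condition, rng, start_trial_id + i, block_index)
        for i in range(config.block_size)
    ]


def expected_trial_reward(config: TaskConfig, condition: str) -> float:
    """Analytic per-trial reward expectation (ml) under ``condition``."""
    if condition == VALUE_FIXED:
        levels = list(config.fixed_levels) + [
            0.5 * sum(config.uncertain_reward_interval)
        ]
        probs = config.cs_probabilities
        return float(sum(p * v for p, v in zip(probs, levels)))
    if condition not in RAMP_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    lo, hi = config.stop_window
    width = hi - lo
    if width == 0:
        return value_at_time(config, condition, lo, lo)
    rate = config.ramp_rate / 1000.0  # ml per ms
    vspan = config.value_max - config.value_min
    t_sat = vspan / rate  # time at which the ramp saturates (clamp kicks in)
    a, b = lo, min(hi, t_sat)
    if condition == VALUE_INCREASE:
        # linear part: value_min + rate*t on [a, b]; constant value_max after
        lin = (config.value_min * (b - a) + rate * (b * b - a * a) / 2.0)
        sat = max(hi - t_sat, 0.0) * config.value_max
    else:
        lin = (config.value_max * (b - a) - rate * (b * b - a * a) / 2.0)
        sat = max(hi - t_sat, 0.0) * config.value_min
    return float((lin + sat) / width)


def expected_block_reward(config: TaskConfig, condition: str) -> float:
    """Analytic expected total reward (ml) over one block of trials."""
    if config.block_size == 0:
        return 0.0
    return config.block_size * expected_trial_reward(config, condition)
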