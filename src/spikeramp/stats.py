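"""Estimators and tests for the value-ramp analysis.

Tonic slope regression (binned rate vs time), cue- and stop-aligned value
regressions, slope comparison, gaze-rate correlations, the neuron-resampling
bootstrap for burst vs non-burst firing, the logistic choice fit, and
per-neuron classification.  Standard tests (Wilcoxon, Kruskal-Wallis,
Pearson, OLS/logistic p-values) are delegated to scipy/statsmodels; this
module owns the data marshaling and invocation contracts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats as sps

from . import bursts as bursts_mod
from . import processing as proc
from .processing import AlignedSpikes, AnalysisWindows
from .task import (
    CS_UNCERTAIN,
    CS_VALUE_LEVELS,
    RAMP_CONDITIONS,
    VALUE_DECREASE,
    VALUE_FIXED,
    VALUE_INCREASE,
)

__all__ = [
    "TimeSlopeResult",
    "ValueRegressionResult",
    "BootstrapConfig",
    "BootstrapResult",
    "ChoiceModel",
    "NeuronSummary",
    "InsufficientDataError",
    "SeparationError",
    "fit_time_slope",
    "fit_value_regression_cue",
    "fit_value_regression_stop",
    "compare_two_slopes",
    "gaze_rate_correlation",
    "bootstrap_mode_comparison",
    "fit_choice_logistic",
    "classify_neuron",
    "analyze_population",
    "population_correlations",
]

log = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Raised when a fit has too few usable points."""


class SeparationError(ValueError):
    """Raised on complete separation in the logistic choice fit."""


# ---------------------------------------------------------------------------
# ordinary least squares core (shared by the slope and value regressions)
# ---------------------------------------------------------------------------

def _ols(
    x: np.ndarray, y: np.ndarray, weights: Optional[np.ndarray] = None
) -> Tuple[float, float, float, float]:
    """Least squares of y on x: (slope, intercept, slope_se, two-sided p).

    With ``weights`` this is weighted least squares (weights proportional to
    inverse variances); without, plain OLS.  Degenerate cases: zero residual
    variance gives p = 0 for a non-zero slope and p = 1 for a zero slope (an
    exactly constant response).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 points for a regression, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    xm = float(np.sum(w * x) / w.sum())
    ym = float(np.sum(w * y) / w.sum())
    sxx = float(np.sum(w * (x - xm) ** 2))
    if sxx == 0:
        raise ValueError("regressor has zero variance")
    slope = float(np.sum(w * (x - xm) * (y - ym)) / sxx)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    rss = float(np.sum(w * resid**2))
    dof = n - 2
    if rss <= 1e-300:
        return slope, intercept, 0.0, (1.0 if slope == 0.0 else 0.0)
    se = float(np.sqrt(rss / dof / sxx))
    tstat = slope / se
    p = float(2.0 * sps.t.sf(abs(tstat), dof))
    return slope, intercept, se, p


@dataclass
class TimeSlopeResult:
    slope: float  # spikes/s per s
    intercept: float
    slope_se: float
    p_value: float
    n_bins: int
    condition: str = ""


@dataclass
class ValueRegressionResult:
    coefficient: float  # spikes/s per value unit
    se: float
    p_value: float
    value_coding: str  # "level_0p1ml" or "ml"
    alignment: str  # "cue" or "stop"
    n: int
    condition: str = ""


def fit_time_slope(
    bin_rates: np.ndarray,
    bin_centers_ms: np.ndarray,
    weights: Optional[np.ndarray] = None,
    condition: str = "",
) -> TimeSlopeResult:
    """Regression of mean bin rate on bin-center time (in seconds).

    NaN bins (missing coverage) are dropped; fewer than three usable bins
    raises :class:`InsufficientDataError`.  Under stop truncation the bin
    means have unequal sampling variance (late bins are covered by few
    trials); passing ``weights`` equal to the per-bin covering-trial counts
    restores the nominal test size, and is what the pipeline does by
    default.  ``weights=None`` gives plain OLS.
    """
    rates = np.asarray(bin_rates, dtype=float)
    centers = np.asarray(bin_centers_ms, dtype=float)
    ok = ~np.isnan(rates)
    if ok.sum() < 3:
        raise InsufficientDataError(f"only {int(ok.sum())} usable bins (need >= 3)")
    w = None if weights is None else np.asarray(weights, dtype=float)[ok]
    slope, intercept, se, p = _ols(centers[ok] / 1000.0, rates[ok], w)
    return TimeSlopeResult(slope, intercept, se, p, int(ok.sum()), condition)


def fit_value_regression_cue(
    session,
    neuron_id,
    windows: AnalysisWindows,
    coding: str = "level_0p1ml",
    spikes: Optional[pd.DataFrame] = None,
) -> ValueRegressionResult:
    """Trial-level regression of the cue-window rate on the cued value.

    Uses value-fixed trials with a certain cued value (the uncertain CS is
    excluded).  Default value coding is 0.1-ml levels (1/2/3); pass
    ``coding='ml'`` for millilitres.
    """
    certain = [cs for cs in CS_VALUE_LEVELS]
    aligned = proc.align_spikes(
        session, neuron_id, "cs_onset", conditions=[VALUE_FIXED], cs_types=certain, spikes=spikes
    )
    present = set(aligned.trials["cs_type"])
    missing = [cs for cs in certain if cs not in present]
    if missing:
        raise InsufficientDataError(f"value level(s) absent in value-fixed trials: {missing}")
    rates = proc.window_rate_per_trial(aligned, windows.cue_response)
    levels = aligned.trials["cs_type"].map(CS_VALUE_LEVELS).to_numpy(dtype=float)
    x = levels if coding == "level_0p1ml" else levels * 0.1
    coef, _, se, p = _ols(x, rates)
    return ValueRegressionResult(coef, se, p, coding, "cue", int(rates.size), VALUE_FIXED)


def fit_value_regression_stop(
    session,
    neuron_id,
    windows: AnalysisWindows,
    condition: str,
    coding: str = "level_0p1ml",
    spikes: Optional[pd.DataFrame] = None,
) -> ValueRegressionResult:
    """Stop-aligned value regression for one ramp condition.

    Trials are grouped into small/medium/large reward-value groups; each
    group's mean stop-window rate is regressed on the group's mean reward
    value.  An empty group raises an error reporting group occupancies.
    """
    if condition not in RAMP_CONDITIONS:
        raise ValueError("stop-aligned regression applies to ramp conditions")
    aligned = proc.align_spikes(session, neuron_id, "stop_onset", conditions=[condition], spikes=spikes)
    if aligned.n_trials == 0:
        raise InsufficientDataError(f"no {condition} trials with a stop event")
    rates = proc.window_rate_per_trial(aligned, windows.stop_response)
    rewards = aligned.trials["reward_ml"].to_numpy(dtype=float)
    groups = windows.value_group_of(rewards)
    occupancy = [int(np.sum(groups == g)) for g in range(len(windows.value_groups))]
    if any(o == 0 for o in occupancy):
        raise InsufficientDataError(
            f"empty value group(s); occupancies small/medium/large = {occupancy}"
        )
    mean_rate = np.array([rates[groups == g].mean() for g in range(len(occupancy))])
    mean_value = np.array([rewards[groups == g].mean() for g in range(len(occupancy))])
    x = mean_value / 0.1 if coding == "level_0p1ml" else mean_value
    coef, _, se, p = _ols(x, mean_rate)
    return ValueRegressionResult(coef, se, p, coding, "stop", len(occupancy), condition)


def compare_two_slopes(fit_a: TimeSlopeResult, fit_b: TimeSlopeResult) -> Tuple[float, float]:
    """z-test for the difference of two independent regression slopes."""
    pooled = np.hypot(fit_a.slope_se, fit_b.slope_se)
    if pooled == 0:
        raise ValueError("both slope standard errors are zero")
    z = (fit_a.slope - fit_b.slope) / pooled
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), p


def gaze_rate_correlation(
    session,
    neuron_id,
    windows: AnalysisWindows,
    condition: str,
) -> pd.DataFrame:
    """Per-bin Pearson correlation between firing rate and vertical gaze.

    For each tonic-fit bin, across trials whose stop time covers the whole
    bin, correlates the bin firing rate with the mean vertical gaze position.
    Bins with fewer than three trials or degenerate variance are NaN.
    """
    if session.gaze is None:
        raise ValueError("session has no gaze table")
    aligned = proc.truncate_at_stop(
        proc.align_spikes(session, neuron_id, "cs_onset", conditions=[condition])
    )
    edges = windows.tonic_bin_edges
    gaze = session.gaze
    rows = []
    for k in range(windows.n_tonic_bins):
        lo, hi = edges[k], edges[k + 1]
        rates, gazes = [], []
        for tid, t in aligned.times.items():
            horizon = aligned.horizons.get(tid, np.inf) if aligned.horizons else np.inf
            if horizon < hi:
                continue
            cs_on = float(aligned.trials.at[tid, "cs_onset_ms"])
            g = gaze[gaze["trial_id"] == tid]
            g_rel = g["sample_time_ms"].to_numpy() - cs_on
            in_bin = (g_rel >= lo) & (g_rel < hi)
            if not np.any(in_bin):
                continue
            rates.append(np.count_nonzero((t >= lo) & (t < hi)) / (hi - lo) * 1000.0)
            gazes.append(float(g["y_deg"].to_numpy()[in_bin].mean()))
        r = p = np.nan
        if len(rates) >= 3 and np.std(rates) > 0 and np.std(gazes) > 0:
            r, p = sps.pearsonr(rates, gazes)
        rows.append(
            {"bin_center_ms": 0.5 * (lo + hi), "r": r, "p_value": p, "n_trials": len(rates)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# burst vs non-burst bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapConfig:
    n_repetitions: int = 1000
    significance_count: int = 975

    def __post_init__(self) -> None:
        if not (0 < self.significance_count <= self.n_repetitions):
            raise ValueError("significance_count must be in (0, n_repetitions]")


@dataclass
class BootstrapResult:
    period_index: int
    count_non_burst_greater: int
    count_burst_greater: int
    count_tie: int
    significant: bool
    direction: Optional[str]  # "non_burst" | "burst" | None


def bootstrap_mode_comparison(
    non_burst_rates: np.ndarray,
    burst_rates: np.ndarray,
    config: BootstrapConfig,
    rng: np.random.Generator,
) -> List[BootstrapResult]:
    """Neuron-resampling bootstrap comparing firing modes per period.

    Inputs are (n_neurons, n_periods) arrays of baseline-subtracted rates.
    For each of ``n_repetitions`` resamples (neurons drawn with replacement,
    same n), the population means of the two modes are compared per period;
    a direction is significant when it wins in more than
    ``significance_count`` repetitions.  Exact ties count for neither side.
    Neurons with missing (NaN) values in any period are excluded.
    """
    nb = np.asarray(non_burst_rates, dtype=float)
    b = np.asarray(burst_rates, dtype=float)
    if nb.shape != b.shape or nb.ndim != 2:
        raise ValueError("mode rate arrays must share the shape (n_neurons, n_periods)")
    ok = ~(np.isnan(nb).any(axis=1) | np.isnan(b).any(axis=1))
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.warning("bootstrap: excluded %d neurons with missing mode data", n_excluded)
    nb, b = nb[ok], b[ok]
    n = nb.shape[0]
    if n == 0:
        raise ValueError("no neurons with complete mode data")
    idx = rng.integers(0, n, size=(config.n_repetitions, n))
    results = []
    for p in range(nb.shape[1]):
        diff = nb[idx, p].mean(axis=1) - b[idx, p].mean(axis=1)
        pos = int(np.sum(diff > 0))
        neg = int(np.sum(diff < 0))
        tie = config.n_repetitions - pos - neg
        if pos > config.significance_count:
            sig, direction = True, "non_burst"
        elif neg > config.significance_count:
            sig, direction = True, "burst"
        else:
            sig, direction = False, None
        results.append(BootstrapResult(p, pos, neg, tie, sig, direction))
    return results


def mode_period_rates(
    session,
    neuron_id,
    windows: AnalysisWindows,
    criteria: Optional[bursts_mod.BurstCriteria] = None,
    condition: str = VALUE_INCREASE,
    baseline: str = "per_mode",
) -> Tuple[np.ndarray, np.ndarray]:
    """Baseline-subtracted period rates for (non-burst, burst) spikes.

    Spikes are burst-labeled per trial on the full train, split by mode, and
    each mode's CS-aligned stop-truncated rate is pooled per period (partial
    coverage).  The baseline is the same mode's pre-fixation rate
    (``baseline='per_mode'``, default) or the overall pre-fixation rate
    (``baseline='overall'``).
    """
    criteria = criteria or bursts_mod.BurstCriteria()
    spk = session.spikes[session.spikes["neuron_id"] == neuron_id]
    burst_tbl, non_burst_tbl = bursts_mod.split_by_mode(spk, criteria)
    out = []
    for tbl in (non_burst_tbl, burst_tbl):
        if baseline == "per_mode":
            try:
                base = proc.baseline_rate(session, neuron_id, windows, conditions=[condition], spikes=tbl)
            except ValueError:
                base = 0.0
        elif baseline == "overall":
            base = proc.baseline_rate(session, neuron_id, windows, conditions=[condition])
        else:
            raise ValueError("baseline must be 'per_mode' or 'overall'")
        aligned = proc.truncate_at_stop(
            proc.align_spikes(session, neuron_id, "cs_onset", conditions=[condition], spikes=tbl)
        )
        out.append(proc.period_rates(aligned, windows, baseline=base))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# logistic choice model
# ---------------------------------------------------------------------------

@dataclass
class ChoiceModel:
    beta0: float
    beta1: float  # per ml of value difference
    se0: float
    se1: float
    n_trials: int


def fit_choice_logistic(choices: pd.DataFrame, penalized: bool = False, ridge: float = 1.0) -> ChoiceModel:
    """Maximum-likelihood logistic fit of choice on the value difference.

    Requires both outcomes to occur.  Complete separation raises
    :class:`SeparationError`; ``penalized=True`` falls back to a ridge
    (L2) penalized fit whose standard errors come from the penalized
    Hessian and are approximate.
    """
    y = choices["chose_right"].to_numpy(dtype=float)
    vdiff = (choices["v_right_ml"] - choices["v_left_ml"]).to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError("choices are all one outcome; logistic fit is undefined")

    def negll(beta, alpha=0.0):
        eta = beta[0] + beta[1] * vdiff
        # log(1 + exp) computed stably
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return -ll + 0.5 * alpha * (beta[0] ** 2 + beta[1] ** 2)

    from scipy.optimize import minimize

    alpha = ridge if penalized else 0.0
    res = minimize(negll, x0=np.zeros(2), args=(alpha,), method="BFGS")
    beta = res.x
    from scipy.special import expit

    mu = expit(beta[0] + beta[1] * vdiff)
    w = mu * (1.0 - mu)
    X = np.column_stack([np.ones_like(vdiff), vdiff])
    hess = X.T @ (X * w[:, None]) + alpha * np.eye(2)
    if not penalized:
        # separation heuristic: diverging coefficients / vanishing curvature
        if np.abs(beta).max() > 1e3 or np.linalg.cond(hess) > 1e12:
            raise SeparationError(
                "complete (or quasi-complete) separation detected; "
                "refit with penalized=True for a ridge-stabilised estimate"
            )
    cov = np.linalg.inv(hess)
    return ChoiceModel(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        se0=float(np.sqrt(cov[0, 0])),
        se1=float(np.sqrt(cov[1, 1])),
        n_trials=int(y.size),
    )


# ---------------------------------------------------------------------------
# per-neuron classification and population summaries
# ---------------------------------------------------------------------------

@dataclass
class NeuronSummary:
    neuron_id: int
    baseline_rates: Dict[str, float] = field(default_factory=dict)
    slope_increase: Optional[TimeSlopeResult] = None
    slope_decrease: Optional[TimeSlopeResult] = None
    slope_uncertain: Optional[TimeSlopeResult] = None
    cue_regression: Optional[ValueRegressionResult] = None
    stop_regression_increase: Optional[ValueRegressionResult] = None
    stop_regression_decrease: Optional[ValueRegressionResult] = None
    tonic_increaser: bool = False
    tonic_decreaser: bool = False
    cue_value_coder: bool = False
    stop_value_coder_increase: bool = False
    stop_value_coder_decrease: bool = False

    def to_row(self) -> dict:
        row = {"neuron_id": self.neuron_id}
        for cond, rate in self.baseline_rates.items():
            row[f"baseline_{cond}"] = rate
        for name in ("slope_increase", "slope_decrease", "slope_uncertain"):
            fit = getattr(self, name)
            row[f"{name}"] = fit.slope if fit else np.nan
            row[f"{name}_se"] = fit.slope_se if fit else np.nan
            row[f"{name}_p"] = fit.p_value if fit else np.nan
        for name in ("cue_regression", "stop_regression_increase", "stop_regression_decrease"):
            fit = getattr(self, name)
            key = name.replace("regression", "coef")
            row[key] = fit.coefficient if fit else np.nan
            row[f"{key}_se"] = fit.se if fit else np.nan
            row[f"{key}_p"] = fit.p_value if fit else np.nan
        for flag in (
            "tonic_increaser",
            "tonic_decreaser",
            "cue_value_coder",
            "stop_value_coder_increase",
            "stop_value_coder_decrease",
        ):
            row[flag] = int(getattr(self, flag))
        return row


def _tonic_fit_for(
    session, neuron_id, windows, condition, coverage="whole"
) -> Optional[TimeSlopeResult]:
    aligned = proc.align_spikes(session, neuron_id, "cs_onset", conditions=[condition])
    if condition in RAMP_CONDITIONS:
        aligned = proc.truncate_at_stop(aligned)
    try:
        binned = proc.bin_rates(aligned, windows, coverage=coverage)
        weights = binned.n_trials if coverage == "whole" else binned.exposure_s
        return fit_time_slope(binned.rates, binned.centers_ms, weights=weights, condition=condition)
    except (ValueError, InsufficientDataError) as exc:
        log.info("tonic fit unusable for neuron %s / %s: %s", neuron_id, condition, exc)
        return None


def classify_neuron(
    session,
    neuron_id,
    windows: AnalysisWindows,
    alpha: float = 0.05,
) -> NeuronSummary:
    """Run every per-neuron fit and derive classification flags.

    Flags follow raw-p significance at ``alpha``: a tonic increaser has a
    significantly positive time slope in the value-increase condition, a
    tonic decreaser a significantly negative slope in the value-decrease
    condition; coder flags mirror coefficient significance.  Missing or
    unusable fits yield null flags.
    """
    summary = NeuronSummary(neuron_id=neuron_id)
    for cond in (VALUE_FIXED, VALUE_INCREASE, VALUE_DECREASE):
        try:
            summary.baseline_rates[cond] = proc.baseline_rate(
                session, neuron_id, windows, conditions=[cond]
            )
        except ValueError:
            summary.baseline_rates[cond] = np.nan

    summary.slope_increase = _tonic_fit_for(session, neuron_id, windows, VALUE_INCREASE)
    summary.slope_decrease = _tonic_fit_for(session, neuron_id, windows, VALUE_DECREASE)
    # uncertain-CS trials of the value-fixed condition: full coverage
    aligned_unc = proc.align_spikes(
        session, neuron_id, "cs_onset", conditions=[VALUE_FIXED], cs_types=[CS_UNCERTAIN]
    )
    if aligned_unc.n_trials:
        try:
            binned = proc.bin_rates(aligned_unc, windows)
            summary.slope_uncertain = fit_time_slope(
                binned.rates, binned.centers_ms, weights=binned.n_trials, condition="uncertain"
            )
        except (ValueError, InsufficientDataError):
            pass
    try:
        summary.cue_regression = fit_value_regression_cue(session, neuron_id, windows)
    except InsufficientDataError as exc:
        log.info("cue regression unusable for neuron %s: %s", neuron_id, exc)
    for cond, attr in (
        (VALUE_INCREASE, "stop_regression_increase"),
        (VALUE_DECREASE, "stop_regression_decrease"),
    ):
        try:
            setattr(summary, attr, fit_value_regression_stop(session, neuron_id, windows, cond))
        except InsufficientDataError as exc:
            log.info("stop regression unusable for neuron %s / %s: %s", neuron_id, cond, exc)

    si, sd = summary.slope_increase, summary.slope_decrease
    summary.tonic_increaser = bool(si and si.slope > 0 and si.p_value < alpha)
    summary.tonic_decreaser = bool(sd and sd.slope < 0 and sd.p_value < alpha)
    cue = summary.cue_regression
    summary.cue_value_coder = bool(cue and cue.p_value < alpha)
    for attr, flag in (
        ("stop_regression_increase", "stop_value_coder_increase"),
        ("stop_regression_decrease", "stop_value_coder_decrease"),
    ):
        fit = getattr(summary, attr)
        setattr(summary, flag, bool(fit and fit.p_value < alpha))
    return summary


def analyze_population(
    session,
    windows: AnalysisWindows,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify every neuron of a session; one row per neuron."""
    rows = [
        classify_neuron(session, nid, windows, alpha).to_row()
        for nid in session.neuron_ids
    ]
    return pd.DataFrame(rows)


_CORRELATION_PAIRS = (
    ("slope_increase", "cue_coef"),
    ("slope_decrease", "cue_coef"),
    ("slope_decrease", "stop_coef_increase"),
    ("slope_increase", "stop_coef_decrease"),
    ("stop_coef_increase", "cue_coef"),
    ("stop_coef_decrease", "cue_coef"),
)


def population_correlations(summary: pd.DataFrame) -> pd.DataFrame:
    """Cross-neuron Pearson correlations between tonic and phasic estimates."""
    rows = []
    for a, b in _CORRELATION_PAIRS:
        sub = summary[[a, b]].dropna()
        if len(sub) >= 3:
            r, p = sps.pearsonr(sub[a], sub[b])
        else:
            r = p = np.nan
        rows.append({"x": b, "y": a, "r": r, "p_value": p, "n": len(sub)})
    return pd.DataFrame(rows)
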