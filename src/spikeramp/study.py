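"""Study orchestration: generate -> analyze -> report, reproducibly.

A :class:`StudyConfig` bundles the task constants, analysis windows, burst
criteria, bootstrap settings, population spec and the master seed.  Stage
seeds are derived from the master seed and the stage name so stages can be
re-run in isolation.  All artifacts are CSV/JSON/markdown; figures are
regenerable outputs, never inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import scipy.stats as sps
import yaml

from . import io as io_mod
from .bursts import BurstCriteria
from .processing import AnalysisWindows, align_spikes, baseline_rate, compute_sdf, truncate_at_stop
from .stats import BootstrapConfig, analyze_population, bootstrap_mode_comparison, mode_period_rates, population_correlations
from .synth import SessionData, simulate_population
from .task import VALUE_DECREASE, VALUE_FIXED, VALUE_INCREASE, TaskConfig

log = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "derive_rng", "run_study"]

DEFAULT_POPULATION = {
    "tonic_increaser": 19,
    "tonic_decreaser": 15,
    "phasic_only": 30,
    "null": 35,
}


def derive_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Stage-specific generator: stable hash of (master seed, stage name)."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    )


@dataclass
class StudyConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    windows: AnalysisWindows = field(default_factory=AnalysisWindows)
    burst: BurstCriteria = field(default_factory=BurstCriteria)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    population: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_POPULATION))
    n_blocks: int = 1
    seed: int = 0
    alpha: float = 0.05
    with_gaze: bool = False
    with_licks: bool = False
    lick_rate_hz: float = 0.5
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)

        def _tuplify(obj):
            if isinstance(obj, list):
                return tuple(_tuplify(v) for v in obj)
            if isinstance(obj, dict):
                return {k: _tuplify(v) for k, v in obj.items()}
            return obj

        kwargs = {}
        for fld in dataclasses.fields(cls):
            if fld.name not in d:
                continue
            val = _tuplify(d[fld.name])
            if fld.name == "task":
                val = TaskConfig(**val)
            elif fld.name == "windows":
                val = AnalysisWindows(**val)
            elif fld.name == "burst":
                val = BurstCriteria(**val)
            elif fld.name == "bootstrap":
                val = BootstrapConfig(**val)
            elif fld.name == "population":
                val = dict(val)
            kwargs[fld.name] = val
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class StudyReport:
    counts: Dict[str, int]
    population_tests: Dict[str, float]
    correlations: pd.DataFrame
    bootstrap: Optional[pd.DataFrame]
    summary_path: Path
    report_path: Path


def _wilcoxon_p(values: np.ndarray) -> float:
    values = values[~np.isnan(values)]
    if len(values) < 5 or np.allclose(values, 0):
        return np.nan
    return float(sps.wilcoxon(values).pvalue)


def generate_stage(config: StudyConfig) -> SessionData:
    rng = derive_rng(config.seed, "generate")
    return simulate_population(
        config.task,
        config.population,
        rng,
        n_blocks=config.n_blocks,
        with_gaze=config.with_gaze,
        with_licks=config.with_licks,
        lick_rate_hz=config.lick_rate_hz,
        session_id=f"sim-seed{config.seed}",
    )


def analyze_stage(config: StudyConfig, session: SessionData) -> pd.DataFrame:
    return analyze_population(session, config.windows, alpha=config.alpha)


def bootstrap_stage(
    config: StudyConfig, session: SessionData, summary: pd.DataFrame
) -> Optional[pd.DataFrame]:
    """Burst vs non-burst comparison over the flagged tonic increasers."""
    flagged = summary.loc[summary["tonic_increaser"] == 1, "neuron_id"].tolist()
    if len(flagged) < 2:
        log.warning("bootstrap stage skipped: only %d tonic increasers", len(flagged))
        return None
    nb_rows, b_rows = [], []
    for nid in flagged:
        nb, b = mode_period_rates(
            session, nid, config.windows, config.burst, condition=VALUE_INCREASE
        )
        nb_rows.append(nb)
        b_rows.append(b)
    rng = derive_rng(config.seed, "bootstrap")
    results = bootstrap_mode_comparison(
        np.array(nb_rows), np.array(b_rows), config.bootstrap, rng
    )
    period_names = ("initial", "middle", "late")
    return pd.DataFrame(
        [
            {
                "period": period_names[r.period_index],
                "count_non_burst_greater": r.count_non_burst_greater,
                "count_burst_greater": r.count_burst_greater,
                "count_tie": r.count_tie,
                "significant": int(r.significant),
                "direction": r.direction or "",
                "n_neurons": len(flagged),
            }
            for r in results
        ]
    )


def _population_sdf_figure(config: StudyConfig, session: SessionData, neuron_ids, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    for ax, cond in zip(axes, (VALUE_INCREASE, VALUE_DECREASE, VALUE_FIXED)):
        curves = []
        for nid in neuron_ids:
            aligned = align_spikes(session, nid, "cs_onset", conditions=[cond])
            if cond != VALUE_FIXED:
                aligned = truncate_at_stop(aligned)
            if aligned.n_trials == 0:
                continue
            sdf = compute_sdf(aligned, grid_range=(-200, 2450))
            base = baseline_rate(session, nid, config.windows, conditions=[cond])
            curves.append(sdf.subtract(base).rate)
        if curves:
            mean_curve = np.nanmean(np.vstack(curves), axis=0)
            ax.plot(np.arange(-200, 2451), mean_curve)
        ax.axvline(0, color="gray", lw=0.5)
        ax.set_title(cond)
        ax.set_xlabel("time from CS onset (ms)")
    axes[0].set_ylabel("rate - baseline (spikes/s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _histogram_figure(summary: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, col, title in (
        (axes[0], "slope_increase", "slope, value-increase"),
        (axes[1], "slope_decrease", "slope, value-decrease"),
    ):
        vals = summary[col].dropna()
        ax.hist(vals, bins=25, color="0.6")
        ax.axvline(0, color="k", lw=0.8)
        ax.set_title(title)
        ax.set_xlabel("spikes/s per s")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_study(config: StudyConfig, out_dir) -> StudyReport:
    """Execute generate -> analyze -> bootstrap -> report; persist everything."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "generate"
    try:
        session = generate_stage(config)
        io_mod.write_session(session, out / "session", seed=config.seed, config=config.to_dict())

        stage = "analyze"
        summary = analyze_stage(config, session)
        summary_path = out / "neuron_summary.csv"
        summary.to_csv(summary_path, index=False)
        correlations = population_correlations(summary)
        correlations.to_csv(out / "population_correlations.csv", index=False)

        stage = "bootstrap"
        bootstrap_df = bootstrap_stage(config, session, summary)
        if bootstrap_df is not None:
            bootstrap_df.to_csv(out / "bootstrap.csv", index=False)

        stage = "report"
        counts = {
            "n_neurons": int(len(summary)),
            "tonic_increasers": int(summary["tonic_increaser"].sum()),
            "tonic_decreasers": int(summary["tonic_decreaser"].sum()),
            "cue_value_coders": int(summary["cue_value_coder"].sum()),
            "stop_value_coders_increase": int(summary["stop_value_coder_increase"].sum()),
            "stop_value_coders_decrease": int(summary["stop_value_coder_decrease"].sum()),
        }
        population_tests = {
            "mean_slope_increase": float(np.nanmean(summary["slope_increase"])),
            "wilcoxon_p_slope_increase": _wilcoxon_p(summary["slope_increase"].to_numpy()),
            "mean_slope_decrease": float(np.nanmean(summary["slope_decrease"])),
            "wilcoxon_p_slope_decrease": _wilcoxon_p(summary["slope_decrease"].to_numpy()),
        }
        if config.make_figures:
            flagged = summary.loc[summary["tonic_increaser"] == 1, "neuron_id"].tolist()
            if flagged:
                _population_sdf_figure(config, session, flagged, out / "population_sdf.png")
            _histogram_figure(summary, out / "slope_histograms.png")

        report_path = out / "report.md"
        lines = [
            "# Study report",
            "",
            f"- config hash: `{io_mod.config_hash(config.to_dict())}`",
            f"- master seed: {config.seed}",
            "",
            "## Population counts",
            "",
        ]
        lines += [f"- {k}: {v}" for k, v in counts.items()]
        lines += ["", "## Population tests", ""]
        lines += [f"- {k}: {v:.4g}" for k, v in population_tests.items()]
        lines += ["", "## Cross-neuron correlations", "", correlations.to_string(index=False)]
        if bootstrap_df is not None:
            lines += ["", "## Burst vs non-burst bootstrap", "", bootstrap_df.to_string(index=False)]
        report_path.write_text("\n".join(lines) + "\n")
        (out / "report.json").write_text(
            json.dumps({"counts": counts, "population_tests": population_tests}, indent=2)
        )
    except Exception as exc:
        raise RuntimeError(f"study failed during stage {stage!r}: {exc}") from exc

    return StudyReport(
        counts=counts,
        population_tests=population_tests,
        correlations=correlations,
        bootstrap=bootstrap_df,
        summary_path=summary_path,
        report_path=report_path,
    )
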