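"""CSV interchange for sessions: write, load, validate.

Schemas
-------
trials.csv: session_id, trial_id, block_index, condition, cs_type,
    stop_time_ms (empty if none), reward_ml, fixation_onset_ms, cs_onset_ms,
    stop_onset_ms, reward_onset_ms, aborted (0/1)
spikes.csv: session_id, neuron_id, trial_id, spike_time_ms
gaze.csv:   trial_id, sample_time_ms, x_deg, y_deg            (optional)
licks.csv:  trial_id, lick_onset_ms                           (optional)
ground_truth.csv: generator parameters, one row per neuron    (optional)
manifest.json: member files, seed, config hash
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .synth import NeuronGroundTruth, SessionData

log = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "session_id",
    "trial_id",
    "block_index",
    "condition",
    "cs_type",
    "stop_time_ms",
    "reward_ml",
    "fixation_onset_ms",
    "cs_onset_ms",
    "stop_onset_ms",
    "reward_onset_ms",
    "aborted",
]
SPIKE_COLUMNS = ["session_id", "neuron_id", "trial_id", "spike_time_ms"]


class SessionFormatError(ValueError):
    pass


def config_hash(obj) -> str:
    """Stable hash of a (nested) config mapping or dataclass."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_session(session: SessionData, out_dir, seed: Optional[int] = None, config=None) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    session.trials.to_csv(out / "trials.csv", index=False)
    files["trials"] = "trials.csv"
    session.spikes.to_csv(out / "spikes.csv", index=False)
    files["spikes"] = "spikes.csv"
    if session.gaze is not None:
        session.gaze.to_csv(out / "gaze.csv", index=False)
        files["gaze"] = "gaze.csv"
    if session.licks is not None:
        session.licks.to_csv(out / "licks.csv", index=False)
        files["licks"] = "licks.csv"
    if session.ground_truth is not None:
        gt = pd.DataFrame([dataclasses.asdict(n) for n in session.ground_truth])
        gt.to_csv(out / "ground_truth.csv", index=False)
        files["ground_truth"] = "ground_truth.csv"
    if session.spike_tags is not None:
        session.spike_tags.to_csv(out / "spike_tags.csv", index=False)
        files["spike_tags"] = "spike_tags.csv"
    manifest = {
        "session_id": session.session_id,
        "files": files,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _require_columns(df: pd.DataFrame, required, name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{name}: missing column(s) {missing}")


def load_session(session_dir, load_ground_truth: bool = False) -> SessionData:
    """Load and validate a session CSV set.

    Raises :class:`SessionFormatError` with offending row numbers on schema
    violations.  Absent gaze/lick files disable the matching analyses with a
    logged notice.  Ground truth is loaded only on request; analysis code
    never needs it.
    """
    d = Path(session_dir)
    trials_path = d / "trials.csv"
    spikes_path = d / "spikes.csv"
    if not trials_path.exists() or not spikes_path.exists():
        raise SessionFormatError(f"expected trials.csv and spikes.csv under {d}")
    trials = pd.read_csv(trials_path)
    spikes = pd.read_csv(spikes_path)
    _require_columns(trials, TRIAL_COLUMNS, "trials.csv")
    _require_columns(spikes, SPIKE_COLUMNS, "spikes.csv")
    if trials["trial_id"].duplicated().any():
        dup = trials.index[trials["trial_id"].duplicated()].tolist()
        raise SessionFormatError(f"trials.csv: duplicate trial_id at rows {dup}")
    known = set(trials["trial_id"])
    orphan = ~spikes["trial_id"].isin(known)
    if orphan.any():
        rows = spikes.index[orphan].tolist()[:10]
        raise SessionFormatError(
            f"spikes.csv: trial_id not in trial table at rows {rows}"
        )
    if not np.isfinite(spikes["spike_time_ms"]).all():
        rows = spikes.index[~np.isfinite(spikes["spike_time_ms"])].tolist()[:10]
        raise SessionFormatError(f"spikes.csv: non-finite spike times at rows {rows}")
    if (spikes["spike_time_ms"] < 0).any():
        rows = spikes.index[spikes["spike_time_ms"] < 0].tolist()[:10]
        raise SessionFormatError(f"spikes.csv: negative spike times at rows {rows}")
    spikes = spikes.sort_values(["neuron_id", "trial_id", "spike_time_ms"]).reset_index(drop=True)

    gaze = licks = None
    if (d / "gaze.csv").exists():
        gaze = pd.read_csv(d / "gaze.csv")
        _require_columns(gaze, ["trial_id", "sample_time_ms", "x_deg", "y_deg"], "gaze.csv")
    else:
        log.info("no gaze.csv under %s; gaze analyses disabled", d)
    if (d / "licks.csv").exists():
        licks = pd.read_csv(d / "licks.csv")
        _require_columns(licks, ["trial_id", "lick_onset_ms"], "licks.csv")
    else:
        log.info("no licks.csv under %s; lick analyses disabled", d)

    ground_truth = None
    if load_ground_truth and (d / "ground_truth.csv").exists():
        gt = pd.read_csv(d / "ground_truth.csv")
        ground_truth = []
        for rec in gt.to_dict("records"):
            for key in ("stop_phasic_offset", "intra_burst_isi"):
                if isinstance(rec.get(key), str):
                    rec[key] = tuple(
                        float(v) for v in rec[key].strip("()[] ").split(",") if v.strip()
                    )
            ground_truth.append(NeuronGroundTruth(**rec))

    session_id = str(trials["session_id"].iloc[0]) if len(trials) else "session"
    return SessionData(
        trials=trials,
        spikes=spikes,
        gaze=gaze,
        licks=licks,
        ground_truth=ground_truth,
        session_id=session_id,
    )
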