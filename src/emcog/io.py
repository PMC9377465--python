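"""File formats: session CSV, trial JSONL, reports, and manifests.

Conventions: UTF-8 comma-separated CSV with a header row, ``NA`` for
missing values, clock times as HH:MM; trial logs are JSONL with one
trial object per line carrying its session coordinates.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .engines import rescore_session, session_rt
from .types import TrialEvent

SESSION_COLUMNS = [
    "participant_id", "group", "day", "session_idx", "test_id", "phase",
    "score", "rt_mean_s", "n_trials", "n_correct", "terminated_by", "completed",
]


def write_sessions_csv(rows: Iterable[dict] | pd.DataFrame, path) -> None:
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    cols = [c for c in SESSION_COLUMNS if c in df.columns]
    df = df[cols] if len(df) else pd.DataFrame(columns=SESSION_COLUMNS)
    df.to_csv(path, index=False, na_rep="NA")


def read_sessions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    if "completed" in df.columns:
        df["completed"] = df["completed"].astype(bool)
    if "phase" in df.columns:
        df["phase"] = df["phase"].fillna("")
    return df


def sessions_to_long_table(sessions: pd.DataFrame) -> pd.DataFrame:
    """Convert a session summary CSV frame into the analysis long table.

    Drops the unscored list-study exposures and renames the secondary
    reaction-time column; the result has one row per scored scheduled
    administration.
    """
    df = sessions.copy()
    df["phase"] = df.get("phase", "").fillna("")
    study = (df["test_id"] == "vlmt") & (df["phase"] == "")
    df = df[~study]
    out = df[["participant_id", "group", "day", "session_idx", "test_id",
              "phase", "completed", "score"]].copy()
    out["rt"] = df["rt_mean_s"].to_numpy() if "rt_mean_s" in df.columns else np.nan
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# trial logs
# ---------------------------------------------------------------------------

def write_trials_jsonl(rows: Iterable[dict], path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write(json.dumps(row, default=_jsonable) + "\n")


def read_trials_jsonl(path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed trial record: {exc}")
    return rows


def rescore_trials(trial_rows: list[dict]) -> pd.DataFrame:
    """Re-score sessions from raw trial logs (log -> score round trip).

    Groups trials by session coordinates, re-adjudicates each from its
    stored stimulus/response, folds the engine scoring rule, and infers
    the termination reason from the log itself.  The output matches the
    engine-emitted session CSV on all scoring columns.
    """
    if not trial_rows:
        return pd.DataFrame(columns=[c for c in SESSION_COLUMNS if c != "group"])
    frame = pd.DataFrame(trial_rows)
    out = []
    keys = ["participant_id", "day", "session_idx", "test_id", "phase"]
    for key, g in frame.groupby(keys, sort=True):
        g = g.sort_values("trial_index")
        trials = [TrialEvent.from_dict(r) for r in g.to_dict("records")]
        test_id = key[3]
        score = rescore_session(test_id, trials)
        n_correct = sum(t.correct for t in trials)
        n_err = len(trials) - n_correct
        if test_id == "matching_pair":
            terminated = "time_limit"
        elif test_id in ("memory_matrix", "copykat") and n_err >= 3:
            terminated = "error_limit"
        else:
            terminated = "trial_count"
        out.append({
            "participant_id": key[0], "day": key[1], "session_idx": key[2],
            "test_id": test_id, "phase": key[4], "score": score,
            "rt_mean_s": session_rt(test_id, trials),
            "n_trials": len(trials), "n_correct": n_correct,
            "terminated_by": terminated, "completed": True,
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# reports & manifests
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonable))


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=_jsonable)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(path, seed: int, config_dict: dict, counts: dict) -> None:
    from . import __version__
    manifest = {
        "emcog_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config_dict),
        "record_counts": counts,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=_jsonable))
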