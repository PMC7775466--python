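"""CSV/JSON round-tripping for sessions, walks, fits, and reports.

CSV is the interchange format for all tabular artifacts; statistical reports
go to JSON.  Every run directory gets a ``run_info.json`` sidecar with the
config hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .task import RewardWalk, SessionData

logger = logging.getLogger(__name__)

__all__ = [
    "sessions_to_frame",
    "write_sessions",
    "read_sessions",
    "write_walk",
    "read_walk",
    "write_json_report",
    "write_run_info",
]


def sessions_to_frame(sessions: list[SessionData]) -> pd.DataFrame:
    return pd.concat([s.to_frame() for s in sessions], ignore_index=True)


def write_sessions(sessions: list[SessionData], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_sessions(path) -> list[SessionData]:
    """Read a cohort CSV; rows with missing choices are dropped and counted."""
    df = pd.read_csv(path)
    required = ["first_choice", "second_state", "second_choice", "reward"]
    ok = df[required].notna().all(axis=1)
    if not ok.all():
        logger.warning("dropping %d row(s) with missing choices", int((~ok).sum()))
        df = df[ok]
    return [
        SessionData.from_frame(g) for _, g in df.groupby("subject_id", sort=False)
    ]


def write_walk(walk: RewardWalk, path) -> None:
    walk.to_frame().to_csv(path, index=False)


def read_walk(path) -> RewardWalk:
    return RewardWalk.from_frame(pd.read_csv(path))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(report), fh, indent=2, allow_nan=True)


def write_run_info(out_dir, config_text: str, seed: int) -> None:
    from . import __version__

    info = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": int(seed),
        "version": __version__,
    }
    with open(Path(out_dir) / "run_info.json", "w") as fh:
        json.dump(info, fh, indent=2)
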