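"""Readers and writers for the package's flat-file formats.

Sessions travel as CSV with one row per trial (``subject_id, trial,
trial_type, offered, choice, reward``; offer lists are semicolon-joined,
trial indices 1-based). Evidence matrices are subjects x models CSV.
Fit and group-comparison results serialize to JSON.
"""

from __future__ import annotations

import json
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult
from .model_selection import EvidenceMatrix
from .simulate import SessionData, TrialRecord
from .tasks import TaskSpec

SESSION_COLUMNS = ("subject_id", "trial", "trial_type", "offered", "choice", "reward")


def write_sessions(sessions: Sequence[SessionData], path: str) -> None:
    rows = []
    for sess in sessions:
        for t in sess.trials:
            rows.append(
                {
                    "subject_id": sess.subject_id,
                    "trial": t.index,
                    "trial_type": t.trial_type,
                    "offered": ";".join(t.offered),
                    "choice": t.choice,
                    "reward": t.reward,
                }
            )
    pd.DataFrame(rows, columns=list(SESSION_COLUMNS)).to_csv(path, index=False)


class SessionFormatError(ValueError):
    """A session CSV row violated the format contract."""


def read_sessions(path: str, task: TaskSpec) -> List[SessionData]:
    """Parse a session CSV against a task; errors name 1-based data rows."""
    df = pd.read_csv(path, dtype={"subject_id": str, "trial_type": str,
                                  "offered": str, "choice": str})
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise SessionFormatError(f"{path}: missing columns {sorted(missing)}")
    sessions: List[SessionData] = []
    for subject_id, group in df.groupby("subject_id", sort=False):
        trials: List[TrialRecord] = []
        expected = 1
        for row_number, row in zip(group.index + 1, group.itertuples(index=False)):
            try:
                trial = int(row.trial)
                reward = float(row.reward)
            except (TypeError, ValueError) as exc:
                raise SessionFormatError(f"{path}: row {row_number}: {exc}") from exc
            if trial != expected:
                raise SessionFormatError(
                    f"{path}: row {row_number}: subject {subject_id!r} trial index "
                    f"{trial} (expected {expected})"
                )
            offered = tuple(str(row.offered).split(";"))
            if row.choice not in offered:
                raise SessionFormatError(
                    f"{path}: row {row_number}: choice {row.choice!r} not among offered {offered}"
                )
            trials.append(TrialRecord(trial, str(row.trial_type), offered, str(row.choice), reward))
            expected += 1
        try:
            sessions.append(SessionData(subject_id=str(subject_id), task=task, trials=trials))
        except ValueError as exc:
            raise SessionFormatError(f"{path}: subject {subject_id!r}: {exc}") from exc
    return sessions


def write_evidence(matrix: EvidenceMatrix, path: str) -> None:
    pd.DataFrame(matrix.values, index=list(matrix.subjects),
                 columns=list(matrix.models)).to_csv(path, index_label="subject_id")


def read_evidence(path: str) -> EvidenceMatrix:
    df = pd.read_csv(path, index_col="subject_id")
    return EvidenceMatrix(
        values=df.to_numpy(dtype=float),
        subjects=tuple(str(s) for s in df.index),
        models=tuple(str(m) for m in df.columns),
    )


def write_fits(fits: Sequence[FitResult], path: str,
               extra: Optional[Dict] = None) -> None:
    payload = {"fits": [f.to_dict() for f in fits]}
    if extra:
        payload.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_fits(path: str) -> List[dict]:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)["fits"]
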