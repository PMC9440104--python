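"""CSV dialect for trial tables and tidy result files.

Trial tables are long-format UTF-8 CSV with '.' decimal separator, one row
per trial, columns: participant_id, study_id, trial_index, target,
effort_rank, addend, reward, choice, decision_time, task_accuracy, task_rt.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import TRIAL_COLUMNS

_TRIAL_DTYPES = {
    "participant_id": str,
    "study_id": int,
    "trial_index": int,
    "target": str,
    "effort_rank": int,
    "addend": int,
    "reward": int,
    "choice": int,
    "decision_time": float,
    "task_accuracy": int,
    "task_rt": float,
}


def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table lacks column(s) {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)
    return path


def read_trials(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=_TRIAL_DTYPES)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return frame
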