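"""Readers/writers for the tidy trial-table format, configuration handling,
and run manifests.

Trial tables are plain CSV, one row per trial:

    subject_id, session, drug, trial, phase, choice_role, outcome, rt_ms

``trial`` is 1-based; ``choice_role`` is one of R-P / P-R / N-N; ``rt_ms``
is optional.  Subject covariates live in a separate CSV keyed by
subject_id.  Small behavioural datasets stay inspectable this way.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .task import ROLES, Session, TaskConfig

__all__ = ["write_trials", "read_trials", "write_subjects", "read_subjects",
           "load_task_config", "task_config_to_dict", "RunManifest"]

_ROLE_TO_IDX = {r: i for i, r in enumerate(ROLES)}
TRIAL_COLUMNS = ["subject_id", "session", "drug", "trial", "phase",
                 "choice_role", "outcome", "rt_ms"]


def write_trials(dataset: Sequence[Sequence[Session]], path) -> pd.DataFrame:
    """Serialise a cohort to the tidy trial table; returns the frame."""
    rows = []
    for sessions in dataset:
        for sess in sessions:
            phases = sess.phases
            for t in range(sess.n_trials):
                rows.append({
                    "subject_id": sess.subject_id,
                    "session": sess.session_index,
                    "drug": sess.drug_label,
                    "trial": t + 1,
                    "phase": phases[t],
                    "choice_role": ROLES[sess.choices[t]],
                    "outcome": int(sess.outcomes[t]),
                    "rt_ms": (float(sess.rt_ms[t]) if sess.rt_ms is not None
                              else np.nan),
                })
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_trials(path, config: Optional[TaskConfig] = None,
                subjects: Optional[pd.DataFrame] = None) -> list:
    """Read a trial table into a validated per-subject session-list dataset.

    Raises with the offending row(s) named on: unknown drug labels,
    outcomes outside {-1, +1}, bad roles, or duplicate
    (subject, session, trial) keys.  ``subjects`` (indexed by subject_id,
    columns wm_span/bis) attaches covariates when given.
    """
    config = config or TaskConfig()
    df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    required = [c for c in TRIAL_COLUMNS if c != "rt_ms"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad = ~df["drug"].isin(["placebo", "MPH"])
    if bad.any():
        raise ValueError(f"unknown drug label(s) at rows {df.index[bad].tolist()[:5]}")
    bad = ~df["outcome"].isin([-1, 1])
    if bad.any():
        raise ValueError(f"outcome must be -1/+1; bad rows {df.index[bad].tolist()[:5]}")
    bad = ~df["choice_role"].isin(ROLES)
    if bad.any():
        raise ValueError(f"unknown choice_role at rows {df.index[bad].tolist()[:5]}")
    dup = df.duplicated(subset=["subject_id", "session", "trial"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject, session, trial) at rows {df.index[dup].tolist()[:5]}")
    has_rt = "rt_ms" in df.columns and df["rt_ms"].notna().any()

    dataset = []
    for sid, sub in df.groupby("subject_id", sort=True):
        wm = bis = None
        if subjects is not None and sid in subjects.index:
            wm = subjects.loc[sid].get("wm_span")
            bis = subjects.loc[sid].get("bis")
        sessions = []
        for s_idx, block in sub.groupby("session", sort=True):
            block = block.sort_values("trial")
            rt = block["rt_ms"].to_numpy(float) if has_rt else None
            if rt is not None and np.isnan(rt).all():
                rt = None
            sessions.append(Session(
                subject_id=str(sid),
                drug_label=str(block["drug"].iloc[0]),
                choices=np.array([_ROLE_TO_IDX[r] for r in block["choice_role"]]),
                outcomes=block["outcome"].to_numpy(float),
                config=config, rt_ms=rt, wm_span=wm, bis=bis,
                session_index=int(s_idx)))
        dataset.append(sessions)
    return dataset


def write_subjects(subjects: pd.DataFrame, path):
    subjects.to_csv(path, index=True)


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    key = "subject" if "subject" in df.columns else "subject_id"
    return df.set_index(key)


def task_config_to_dict(config: TaskConfig) -> dict:
    return {
        "n_trials": config.n_trials,
        "reversal_trial": config.reversal_trial,
        "n_options": config.n_options,
        "contingencies": np.asarray(config.contingencies).tolist(),
        "schedule_mode": config.schedule_mode,
        "max_run": config.max_run,
    }


def load_task_config(path_or_dict) -> TaskConfig:
    """Task configuration from a YAML file or a plain dict."""
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    if "contingencies" in raw:
        raw["contingencies"] = np.asarray(raw["contingencies"], dtype=float)
    return TaskConfig(**raw)


@dataclass
class RunManifest:
    """Provenance record for a pipeline run: every stochastic stage's seed
    must appear here.  Written at start, finalised at the end."""

    command: str
    seeds: dict
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    config_hash: str = ""
    stages: list = field(default_factory=list)
    version: str = ""
    started: str = ""
    finished: str = ""

    @staticmethod
    def hash_config(config: dict) -> str:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def start(self, path):
        from . import __version__
        self.version = __version__
        self.started = time.strftime("%Y-%m-%dT%H:%M:%S")
        self._write(path)

    def finish(self, path):
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        self._write(path)

    def record_stage(self, name: str):
        self.stages.append(name)

    def _write(self, path):
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))
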