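"""Delimited-text serialisation of trial and choice tables.

One row per trial; stimulus heights are spread over columns
``h_left_1..n`` / ``h_right_1..n`` alongside the generative parameters
per side.  Choice tables append choice/correct and optional epoch,
session and timing metadata.  Round-trips are exact for rounded
(integer) heights and float-precise otherwise.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .trialgen import (
    ChoiceSet,
    GenConfig,
    GenerativeParams,
    StimulusStream,
    Trial,
    TrialSet,
)

__all__ = [
    "trials_to_frame",
    "frame_to_trials",
    "choices_to_frame",
    "frame_to_choices",
    "write_trials",
    "read_trials",
    "write_choices",
    "read_choices",
    "load_config",
]


def trials_to_frame(ts: TrialSet) -> pd.DataFrame:
    rows = []
    for i, t in enumerate(ts):
        row = {
            "trial_id": i,
            "context": t.context,
            "condition": t.condition,
            "n_samples": t.n_samples,
            "mu_left": t.left.params.mu,
            "sigma_left": t.left.params.sigma,
            "type_left": t.left.params.stream_type,
            "z_left": t.left.params.z,
            "mu_right": t.right.params.mu,
            "sigma_right": t.right.params.sigma,
            "type_right": t.right.params.stream_type,
            "z_right": t.right.params.z,
            "seed": ts.seed,
        }
        for k, h in enumerate(t.left.heights):
            row[f"h_left_{k + 1}"] = h
        for k, h in enumerate(t.right.heights):
            row[f"h_right_{k + 1}"] = h
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_trials(df: pd.DataFrame) -> TrialSet:
    trials = []
    for _, row in df.iterrows():
        n = int(row["n_samples"])
        left = StimulusStream(
            np.array([row[f"h_left_{k + 1}"] for k in range(n)], dtype=float),
            GenerativeParams(
                float(row["mu_left"]),
                float(row["sigma_left"]),
                str(row["type_left"]),
                float(row.get("z_left", 0.0)),
            ),
        )
        right = StimulusStream(
            np.array([row[f"h_right_{k + 1}"] for k in range(n)], dtype=float),
            GenerativeParams(
                float(row["mu_right"]),
                float(row["sigma_right"]),
                str(row["type_right"]),
                float(row.get("z_right", 0.0)),
            ),
        )
        trials.append(Trial(left, right, str(row["context"]), str(row["condition"])))
    seed = int(df["seed"].iloc[0]) if "seed" in df.columns and len(df) else 0
    return TrialSet(trials, {}, seed)


def choices_to_frame(cs: ChoiceSet) -> pd.DataFrame:
    df = trials_to_frame(cs.trials)
    df["chose_left"] = cs.chose_left.astype(int)
    df["correct"] = cs.correct.astype(int)
    if cs.epoch is not None:
        df["epoch"] = np.asarray(cs.epoch)
    if cs.session_id is not None:
        df["session_id"] = cs.session_id
    if cs.time_min is not None:
        df["time_min"] = np.asarray(cs.time_min)
    return df


def frame_to_choices(df: pd.DataFrame) -> ChoiceSet:
    ts = frame_to_trials(df)
    return ChoiceSet(
        ts,
        df["chose_left"].to_numpy(dtype=bool),
        df["correct"].to_numpy(dtype=bool),
        epoch=df["epoch"].to_numpy() if "epoch" in df.columns else None,
        session_id=df["session_id"].iloc[0] if "session_id" in df.columns else None,
        time_min=df["time_min"].to_numpy(dtype=float) if "time_min" in df.columns else None,
    )


def write_trials(ts: TrialSet, path) -> None:
    trials_to_frame(ts).to_csv(path, index=False)


def read_trials(path) -> TrialSet:
    return frame_to_trials(pd.read_csv(path))


def write_choices(cs: ChoiceSet, path) -> None:
    choices_to_frame(cs).to_csv(path, index=False)


def read_choices(path) -> ChoiceSet:
    return frame_to_choices(pd.read_csv(path))


def load_config(path) -> GenConfig:
    """Build a GenConfig from a YAML/JSON key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return GenConfig(**raw)
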