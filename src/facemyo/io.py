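"""Plain-text dataset persistence.

Layout of a dataset directory:

    meta.json              channel names, sampling rate, units, generator
                           parameters
    events.tsv             trial, session, onset_sample, duration_samples,
                           label (one row per trial)
    trials/trial_0000.tsv  one tab-separated signal file per trial record,
                           one column per channel

All files are plain text so datasets diff cleanly and open anywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth_emg import ActionClass, EmgRecording, TrialTimeline

__all__ = ["save_dataset", "load_dataset", "save_features", "load_features"]


def save_dataset(
    directory: str | Path,
    recordings: list[EmgRecording],
    labels: pd.DataFrame,
    timeline: TrialTimeline | None = None,
    extra_meta: dict | None = None,
) -> Path:
    """Write recordings + label table to a dataset directory."""
    directory = Path(directory)
    trials_dir = directory / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    timeline = timeline or TrialTimeline()

    rows = []
    for i, (rec, (_, label_row)) in enumerate(zip(recordings, labels.iterrows())):
        df = pd.DataFrame(rec.signal.T, columns=list(rec.channels))
        df.to_csv(trials_dir / f"trial_{i:04d}.tsv", sep="\t",
                  index=False, float_format="%.6f")
        onset, action = rec.events[0]
        rows.append(
            {
                "trial": int(label_row["trial"]),
                "session": int(label_row["session"]),
                "onset_sample": int(onset),
                "duration_samples": int(round(timeline.action_s * rec.sampling_rate)),
                "label": action.value,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "events.tsv", sep="\t", index=False)

    rec0 = recordings[0]
    meta = {
        "sampling_rate": rec0.sampling_rate,
        "channels": list(rec0.channels),
        "units": "arbitrary amplitude units",
        "n_trials": len(recordings),
        "timeline": {
            "prep_s": timeline.prep_s,
            "action_s": timeline.action_s,
            "break_s": timeline.break_s,
        },
    }
    if extra_meta:
        meta.update(extra_meta)
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_dataset(directory: str | Path) -> tuple[list[EmgRecording], pd.DataFrame]:
    """Read back a dataset directory written by :func:`save_dataset`."""
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    events = pd.read_csv(directory / "events.tsv", sep="\t")
    channels = tuple(meta["channels"])
    fs = float(meta["sampling_rate"])

    recordings = []
    for _, row in events.iterrows():
        path = directory / "trials" / f"trial_{int(row['trial']):04d}.tsv"
        df = pd.read_csv(path, sep="\t")
        recordings.append(
            EmgRecording(
                signal=df[list(channels)].to_numpy().T,
                sampling_rate=fs,
                channels=channels,
                events=[(int(row["onset_sample"]), ActionClass(row["label"]))],
                meta={"trial": int(row["trial"]), "session": int(row["session"])},
            )
        )
    labels = events[["trial", "session", "label"]].copy()
    return recordings, labels


def save_features(path: str | Path, table: pd.DataFrame, labels) -> Path:
    """Tab-separated feature table with a trailing ``label`` column."""
    path = Path(path)
    out = table.copy()
    out["label"] = [getattr(a, "value", a) for a in labels]
    out.to_csv(path, sep="\t", index=False)
    return path


def load_features(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    labels = np.array([ActionClass(v) for v in df.pop("label")], dtype=object)
    return df, labels
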