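"""Delimited-text I/O for audiogram datasets and trial sequences.

Audiogram CSV schema: columns ``id, age, gender, f125, f250, ..., f8000``
(one column per standard frequency; empty cell = threshold undefined).
Trials CSV schema: ``frequency_hz, intensity_db, response`` with response
in {-1, +1}.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gp_mixture import SideInfo
from .learning import AudiogramDataset, AudiogramRecord
from .psychoacoustics import STANDARD_FREQUENCIES_HZ, bark, bark_inverse
from .response_model import Stimulus, Trial

__all__ = [
    "read_audiograms",
    "write_audiograms",
    "read_trials",
    "write_trials",
]

_FREQ_COLUMNS = {f"f{int(f)}": float(f) for f in STANDARD_FREQUENCIES_HZ}


def write_audiograms(dataset: AudiogramDataset, path) -> None:
    rows = []
    for i, rec in enumerate(dataset.records):
        row = {
            "id": i,
            "age": "" if rec.info.age is None else rec.info.age,
            "gender": rec.info.gender,
        }
        for col, f in _FREQ_COLUMNS.items():
            row[col] = rec.thresholds.get(f, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_audiograms(path) -> AudiogramDataset:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        age = row.get("age")
        age = None if pd.isna(age) or age == "" else int(age)
        gender = row.get("gender")
        gender = "unspecified" if pd.isna(gender) or gender == "" else str(gender)
        thresholds = {}
        for col, f in _FREQ_COLUMNS.items():
            if col in df.columns and not pd.isna(row[col]):
                thresholds[f] = float(row[col])
        records.append(AudiogramRecord(thresholds=thresholds, info=SideInfo(age=age, gender=gender)))
    return AudiogramDataset(records)


def write_trials(trials, path) -> None:
    df = pd.DataFrame(
        {
            "frequency_hz": [bark_inverse(t.stimulus.x) for t in trials],
            "intensity_db": [t.stimulus.h for t in trials],
            "response": [t.y for t in trials],
        }
    )
    df.to_csv(path, index=False)


def read_trials(path) -> list:
    df = pd.read_csv(path)
    trials = []
    for _, row in df.iterrows():
        y = int(row["response"])
        trials.append(
            Trial(Stimulus(x=bark(float(row["frequency_hz"])), h=float(row["intensity_db"])), y)
        )
    return trials
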