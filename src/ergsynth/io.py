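"""CSV persistence for waveform datasets.

Long (tidy) dialect, one row per sample:

    subject_id,eye,sex,stimulus,provenance,replicate_index,fs,sample_index,amplitude_uv

A record is identified by (subject_id, eye, sex, stimulus, provenance,
replicate_index); within a record, sample_index runs contiguously from 0 and
fs is constant.  All records of one stimulus in a dataset share length and
sampling rate.  Missing or non-finite amplitudes are rejected, never imputed:
the upstream acquisition averages artifact-rejected sweeps, so a clean
waveform is part of the contract.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import ErgWaveform

__all__ = ["COLUMNS", "DatasetError", "write_dataset", "read_dataset", "dataset_frame"]

COLUMNS = [
    "subject_id", "eye", "sex", "stimulus", "provenance",
    "replicate_index", "fs", "sample_index", "amplitude_uv",
]

_KEY = ["subject_id", "eye", "sex", "stimulus", "provenance", "replicate_index"]


class DatasetError(ValueError):
    """Raised on malformed dataset files or invalid datasets."""


def _check_homogeneous(dataset: Sequence[ErgWaveform]) -> None:
    shapes: dict[str, tuple[int, float]] = {}
    for w in dataset:
        got = (w.samples.size, w.fs)
        want = shapes.setdefault(w.stimulus, got)
        if got != want:
            raise DatasetError(
                f"records of stimulus {w.stimulus} disagree in length/fs: {got} vs {want}"
            )


def dataset_frame(dataset: Sequence[ErgWaveform]) -> pd.DataFrame:
    """Long-format DataFrame view of a waveform collection."""
    if not dataset:
        raise DatasetError("empty dataset")
    _check_homogeneous(dataset)
    parts = []
    for w in dataset:
        n = w.samples.size
        parts.append(pd.DataFrame({
            "subject_id": w.subject_id, "eye": w.eye, "sex": w.sex,
            "stimulus": w.stimulus, "provenance": w.provenance,
            "replicate_index": w.replicate_index, "fs": w.fs,
            "sample_index": np.arange(n), "amplitude_uv": w.samples,
        }))
    return pd.concat(parts, ignore_index=True)[COLUMNS]


def write_dataset(dataset: Sequence[ErgWaveform], path: str | os.PathLike) -> None:
    """Write a dataset to CSV in the long dialect (repr-faithful amplitudes)."""
    frame = dataset_frame(dataset)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(COLUMNS) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(
                f"{row.subject_id},{row.eye},{row.sex},{row.stimulus},"
                f"{row.provenance},{row.replicate_index},{row.fs!r},"
                f"{row.sample_index},{row.amplitude_uv!r}\n"
            )


def read_dataset(path: str | os.PathLike) -> list[ErgWaveform]:
    """Read a dataset CSV, validating the dialect record by record."""
    frame = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetError(f"missing columns: {missing}")
    if frame.empty:
        raise DatasetError("dataset file contains no rows")
    if frame["amplitude_uv"].isna().any() or not np.isfinite(frame["amplitude_uv"]).all():
        bad = frame.loc[~np.isfinite(frame["amplitude_uv"].fillna(np.nan))]
        key = tuple(bad.iloc[0][k] for k in _KEY)
        raise DatasetError(f"non-finite amplitude in record {key}")

    dataset: list[ErgWaveform] = []
    for key, grp in frame.groupby(_KEY, sort=False):
        if grp["fs"].nunique() != 1:
            raise DatasetError(f"mixed sampling rates within record {key}")
        grp = grp.sort_values("sample_index")
        idx = grp["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise DatasetError(f"sample_index not a contiguous 0-based run in record {key}")
        subject_id, eye, sex, stimulus, provenance, replicate_index = key
        dataset.append(ErgWaveform(
            samples=grp["amplitude_uv"].to_numpy(dtype=float),
            fs=float(grp["fs"].iloc[0]), stimulus=str(stimulus),
            subject_id=str(subject_id), eye=str(eye), sex=str(sex),
            provenance=str(provenance), replicate_index=int(replicate_index),
        ))
    _check_homogeneous(dataset)
    return dataset
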