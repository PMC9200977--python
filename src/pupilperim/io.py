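"""Readers and writers for traces, subject tables, features and results.

Traces travel as long-format delimited text, one row per sample:
``subject_id,eye,condition,target_index,time_s,diameter_mm`` with missing
diameters encoded as empty fields.  Subjects and features are tab-separated
tables; structured results are JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .features import PARAMETER_NAMES
from .protocol import Condition, Eye
from .synth import Cohort, PupilTrace

log = logging.getLogger(__name__)

TRACE_COLUMNS = ["subject_id", "eye", "condition", "target_index", "time_s", "diameter_mm"]
SUBJECT_COLUMNS = ["subject_id", "group", "age_years", "sex"]


def write_traces(traces, path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": tr.subject_id,
                    "eye": tr.eye.value,
                    "condition": tr.condition.value,
                    "target_index": tr.target_index,
                    "time_s": tr.times,
                    "diameter_mm": tr.diameters,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACE_COLUMNS)
    out.to_csv(path, index=False)


def read_traces(path) -> list[PupilTrace]:
    """Read long-format traces, rejecting malformed traces individually.

    A trace with a non-uniform or non-increasing time grid is dropped with
    a logged warning naming the trace key; other traces are kept.
    """
    df = pd.read_csv(path)
    if df.empty:
        log.warning("trace file %s is empty", path)
        return []
    missing_cols = set(TRACE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"trace file missing columns: {sorted(missing_cols)}")
    traces: list[PupilTrace] = []
    for key, grp in df.groupby(
        ["subject_id", "eye", "condition", "target_index"], sort=False
    ):
        t = grp["time_s"].to_numpy(dtype=float)
        if len(t) < 2 or np.any(np.diff(t) <= 0) or not np.allclose(
            np.diff(t), t[1] - t[0], rtol=0, atol=1e-9
        ):
            log.warning("rejecting trace %s: non-uniform time grid (rows %d..%d)",
                        key, grp.index[0] + 2, grp.index[-1] + 2)
            continue
        traces.append(
            PupilTrace(
                subject_id=str(key[0]),
                eye=Eye(key[1]),
                condition=Condition(key[2]),
                target_index=int(key[3]),
                times=t,
                diameters=grp["diameter_mm"].to_numpy(dtype=float),
            )
        )
    return traces


def write_subjects(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, sep="\t", index=False)


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subject file missing columns: {sorted(missing)}")
    bad = set(df["group"]) - {"FHpos", "FHneg"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return df


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"subject_id", "eye", "condition", "target_index", *PARAMETER_NAMES}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"feature file missing columns: {sorted(missing)}")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def cohort_to_files(cohort: Cohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_traces(cohort.traces, outdir / "traces.csv")
    write_subjects(cohort.subjects, outdir / "subjects.tsv")
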