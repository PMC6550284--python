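"""Reading and writing actigraphy files in the public dataset's dialect.

Each subject is one CSV with header ``timestamp,date,activity``
(``YYYY-MM-DD HH:MM:SS`` timestamps at one-minute spacing), stored under a
``condition/`` or ``control/`` subdirectory; a separate ``scores.csv``
carries, at minimum, ``number`` (subject id), ``afftype`` (group code) and
the pre/post MADRS scores ``madrs1``/``madrs2`` for condition subjects.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import (GROUP_CONTROL, GROUP_PATIENT, ActigraphySeries, Cohort,
                   SubjectRecord)

REQUIRED_COLUMNS = ("timestamp", "date", "activity")


def read_subject_csv(path: Union[str, Path]) -> ActigraphySeries:
    """Load one subject CSV into an :class:`ActigraphySeries`.

    The loader enforces the dialect contract: required columns, strictly
    one-minute spacing with no gaps, non-negative activity.  Violations raise
    ``ValueError`` naming the first offending data row (0-based).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    if len(frame) == 0:
        raise ValueError(f"{path.name}: file has no data rows")

    stamps = pd.to_datetime(frame["timestamp"], format="%Y-%m-%d %H:%M:%S")
    steps = stamps.diff().dropna()
    bad = steps[steps != pd.Timedelta(minutes=1)]
    if len(bad) > 0:
        row = int(bad.index[0])
        raise ValueError(
            f"{path.name}: timestamps must advance by exactly 1 minute; "
            f"row {row} steps by {bad.iloc[0]}")

    activity = pd.to_numeric(frame["activity"], errors="coerce")
    if activity.isna().any():
        row = int(activity.isna().idxmax())
        raise ValueError(f"{path.name}: non-numeric activity at row {row}")
    if (activity < 0).any():
        row = int((activity < 0).idxmax())
        raise ValueError(f"{path.name}: negative activity at row {row}")

    return ActigraphySeries(subject_id=path.stem, start_time=stamps.iloc[0],
                            values=activity.to_numpy(dtype=float))


def write_subject_csv(series: ActigraphySeries, path: Union[str, Path]) -> Path:
    """Write a series in the exact dialect :func:`read_subject_csv` accepts."""
    path = Path(path)
    stamps = pd.date_range(series.start_time, periods=len(series), freq="min")
    frame = pd.DataFrame({
        "timestamp": stamps.strftime("%Y-%m-%d %H:%M:%S"),
        "date": stamps.strftime("%Y-%m-%d"),
        "activity": series.values,
    })
    frame.to_csv(path, index=False)
    return path


def write_cohort(cohort: Cohort, out_dir: Union[str, Path]) -> Path:
    """Write one CSV per subject under ``condition/``/``control/`` plus scores.csv."""
    out_dir = Path(out_dir)
    (out_dir / "condition").mkdir(parents=True, exist_ok=True)
    (out_dir / "control").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        sub = "condition" if rec.group == GROUP_PATIENT else "control"
        write_subject_csv(rec.series, out_dir / sub / f"{rec.subject_id}.csv")
        rows.append({
            "number": rec.subject_id,
            "afftype": 1 if rec.group == GROUP_PATIENT else 0,
            "madrs1": rec.madrs_pre if rec.madrs_pre is not None else "",
            "madrs2": rec.madrs_post if rec.madrs_post is not None else "",
        })
    pd.DataFrame(rows).to_csv(out_dir / "scores.csv", index=False)
    return out_dir


def load_cohort(directory: Union[str, Path],
                scores: Union[str, Path, None] = None) -> Cohort:
    """Assemble a cohort from ``condition/`` + ``control/`` CSVs and a scores table.

    Group is taken from the subdirectory.  MADRS pre/post scores are attached
    to condition subjects (an error if missing); scores listed for a control
    raise a warning and are dropped.
    """
    directory = Path(directory)
    scores = Path(scores) if scores is not None else directory / "scores.csv"

    paths = sorted((directory / "condition").glob("*.csv")) + \
        sorted((directory / "control").glob("*.csv"))
    if not paths:
        raise ValueError(f"no subjects found under {directory}")

    table = pd.read_csv(scores)
    if "number" not in table.columns:
        raise ValueError(f"{scores.name}: missing 'number' column")
    table = table.set_index(table["number"].astype(str))

    records = []
    for path in paths:
        series = read_subject_csv(path)
        group = GROUP_PATIENT if path.parent.name == "condition" else GROUP_CONTROL
        pre = post = None
        if series.subject_id in table.index:
            row = table.loc[series.subject_id]
            pre = row.get("madrs1")
            post = row.get("madrs2")
            pre = None if pd.isna(pre) or pre == "" else float(pre)
            post = None if pd.isna(post) or post == "" else float(post)
        if group == GROUP_PATIENT:
            if pre is None or post is None:
                raise ValueError(
                    f"scores row with madrs1/madrs2 missing for condition "
                    f"subject {series.subject_id}")
        elif pre is not None or post is not None:
            warnings.warn(f"control {series.subject_id} has MADRS scores; dropped")
            pre = post = None
        records.append(SubjectRecord(series.subject_id, group, series,
                                     madrs_pre=pre, madrs_post=post))
    return Cohort(records=records)


def truncate_to_common_length(cohort: Cohort) -> Cohort:
    """Cut every series to the cohort-wide minimum length, keeping the
    earliest minutes, so every derived biomarker exists for every subject."""
    if len(cohort) == 0:
        raise ValueError("cannot truncate an empty cohort")
    n = min(len(r.series) for r in cohort)
    records = []
    for rec in cohort:
        series = rec.series if len(rec.series) == n else rec.series.truncated(n)
        records.append(SubjectRecord(rec.subject_id, rec.group, series,
                                     madrs_pre=rec.madrs_pre,
                                     madrs_post=rec.madrs_post))
    return Cohort(records=records, common_length=n)
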