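"""Core data containers shared across the pipeline.

The unit of analysis is a subject wearing a wrist actigraph: gross motor
activity is summarized as one non-negative count per minute.  A cohort is a
set of such recordings split into a patient (mood-disorder) group and a
healthy-control group, with pre/post MADRS depression scores attached to
patients only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GROUP_PATIENT = "patient"
GROUP_CONTROL = "control"
VALID_GROUPS = (GROUP_PATIENT, GROUP_CONTROL)


@dataclass
class ActigraphySeries:
    """Equally spaced minute-level activity counts for one subject.

    Parameters
    ----------
    subject_id : str
        Stable identifier, typically the file stem (``condition_12``).
    start_time : pandas.Timestamp
        Wall-clock time of the first sample, minute resolution.
    values : numpy.ndarray
        Non-negative activity counts, one per minute, no gaps.
    """

    subject_id: str
    start_time: pd.Timestamp
    values: np.ndarray

    #: sampling interval; fixed by the data model
    interval: pd.Timedelta = field(default=pd.Timedelta(minutes=1))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("series must be a non-empty 1-D array")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("series contains non-finite values")
        if np.any(self.values < 0):
            bad = int(np.argmax(self.values < 0))
            raise ValueError(f"negative activity at row {bad}")
        self.start_time = pd.Timestamp(self.start_time).floor("min")

    def __len__(self) -> int:
        return int(self.values.size)

    def truncated(self, n_minutes: int) -> "ActigraphySeries":
        """Return a copy keeping only the earliest ``n_minutes`` samples."""
        if n_minutes < 1 or n_minutes > len(self):
            raise ValueError(f"cannot truncate length {len(self)} to {n_minutes}")
        return ActigraphySeries(self.subject_id, self.start_time,
                                self.values[:n_minutes].copy())


@dataclass
class SubjectRecord:
    """One subject: series, diagnostic group, and (patients only) MADRS scores."""

    subject_id: str
    group: str
    series: ActigraphySeries
    madrs_pre: Optional[float] = None
    madrs_post: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {VALID_GROUPS}")
        has_scores = self.madrs_pre is not None or self.madrs_post is not None
        if self.group == GROUP_CONTROL and has_scores:
            raise ValueError("controls carry no MADRS scores")
        if self.group == GROUP_PATIENT and (self.madrs_pre is None or self.madrs_post is None):
            raise ValueError("patients require both madrs_pre and madrs_post")

    @property
    def madrs_change(self) -> Optional[float]:
        """Pre minus post score; positive = symptom improvement."""
        if self.madrs_pre is None or self.madrs_post is None:
            return None
        return float(self.madrs_pre) - float(self.madrs_post)


@dataclass
class Cohort:
    """A collection of subject records, optionally length-normalized."""

    records: list
    common_length: Optional[int] = None

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")
        if self.common_length is not None:
            bad = [r.subject_id for r in self.records if len(r.series) != self.common_length]
            if bad:
                raise ValueError(f"series length != common_length for {bad}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patients(self) -> Sequence[SubjectRecord]:
        return [r for r in self.records if r.group == GROUP_PATIENT]

    @property
    def controls(self) -> Sequence[SubjectRecord]:
        return [r for r in self.records if r.group == GROUP_CONTROL]
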