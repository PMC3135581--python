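"""Core data container and delimited-text I/O for right-censored
competing-risks data.

A dataset is one row per subject: an observed time ``T`` and the state
``X_T`` entered at that time — status 1 for the event of interest, status 2
for the competing event, status 0 when the subject was right-censored before
any event. An optional binary ``group`` column distinguishes control (0)
from treatment (1) arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError, ValidationError

__all__ = [
    "CompetingRisksDataset",
    "DEFAULT_DIALECT",
    "read_dataset",
    "write_dataset",
    "summarize",
]

#: default column-name mapping for CSV I/O
DEFAULT_DIALECT = {"id": "id", "time": "time", "status": "status", "group": "group"}

VALID_STATUSES = (0, 1, 2)


@dataclass(frozen=True)
class CompetingRisksDataset:
    """Validated competing-risks sample.

    Parameters
    ----------
    time
        Positive, finite observed times (time to first event or censoring).
    status
        Integer codes: 0 censored, 1 event of interest, 2 competing event.
    group
        Optional binary arm labels (0 control, 1 treatment).
    subject_id
        Opaque labels; generated as ``1..n`` when not supplied.
    """

    time: np.ndarray
    status: np.ndarray
    group: np.ndarray | None = None
    subject_id: np.ndarray | None = None

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        status = np.asarray(self.status)
        object.__setattr__(self, "time", time)
        if time.ndim != 1:
            raise ValidationError("time must be one-dimensional")
        n = time.size
        if status.shape != (n,):
            raise ValidationError("status must match time in length")
        bad = np.flatnonzero(~np.isfinite(time) | (time <= 0))
        if bad.size:
            raise ValidationError(
                f"time must be positive and finite, got {time[bad[0]]!r}", row=int(bad[0])
            )
        try:
            status_i = status.astype(np.int64)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"status must be integer-coded: {exc}") from exc
        if not np.array_equal(status_i, np.asarray(status, dtype=float)):
            raise ValidationError("status codes must be whole numbers")
        object.__setattr__(self, "status", status_i)
        bad = np.flatnonzero(~np.isin(status_i, VALID_STATUSES))
        if bad.size:
            raise ValidationError(
                f"status must be in {{0, 1, 2}}, got {status_i[bad[0]]}", row=int(bad[0])
            )
        if self.group is not None:
            group = np.asarray(self.group)
            if group.shape != (n,):
                raise ValidationError("group must match time in length")
            group_i = group.astype(np.int64)
            bad = np.flatnonzero(~np.isin(group_i, (0, 1)))
            if bad.size:
                raise ValidationError(
                    f"group must be binary 0/1, got {group_i[bad[0]]}", row=int(bad[0])
                )
            object.__setattr__(self, "group", group_i)
        if self.subject_id is None:
            object.__setattr__(self, "subject_id", np.arange(1, n + 1))
        else:
            sid = np.asarray(self.subject_id)
            if sid.shape != (n,):
                raise ValidationError("subject_id must match time in length")
            object.__setattr__(self, "subject_id", sid)

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def n(self) -> int:
        return len(self)

    def status_counts(self) -> dict[int, int]:
        """Counts by status code; always keyed by 0, 1 and 2."""
        return {s: int(np.sum(self.status == s)) for s in VALID_STATUSES}

    def subset(self, mask: np.ndarray) -> "CompetingRisksDataset":
        return CompetingRisksDataset(
            time=self.time[mask],
            status=self.status[mask],
            group=None if self.group is None else self.group[mask],
            subject_id=self.subject_id[mask],
        )

    def arm(self, label: int) -> "CompetingRisksDataset":
        """Subjects belonging to one arm of a two-arm dataset."""
        if self.group is None:
            raise ValidationError("dataset has no group column")
        return self.subset(self.group == label)

    def to_frame(self, dialect: dict[str, str] = DEFAULT_DIALECT) -> pd.DataFrame:
        cols = {
            dialect["id"]: self.subject_id,
            dialect["time"]: self.time,
            dialect["status"]: self.status,
        }
        if self.group is not None:
            cols[dialect["group"]] = self.group
        return pd.DataFrame(cols)


def _resolve(df: pd.DataFrame, dialect: dict[str, str], key: str, required: bool = True):
    name = dialect.get(key, DEFAULT_DIALECT[key])
    if name not in df.columns:
        if required:
            raise ValidationError(f"required column {name!r} (for {key!r}) not found")
        return None
    return df[name]


def read_dataset(
    path: str | Path, dialect: dict[str, str] | None = None
) -> CompetingRisksDataset:
    """Read a competing-risks dataset from a header-row CSV file.

    ``dialect`` maps the logical names ``id``/``time``/``status``/``group``
    to the file's column names; unspecified entries use the defaults.
    Row order is preserved. Validation failures name the offending row
    (0-based data row, excluding the header).
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, float_precision="round_trip")
    time_col = _resolve(df, dialect, "time")
    status_col = _resolve(df, dialect, "status")
    time = pd.to_numeric(time_col, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(np.isnan(time) & time_col.notna().to_numpy())
    if bad.size:
        raise ValidationError(
            f"non-numeric time value {time_col.iloc[bad[0]]!r}", row=int(bad[0])
        )
    if np.isnan(time).any():
        raise ValidationError("missing time value", row=int(np.flatnonzero(np.isnan(time))[0]))
    group_col = _resolve(df, dialect, "group", required=False)
    id_col = _resolve(df, dialect, "id", required=False)
    return CompetingRisksDataset(
        time=time,
        status=status_col.to_numpy(),
        group=None if group_col is None else group_col.to_numpy(),
        subject_id=None if id_col is None else id_col.to_numpy(),
    )


def write_dataset(
    data: CompetingRisksDataset,
    path: str | Path,
    dialect: dict[str, str] | None = None,
) -> None:
    """Write the dataset as RFC-4180-style CSV with a header row.

    Times are written with ``repr`` round-trip precision so that
    ``read_dataset(write_dataset(d))`` reproduces ``d`` exactly.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    data.to_frame(dialect).to_csv(path, index=False)


def summarize(data: CompetingRisksDataset) -> pd.DataFrame:
    """Counts and proportions by status, per group when present.

    Returns a tidy frame with one row per (group, status) cell; the
    ``proportion`` column is relative to the group size. Proportions within
    a group sum to 1 exactly (before any display rounding).
    """
    if len(data) == 0:
        raise EmptyDatasetError("cannot summarize an empty dataset")
    frames = []
    groups = [(None, data)] if data.group is None else [
        (g, data.arm(g)) for g in sorted(np.unique(data.group))
    ]
    labels = {0: "censored", 1: "event of interest", 2: "competing event"}
    for g, sub in groups:
        counts = sub.status_counts()
        n = len(sub)
        for s in VALID_STATUSES:
            frames.append(
                {
                    "group": g,
                    "status": s,
                    "label": labels[s],
                    "count": counts[s],
                    "proportion": counts[s] / n,
                }
            )
    out = pd.DataFrame(frames)
    if data.group is None:
        out = out.drop(columns=["group"])
    return out
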