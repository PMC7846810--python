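"""Reading, validating and writing presence recordings and tabular outputs.

The atomic observation is a *recording*: one antenna read, i.e. a timestamp,
the RFID tag of the animal that triggered the reader, and the identifier of
the box the reader is mounted on.  Recordings are held in a
:class:`RecordingSet`, a thin wrapper around a :class:`pandas.DataFrame`
with a canonical, deterministic sort order.  Duplicate identical rows are
preserved on purpose: an animal re-passing the entrance is a genuine
re-recording, and the event-pairing rules in :mod:`leadfollow.inference`
select among multiple reads.

All on-disk formats are plain UTF-8 CSV.  Timestamps are ISO-8601 local
time by default; a *dialect* may remap column names and declare
epoch-second timestamps instead.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .inference import LFEvent

__all__ = [
    "ValidationError",
    "MissingColumnError",
    "TimestampParseError",
    "EmptyInputError",
    "Dialect",
    "BoxMetadata",
    "RecordingSet",
    "read_recordings",
    "write_recordings",
    "read_events",
    "write_events",
    "read_box_metadata",
    "write_box_metadata",
]

#: Fixed schema of the event table written by :func:`write_events`.
EVENT_COLUMNS = [
    "leader_id",
    "follower_id",
    "box_id",
    "t_leader",
    "t_follower",
    "time_difference_minutes",
]


class ValidationError(ValueError):
    """Base class for input-validation failures."""


class MissingColumnError(ValidationError):
    """A required column could not be resolved through the dialect."""


class TimestampParseError(ValidationError):
    """A timestamp value could not be parsed."""


class EmptyInputError(ValidationError):
    """The input file contains no data rows."""


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping (and timestamp convention) of a recordings CSV.

    Parameters
    ----------
    timestamp, bat_id, box_id
        Names of the corresponding columns in the file.
    timestamp_format
        ``"iso"`` for ISO-8601 strings (default) or ``"epoch_s"`` for
        numeric seconds since the Unix epoch.  Both denote the same local
        wall-clock instants; no timezone arithmetic is performed (all
        loggers in a study share one local clock).
    """

    timestamp: str = "timestamp"
    bat_id: str = "bat_id"
    box_id: str = "box_id"
    timestamp_format: str = "iso"

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str] | "Dialect" | None) -> "Dialect":
        if mapping is None:
            return cls()
        if isinstance(mapping, cls):
            return mapping
        return cls(**dict(mapping))


@dataclass(frozen=True)
class BoxMetadata:
    """Per-box metadata: the day (if any) the box became an occupied roost.

    A box is *occupied* on the first day it is used as a day roost by at
    least two animals (the minimum number for a group decision).  Boxes
    that were never occupied carry ``occupation_date=None``.
    """

    box_id: str
    occupation_date: _dt.date | None = None


class RecordingSet:
    """Canonically sorted collection of presence recordings.

    Rows are sorted ascending by timestamp, ties broken by
    ``(bat_id, box_id)`` lexicographically, which makes the order total and
    deterministic irrespective of input permutation.  Duplicate rows are
    kept.
    """

    COLUMNS = ["timestamp", "bat_id", "box_id"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise MissingColumnError(f"missing columns: {missing}")
        out = df.loc[:, self.COLUMNS].copy()
        out["timestamp"] = pd.to_datetime(out["timestamp"])
        out["bat_id"] = out["bat_id"].astype(str)
        out["box_id"] = out["box_id"].astype(str)
        out = out.sort_values(self.COLUMNS, kind="mergesort").reset_index(drop=True)
        self._df = out

    @classmethod
    def from_records(
        cls, rows: Iterable[tuple[object, str, str]]
    ) -> "RecordingSet":
        """Build from an iterable of ``(timestamp, bat_id, box_id)`` tuples."""
        return cls(pd.DataFrame(list(rows), columns=cls.COLUMNS))

    @property
    def df(self) -> pd.DataFrame:
        """The underlying canonical DataFrame (do not mutate)."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RecordingSet):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_bats = self._df["bat_id"].nunique()
        n_boxes = self._df["box_id"].nunique()
        return f"RecordingSet({len(self)} reads, {n_bats} bats, {n_boxes} boxes)"

    def by_box(self) -> Iterable[tuple[str, pd.DataFrame]]:
        """Iterate ``(box_id, sub-frame)`` pairs, order preserved within box."""
        return self._df.groupby("box_id", sort=True)

    def boxes(self) -> list[str]:
        return sorted(self._df["box_id"].unique())

    def bats(self) -> list[str]:
        return sorted(self._df["bat_id"].unique())

    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Earliest and latest timestamp; raises on empty sets."""
        if len(self._df) == 0:
            raise EmptyInputError("recording set is empty")
        return self._df["timestamp"].iloc[0], self._df["timestamp"].iloc[-1]


def read_recordings(
    path: str | Path, dialect: Mapping[str, str] | Dialect | None = None
) -> RecordingSet:
    """Read a recordings CSV into a canonical :class:`RecordingSet`.

    Raises :class:`EmptyInputError`, :class:`MissingColumnError` or
    :class:`TimestampParseError` with the offending detail.  Row count is
    preserved (duplicates included).
    """
    d = Dialect.from_mapping(dialect)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: no data") from exc
    if len(raw) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    for logical, actual in (
        ("timestamp", d.timestamp),
        ("bat_id", d.bat_id),
        ("box_id", d.box_id),
    ):
        if actual not in raw.columns:
            raise MissingColumnError(
                f"{path}: column {actual!r} (for {logical}) not found"
            )
    df = pd.DataFrame(
        {
            "timestamp": raw[d.timestamp],
            "bat_id": raw[d.bat_id],
            "box_id": raw[d.box_id],
        }
    )
    if d.timestamp_format == "epoch_s":
        ts = pd.to_numeric(df["timestamp"], errors="coerce")
        if ts.isna().any():
            bad = df["timestamp"][ts.isna()].iloc[0]
            raise TimestampParseError(f"{path}: bad epoch timestamp {bad!r}")
        df["timestamp"] = pd.to_datetime(ts, unit="s")
    elif d.timestamp_format == "iso":
        ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
        if ts.isna().any():
            bad = df["timestamp"][ts.isna()].iloc[0]
            raise TimestampParseError(f"{path}: unparseable timestamp {bad!r}")
        df["timestamp"] = ts
    else:
        raise ValidationError(f"unknown timestamp_format {d.timestamp_format!r}")
    if (df["bat_id"].isna() | (df["bat_id"] == "")).any():
        raise ValidationError(f"{path}: empty bat_id")
    if (df["box_id"].isna() | (df["box_id"] == "")).any():
        raise ValidationError(f"{path}: empty box_id")
    return RecordingSet(df)


def write_recordings(
    rs: RecordingSet, path: str | Path, dialect: Mapping[str, str] | Dialect | None = None
) -> None:
    """Write a RecordingSet back to CSV (inverse of :func:`read_recordings`)."""
    d = Dialect.from_mapping(dialect)
    df = rs.df.copy()
    if d.timestamp_format == "epoch_s":
        col = (df["timestamp"].astype("int64") // 10**9).astype("int64")
    else:
        col = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out = pd.DataFrame({d.timestamp: col, d.bat_id: df["bat_id"], d.box_id: df["box_id"]})
    out.to_csv(path, index=False)


def write_events(events: Sequence["LFEvent"], path: str | Path) -> None:
    """Write inferred leading-following events as CSV.

    Column order is fixed (``leader_id, follower_id, box_id, t_leader,
    t_follower, time_difference_minutes``); an empty event list yields a
    header-only file.  :func:`read_events` is its exact inverse.
    """
    rows = [
        {
            "leader_id": e.leader_id,
            "follower_id": e.follower_id,
            "box_id": e.box_id,
            "t_leader": pd.Timestamp(e.t_leader).strftime("%Y-%m-%dT%H:%M:%S"),
            "t_follower": pd.Timestamp(e.t_follower).strftime("%Y-%m-%dT%H:%M:%S"),
            "time_difference_minutes": e.time_difference,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path: str | Path) -> list["LFEvent"]:
    """Read an event table written by :func:`write_events`."""
    from .inference import LFEvent

    df = pd.read_csv(path, dtype={"leader_id": str, "follower_id": str, "box_id": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")
    return [
        LFEvent(
            leader_id=r.leader_id,
            follower_id=r.follower_id,
            box_id=r.box_id,
            t_leader=pd.Timestamp(r.t_leader),
            t_follower=pd.Timestamp(r.t_follower),
        )
        for r in df.itertuples()
    ]


def read_box_metadata(path: str | Path) -> list[BoxMetadata]:
    """Read box metadata CSV with columns ``box_id,occupation_date``.

    ``occupation_date`` may be blank for never-occupied boxes.
    """
    df = pd.read_csv(path, dtype={"box_id": str})
    if "box_id" not in df.columns:
        raise MissingColumnError(f"{path}: missing column 'box_id'")
    out: list[BoxMetadata] = []
    for r in df.itertuples():
        occ = getattr(r, "occupation_date", None)
        if occ is None or (isinstance(occ, float) and pd.isna(occ)) or occ == "":
            date = None
        else:
            date = pd.Timestamp(occ).date()
        out.append(BoxMetadata(box_id=r.box_id, occupation_date=date))
    return out


def write_box_metadata(boxes: Sequence[BoxMetadata], path: str | Path) -> None:
    rows = [
        {
            "box_id": b.box_id,
            "occupation_date": b.occupation_date.isoformat() if b.occupation_date else "",
        }
        for b in boxes
    ]
    pd.DataFrame(rows, columns=["box_id", "occupation_date"]).to_csv(path, index=False)
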