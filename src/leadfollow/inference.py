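"""Inference of leading-following (L/F) events from presence recordings.

An individual is *naïve* with respect to a box at time t if it has never
been recorded there before t, and *experienced* if it has.  A
leading-following event is a joint visit of one experienced individual
(the leader) and one naïve individual (the follower) to a box, with the
two reads at most ``lf_delay`` minutes apart.  Three parameters govern the
inference:

``lf_delay``
    maximum allowed absolute time difference (minutes) between the
    leader's and the follower's chosen recordings;
``turnaround_time``
    minimum time (minutes) after an individual first appears at a box
    before it may act as a leader there — the time needed to find and
    lead followers.  Too-small values falsely promote recent followers to
    leaders;
``occupation_deadline``
    hour of the morning on a box's occupation day after which that box's
    recordings are discarded, because swarming (local enhancement) at an
    occupied roost produces bursts of reads not caused by
    leading-following.

When several animals arrive jointly — k experienced and m naïve — all
k×m leader/follower pairs are formed.  When a leader has several
qualifying reads, the one minimizing the absolute gap to the follower's
read is chosen (ties broken toward the earlier read).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BoxMetadata, RecordingSet

__all__ = [
    "InferenceParams",
    "LFEvent",
    "build_experience_table",
    "apply_occupation_cutoff",
    "infer_events",
    "time_differences",
    "estimate_occupation_dates",
]


@dataclass(frozen=True)
class InferenceParams:
    """The three-parameter tuple governing L/F event inference.

    ``occupation_deadline`` is an hour of day in [0, 24), or ``None`` to
    disable the occupation cutoff entirely.
    """

    lf_delay: float = 5.0
    turnaround_time: float = 3.0
    occupation_deadline: float | None = 5.0

    def __post_init__(self) -> None:
        if self.lf_delay <= 0:
            raise ValueError("lf_delay must be positive")
        if self.turnaround_time < 0:
            raise ValueError("turnaround_time must be nonnegative")
        if self.occupation_deadline is not None and not (
            0 <= self.occupation_deadline < 24
        ):
            raise ValueError("occupation_deadline must be in [0, 24) or None")


@dataclass(frozen=True)
class LFEvent:
    """One inferred leading-following event.

    The link semantics downstream are *follower → leader*: the follower
    learned the box location from the leader.
    """

    leader_id: str
    follower_id: str
    box_id: str
    t_leader: pd.Timestamp
    t_follower: pd.Timestamp

    def __post_init__(self) -> None:
        if self.leader_id == self.follower_id:
            raise ValueError("leader and follower must differ")

    @property
    def time_difference(self) -> float:
        """Absolute leader/follower recording gap in fractional minutes."""
        delta = pd.Timestamp(self.t_leader) - pd.Timestamp(self.t_follower)
        return abs(delta.total_seconds()) / 60.0


def build_experience_table(rs: RecordingSet) -> dict[tuple[str, str], pd.Timestamp]:
    """First-recording time for every (bat, box) pair present in ``rs``.

    A bat is naïve at box b at time t iff (bat, b) is absent from the
    table or its first-recording time is >= t; experienced iff it is < t.
    """
    if len(rs) == 0:
        return {}
    grp = rs.df.groupby(["bat_id", "box_id"], sort=False)["timestamp"].min()
    return {k: v for k, v in grp.items()}


def _cutoff_instant(occupation_date: _dt.date, deadline_hour: float) -> pd.Timestamp:
    return pd.Timestamp(occupation_date) + pd.Timedelta(hours=deadline_hour)


def apply_occupation_cutoff(
    rs: RecordingSet,
    boxes: Iterable[BoxMetadata],
    deadline_hour: float,
) -> RecordingSet:
    """Drop reads at occupied boxes from the occupation-day deadline onward.

    For each box with an occupation date, every recording at that box with
    timestamp >= (occupation date at ``deadline_hour``) is removed — the
    cutoff is half-open, reads strictly before the deadline are kept.
    Boxes without an occupation date pass through unfiltered.
    """
    if not (0 <= deadline_hour < 24):
        raise ValueError("deadline_hour must be in [0, 24)")
    df = rs.df
    keep = np.ones(len(df), dtype=bool)
    for b in boxes:
        if b.occupation_date is None:
            continue
        cutoff = _cutoff_instant(b.occupation_date, deadline_hour)
        keep &= ~((df["box_id"] == b.box_id) & (df["timestamp"] >= cutoff))
    return RecordingSet(df.loc[keep])


def infer_events(
    rs: RecordingSet,
    params: InferenceParams,
    boxes: Iterable[BoxMetadata] = (),
) -> list[LFEvent]:
    """Infer all leading-following events under the three-parameter model.

    Per box (after the occupation cutoff, if enabled):

    1. the follower slot of an event is always a bat's *first* read at the
       box (a repeat visitor is experienced by definition and cannot be
       "led" there again);
    2. a leader candidate is any other bat, first recorded at the box at
       time ``t_e``, with some read ``t_l`` satisfying
       ``|t_l - t_f| <= lf_delay``, ``t_l > t_e`` and
       ``t_l >= t_e + turnaround_time``;
    3. among a candidate's qualifying reads, ``t_l`` minimizes
       ``|t_l - t_f|``, ties broken toward the earlier read;
    4. one event per (leader, follower) pair — a joint arrival of k
       experienced and m naïve bats yields k×m events.

    The leader's read may precede or follow the follower's: a joint visit
    is defined by the absolute gap, not by an ordering.  The returned list
    is sorted by ``(box_id, t_follower, leader_id)``.
    """
    if params.occupation_deadline is not None:
        rs = apply_occupation_cutoff(rs, boxes, params.occupation_deadline)
    if len(rs) == 0:
        return []

    delay = pd.Timedelta(minutes=params.lf_delay)
    turnaround = pd.Timedelta(minutes=params.turnaround_time)
    events: list[LFEvent] = []

    for box_id, sub in rs.by_box():
        times = sub["timestamp"].to_numpy()
        bats = sub["bat_id"].to_numpy()
        # first read per bat at this box (sub is time-sorted)
        first_idx = pd.Series(np.arange(len(sub)), index=bats).groupby(level=0).min()
        first_time = {bat: times[i] for bat, i in first_idx.items()}
        # leader must be experienced (strictly after its own first read) and
        # past the turnaround window anchored at that first read
        min_gap = max(turnaround.to_timedelta64(), np.timedelta64(1, "ns"))
        earliest_lead = {bat: t + min_gap for bat, t in first_time.items()}
        for follower, fi in first_idx.items():
            t_f = times[fi]
            lo = np.searchsorted(times, t_f - delay.to_timedelta64(), side="left")
            hi = np.searchsorted(times, t_f + delay.to_timedelta64(), side="right")
            best: dict[str, np.datetime64] = {}
            for j in range(lo, hi):
                cand = bats[j]
                if cand == follower:
                    continue
                t_l = times[j]
                if t_l < earliest_lead[cand]:
                    continue
                prev = best.get(cand)
                if prev is None:
                    best[cand] = t_l
                    continue
                d_new, d_old = abs(t_l - t_f), abs(prev - t_f)
                if d_new < d_old or (d_new == d_old and t_l < prev):
                    best[cand] = t_l
            for leader, t_l in best.items():
                events.append(
                    LFEvent(
                        leader_id=leader,
                        follower_id=follower,
                        box_id=box_id,
                        t_leader=pd.Timestamp(t_l),
                        t_follower=pd.Timestamp(t_f),
                    )
                )
    events.sort(key=lambda e: (e.box_id, e.t_follower, e.leader_id))
    return events


def time_differences(events: Sequence[LFEvent]) -> np.ndarray:
    """Multiset of absolute leader/follower gaps (minutes), event order kept."""
    return np.array([e.time_difference for e in events], dtype=float)


def estimate_occupation_dates(
    rs: RecordingSet,
    min_bats: int = 2,
    morning_start_hour: float = 5.0,
    morning_end_hour: float = 12.0,
) -> list[BoxMetadata]:
    """Heuristically guess occupation dates from raw reads.

    Flags a box as occupied on the first date on which at least
    ``min_bats`` distinct bats are recorded there between
    ``morning_start_hour`` and ``morning_end_hour``.  This is a
    convenience heuristic only — occupation dates observed in the field
    (day-roost checks) are the authoritative input and should be preferred
    whenever available.
    """
    out: list[BoxMetadata] = []
    df = rs.df
    hours = df["timestamp"].dt.hour + df["timestamp"].dt.minute / 60.0
    morning = df[(hours >= morning_start_hour) & (hours < morning_end_hour)]
    for box_id in rs.boxes():
        sub = morning[morning["box_id"] == box_id]
        date = None
        if len(sub):
            per_day = sub.groupby(sub["timestamp"].dt.date)["bat_id"].nunique()
            hits = per_day[per_day >= min_bats]
            if len(hits):
                date = hits.index[0]
        out.append(BoxMetadata(box_id=box_id, occupation_date=date))
    return out
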