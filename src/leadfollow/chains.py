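"""Chains of leading-following events and their length distribution.

A chain of length k is a sequence of k events in which the follower of an
earlier event is the leader of a later event: information received is
passed on.  Two events A→B (A followed B) and C→A form a chain of length
two, and each also counts as a chain of length one — sub-chains are
counted separately.  Events are the nodes of an *event-chain graph* with
an arc e → e' whenever follower(e) = leader(e') and t(e) < t(e'), where
t(e) is the follower's recording time (the moment the information was
received).  Arcs strictly increase in time, so the graph is acyclic and
chains can be counted by dynamic programming over paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .inference import LFEvent

__all__ = ["ChainStats", "count_chains", "build_event_graph"]


@dataclass(frozen=True)
class ChainStats:
    """Counts and relative frequencies of chain lengths 1..max_len."""

    counts: dict[int, int]
    max_observed: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[int, float]:
        tot = self.total
        if tot == 0:
            return {}
        return {k: v / tot for k, v in self.counts.items()}


def build_event_graph(events: Sequence[LFEvent]) -> list[list[int]]:
    """Predecessor lists of the event-chain graph.

    ``preds[i]`` holds the indices j with an arc event[j] → event[i],
    i.e. follower(j) = leader(i) and t_follower(j) < t_follower(i).
    """
    n = len(events)
    preds: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        e_i = events[i]
        for j in range(n):
            if i == j:
                continue
            e_j = events[j]
            if e_j.follower_id == e_i.leader_id and e_j.t_follower < e_i.t_follower:
                preds[i].append(j)
    return preds


def count_chains(events: Sequence[LFEvent], max_len: int = 16) -> ChainStats:
    """Count every directed path of 1..max_len events in the chain graph.

    Dynamic programming over events in time order: ``P[i][k]`` is the
    number of k-event chains ending at event i, with ``P[i][1] = 1`` and
    ``P[i][k] = Σ_{j → i} P[j][k-1]``.  Sub-chains count separately, so a
    linear cascade of m events contributes m−k+1 chains of length k.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    n = len(events)
    if n == 0:
        return ChainStats(counts={}, max_observed=0)
    order = sorted(range(n), key=lambda i: (events[i].t_follower, i))
    preds = build_event_graph(events)
    # paths[i][k-1] = number of chains of k events ending at event i
    paths = np.zeros((n, max_len), dtype=np.int64)
    for i in order:
        paths[i, 0] = 1
        for j in preds[i]:
            paths[i, 1:] += paths[j, : max_len - 1]
    totals = paths.sum(axis=0)
    counts = {k + 1: int(c) for k, c in enumerate(totals) if c > 0}
    max_observed = max(counts) if counts else 0
    return ChainStats(counts=counts, max_observed=max_observed)
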