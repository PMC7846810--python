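"""Directed weighted leading-following networks and their topology.

A node is an individual; a directed link follower → leader means the
follower followed that leader to some box, and the link weight counts how
many times it did so (target boxes are disregarded — events are summed
over all boxes).  The graph container is a :class:`networkx.DiGraph` with
a ``weight`` attribute per edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .inference import LFEvent

__all__ = [
    "LFNetwork",
    "TopologySummary",
    "UndefinedDensityError",
    "build_network",
    "density",
    "components",
    "total_events",
    "write_edgelist",
    "read_edgelist",
]

#: Alias for the network container: edges run follower -> leader.
LFNetwork = nx.DiGraph


class UndefinedDensityError(ValueError):
    """Density is undefined for networks with fewer than two nodes."""


@dataclass(frozen=True)
class TopologySummary:
    """Connectedness summary of one L/F network.

    ``n_links`` counts unique ordered (follower, leader) pairs;
    ``n_events`` is the weight total, i.e. the number of underlying
    events.  ``n_scc`` counts strongly connected components of size >= 2
    (an isolated node is trivially its own SCC and carries no information
    about mutual leading-following); ``n_scc_with_singletons`` is the
    inclusive count.
    """

    n_bats: int
    n_links: int
    n_events: int
    density: float | None
    n_wcc: int
    n_scc: int
    n_scc_with_singletons: int
    largest_scc_size: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def build_network(events: Sequence[LFEvent]) -> LFNetwork:
    """Aggregate events into a directed weighted network.

    Nodes are all bats appearing in any event; the weight of edge
    follower → leader is the number of events between that ordered pair,
    regardless of box.  Order-invariant in the input.
    """
    g = nx.DiGraph()
    for e in events:
        if g.has_edge(e.follower_id, e.leader_id):
            g[e.follower_id][e.leader_id]["weight"] += 1
        else:
            g.add_edge(e.follower_id, e.leader_id, weight=1)
    return g


def density(net: LFNetwork) -> float:
    """Unique directed links divided by n(n-1) possible links."""
    n = net.number_of_nodes()
    if n < 2:
        raise UndefinedDensityError("density needs at least two nodes")
    return net.number_of_edges() / (n * (n - 1))


def total_events(net: LFNetwork) -> int:
    """Number of events the network aggregates (sum of edge weights)."""
    return int(sum(w for _, _, w in net.edges(data="weight", default=1)))


def components(net: LFNetwork) -> TopologySummary:
    """Weak/strong connectivity summary of the network."""
    n = net.number_of_nodes()
    sccs = [c for c in nx.strongly_connected_components(net)]
    nontrivial = [c for c in sccs if len(c) >= 2]
    return TopologySummary(
        n_bats=n,
        n_links=net.number_of_edges(),
        n_events=total_events(net),
        density=density(net) if n >= 2 else None,
        n_wcc=nx.number_weakly_connected_components(net),
        n_scc=len(nontrivial),
        n_scc_with_singletons=len(sccs),
        largest_scc_size=max((len(c) for c in sccs), default=0),
    )


def write_edgelist(net: LFNetwork, path: str | Path) -> None:
    """Serialize as CSV ``follower,leader,weight`` (deterministic order)."""
    rows = sorted(
        ({"follower": u, "leader": v, "weight": d["weight"]} for u, v, d in net.edges(data=True)),
        key=lambda r: (r["follower"], r["leader"]),
    )
    pd.DataFrame(rows, columns=["follower", "leader", "weight"]).to_csv(path, index=False)


def read_edgelist(path: str | Path) -> LFNetwork:
    df = pd.read_csv(path, dtype={"follower": str, "leader": str})
    g = nx.DiGraph()
    for r in df.itertuples():
        g.add_edge(r.follower, r.leader, weight=int(r.weight))
    return g
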