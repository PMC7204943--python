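"""Consensus protein-protein interaction network around a seed set.

The study universe is defined in three steps: (1) keep only proteins
reported by at least two of the source interaction databases; (2) take the
first-order subnetwork around the seed proteins (seeds, their direct
interactors, and every consensus edge among that node set, so
interactor-interactor edges are retained); (3) compute degrees and call
hubs at the 75th percentile of the degree distribution.

"75th percentile" uses the nearest-rank definition so the threshold is
always an observed degree; a node is a hub when its degree meets or exceeds
that threshold (the top quartile of the distribution).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_integration import ConfigError, InteractionEdgeRaw

logger = logging.getLogger("ptmatlas.network")

Edge = tuple[str, str]


def _undirected(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


def _as_pairs(edges: Iterable) -> list[tuple[str, str]]:
    out = []
    for e in edges:
        if isinstance(e, InteractionEdgeRaw):
            out.append((e.accession_a, e.accession_b))
        else:
            out.append((e[0], e[1]))
    return out


@dataclass
class ConsensusNetwork:
    """An undirected PPI graph restricted to multi-source proteins."""

    nodes: set[str]
    edges: set[Edge]
    node_sources: dict[str, set[str]] = field(default_factory=dict)
    degree: dict[str, int] = field(default_factory=dict)
    hub_threshold: float | None = None
    hubs: set[str] = field(default_factory=set)

    def compute_degrees(self) -> None:
        self.degree = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            self.degree[a] += 1
            self.degree[b] += 1


def consensus_nodes(
    edge_lists_by_source: Mapping[str, Iterable],
    min_sources: int = 2,
) -> dict[str, set[str]]:
    """Map each accession to the set of source databases reporting it, keeping
    only accessions supported by at least ``min_sources`` distinct sources.

    An accession counts as reported by a source if it appears as either
    endpoint of any edge in that source's list.
    """
    if len(edge_lists_by_source) < 2:
        raise ConfigError(
            f"need edge lists from >=2 sources, got {len(edge_lists_by_source)}"
        )
    support: dict[str, set[str]] = {}
    for source, edges in edge_lists_by_source.items():
        for a, b in _as_pairs(edges):
            support.setdefault(a, set()).add(source)
            support.setdefault(b, set()).add(source)
    return {acc: srcs for acc, srcs in support.items() if len(srcs) >= min_sources}


def consensus_edges(
    edge_lists_by_source: Mapping[str, Iterable],
    nodes: Mapping[str, set[str]] | set[str],
) -> tuple[set[Edge], dict[Edge, set[str]]]:
    """Collapse per-source edge lists into undirected edges among consensus
    nodes, recording per-edge source support.  Self-loops are dropped."""
    keep = set(nodes)
    edges: dict[Edge, set[str]] = {}
    for source, raw in edge_lists_by_source.items():
        for a, b in _as_pairs(raw):
            if a == b or a not in keep or b not in keep:
                continue
            edges.setdefault(_undirected(a, b), set()).add(source)
    return set(edges), edges


def first_order_subnetwork(
    seeds: Iterable[str],
    edges: Iterable,
    node_sources: Mapping[str, set[str]] | None = None,
) -> ConsensusNetwork:
    """First-order subnetwork: seeds plus their direct interactors, with every
    edge whose endpoints both lie in that node set (seed-interactor and
    interactor-interactor alike).

    Self-loops are removed and duplicate A-B / B-A edges collapse to one
    undirected edge.  A seed absent from the edge data is kept as an isolated
    node with a warning.
    """
    seeds = set(seeds)
    undirected = {
        _undirected(a, b) for a, b in _as_pairs(edges) if a != b
    }
    neighbours: set[str] = set()
    for a, b in undirected:
        if a in seeds:
            neighbours.add(b)
        if b in seeds:
            neighbours.add(a)
    nodes = seeds | neighbours
    sub_edges = {(a, b) for a, b in undirected if a in nodes and b in nodes}
    touched = {x for e in sub_edges for x in e}
    for seed in sorted(seeds - touched):
        logger.warning("seed %s absent from edge data; kept as isolated node", seed)
    net = ConsensusNetwork(
        nodes=nodes,
        edges=sub_edges,
        node_sources={n: set(node_sources.get(n, set())) for n in nodes}
        if node_sources
        else {},
    )
    net.compute_degrees()
    return net


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile: the value at rank ceil(p/100 * n) of the
    ascending multiset."""
    if not values:
        raise ValueError("empty value list")
    ordered = sorted(values)
    rank = max(1, math.ceil(percentile / 100.0 * len(ordered)))
    return ordered[rank - 1]


def call_hubs(network: ConsensusNetwork, percentile: float = 75.0) -> tuple[float, set[str]]:
    """Call hub proteins at the given degree percentile (default 75th).

    Sets ``hub_threshold`` and ``hubs`` on the network and returns them.
    Every node with degree >= threshold is a hub, so the hub set is never
    empty (the maximum degree always qualifies).
    """
    if not network.nodes:
        raise ValueError("cannot call hubs on an empty network")
    if not network.degree:
        network.compute_degrees()
    threshold = nearest_rank_percentile(list(network.degree.values()), percentile)
    hubs = {n for n, d in network.degree.items() if d >= threshold}
    network.hub_threshold = threshold
    network.hubs = hubs
    return threshold, hubs


def build_consensus_network(
    edge_lists_by_source: Mapping[str, Iterable],
    seeds: Iterable[str],
    percentile: float = 75.0,
    min_sources: int = 2,
) -> ConsensusNetwork:
    """Run the full chain: consensus node filter, first-order subnetwork,
    degrees, hub calling."""
    sources = consensus_nodes(edge_lists_by_source, min_sources=min_sources)
    # seeds always participate in their own subnetwork
    seeds = set(seeds)
    edge_set, _ = consensus_edges(edge_lists_by_source, set(sources) | seeds)
    net = first_order_subnetwork(seeds, edge_set, node_sources=sources)
    call_hubs(net, percentile)
    return net
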