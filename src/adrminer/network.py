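"""Thresholded ADR-ADR co-occurrence networks and centrality analysis.

Two ADRs are connected by an edge when they co-occur in the profiles of at
least a configurable fraction (default 50%) of the drugs; the edge weight is
the number of drugs sharing the pair. Degree centrality (neighbor count) and
eigenvector centrality (principal eigenvector of the unweighted adjacency
matrix, unit Euclidean norm, computed on the largest connected component)
identify the hub ADRs, and two networks can be ranked and compared to find
ADRs central in one corpus but absent from the other.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

from .errors import EmptyInputError

logger = logging.getLogger(__name__)

_DENSE_EIG_LIMIT = 500
_POWER_TOL = 1e-10


@dataclass(frozen=True)
class DrugAdrTable:
    """Per-drug ADR profiles: drug name -> set of normalized term ids."""

    profiles: Mapping[str, frozenset[str]]

    def __post_init__(self):
        object.__setattr__(
            self,
            "profiles",
            {d: frozenset(adrs) for d, adrs in self.profiles.items()},
        )

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(sorted(self.profiles))

    def support(self, term_id: str) -> int:
        """Number of drugs whose profile contains ``term_id``."""
        return sum(1 for adrs in self.profiles.values() if term_id in adrs)


@dataclass
class AdrNetwork:
    """Undirected weighted ADR co-occurrence graph above a count threshold."""

    graph: nx.Graph
    threshold_fraction: float
    min_count: int

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> dict[tuple[str, str], int]:
        return {
            (min(a, b), max(a, b)): d["weight"] for a, b, d in self.graph.edges(data=True)
        }


@dataclass(frozen=True)
class CentralityTable:
    """Per-node degree and eigenvector centrality."""

    degree: Mapping[str, int] = field(default_factory=dict)
    eigenvector: Mapping[str, float] = field(default_factory=dict)


def min_edge_count(n_drugs: int, fraction: float) -> int:
    """Smallest drug count meeting ``fraction`` of ``n_drugs`` (ceiling)."""
    if n_drugs < 1:
        raise ValueError("n_drugs must be positive")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return math.ceil(fraction * n_drugs)


def build_cooccurrence_network(table: DrugAdrTable, fraction: float = 0.5) -> AdrNetwork:
    """Connect ADR pairs co-occurring in >= fraction of the table's drugs.

    ADRs left with no qualifying edge are excluded from the node set.
    """
    if not table.profiles:
        raise EmptyInputError("empty drug-ADR table")
    threshold = min_edge_count(len(table.profiles), fraction)
    pair_counts: dict[tuple[str, str], int] = {}
    for adrs in table.profiles.values():
        ordered = sorted(adrs)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    g = nx.Graph()
    for (a, b), count in sorted(pair_counts.items()):
        if count >= threshold:
            g.add_edge(a, b, weight=count)
    for a, b, d in g.edges(data=True):
        assert d["weight"] <= min(table.support(a), table.support(b))
    return AdrNetwork(graph=g, threshold_fraction=fraction, min_count=threshold)


def degree_centrality(net: AdrNetwork) -> CentralityTable:
    """Neighbor count per node."""
    return CentralityTable(degree={n: d for n, d in net.graph.degree()})


def _principal_eigenvector(adj: np.ndarray) -> np.ndarray:
    """Nonnegative unit-norm principal eigenvector of a symmetric 0/1 matrix."""
    n = adj.shape[0]
    if n <= _DENSE_EIG_LIMIT:
        vals, vecs = np.linalg.eigh(adj)
        v = vecs[:, -1]
    else:
        rng_free = np.full(n, 1.0 / math.sqrt(n))
        v = rng_free
        for _ in range(10_000):
            w = adj @ v
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            if np.linalg.norm(w - v) < _POWER_TOL:
                v = w
                break
            v = w
    # Perron vector of a connected graph is strictly positive up to sign.
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    norm = np.linalg.norm(v)
    return v / norm if norm else v


def eigenvector_centrality(net: AdrNetwork) -> CentralityTable:
    """Eigenvector centrality on the largest connected component.

    Nodes outside the largest component get 0 (power iteration is
    ill-defined across components); the vector has unit Euclidean norm over
    the component it is computed on.
    """
    if net.graph.number_of_nodes() == 0:
        return CentralityTable()
    components = sorted(nx.connected_components(net.graph), key=lambda c: (-len(c), sorted(c)))
    largest = sorted(components[0])
    if len(components) > 1:
        logger.warning(
            "eigenvector centrality computed on largest component (%d nodes); "
            "%d other component(s) set to 0",
            len(largest),
            len(components) - 1,
        )
    adj = nx.to_numpy_array(net.graph, nodelist=largest, weight=None)
    v = _principal_eigenvector(adj)
    eig = {n: 0.0 for n in net.graph.nodes}
    eig.update({n: float(x) for n, x in zip(largest, v)})
    return CentralityTable(eigenvector=eig)


def centrality(net: AdrNetwork) -> CentralityTable:
    """Degree and eigenvector centrality in one table."""
    return CentralityTable(
        degree=degree_centrality(net).degree,
        eigenvector=eigenvector_centrality(net).eigenvector,
    )


def rank_nodes(net: AdrNetwork) -> list[str]:
    """Nodes ranked by (eigenvector desc, degree desc, term id asc)."""
    table = centrality(net)
    return sorted(
        net.graph.nodes,
        key=lambda n: (-table.eigenvector[n], -table.degree[n], n),
    )


def rankings_consistent(net: AdrNetwork) -> bool:
    """Diagnostic: does the eigenvector ranking also order degrees?"""
    table = centrality(net)
    degrees = [table.degree[n] for n in rank_nodes(net)]
    return all(a >= b for a, b in zip(degrees, degrees[1:]))


@dataclass(frozen=True)
class NetworkComparison:
    ranking_a: tuple[str, ...]
    ranking_b: tuple[str, ...]
    only_in_a: frozenset[str]
    only_in_b: frozenset[str]


def rank_and_compare(net_a: AdrNetwork, net_b: AdrNetwork) -> NetworkComparison:
    """Rank both networks and report nodes present in one but not the other."""
    return NetworkComparison(
        ranking_a=tuple(rank_nodes(net_a)),
        ranking_b=tuple(rank_nodes(net_b)),
        only_in_a=net_a.nodes - net_b.nodes,
        only_in_b=net_b.nodes - net_a.nodes,
    )


def write_edge_list(net: AdrNetwork, path) -> None:
    """Weighted edge list as TSV (term_a, term_b, weight)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_a\tterm_b\tweight\n")
        for (a, b), w in sorted(net.edges.items()):
            fh.write(f"{a}\t{b}\t{w}\n")


def write_centrality(net: AdrNetwork, path, names: Mapping[str, str] | None = None) -> None:
    """Centrality table as TSV sorted by rank."""
    table = centrality(net)
    names = names or {}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tname\tdegree\teigenvector\n")
        for n in rank_nodes(net):
            fh.write(
                f"{n}\t{names.get(n, n)}\t{table.degree[n]}\t{table.eigenvector[n]:.6f}\n"
            )


def write_graphml(net: AdrNetwork, path) -> None:
    nx.write_graphml(net.graph, str(path))
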