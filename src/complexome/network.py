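"""Bipartite complex–protein network and its weighted one-mode projections.

A complex is linked to a protein if the protein is one of its components.
The protein-mode projection links two proteins with weight equal to the
number of complexes they share; the complex-mode projection links two
complexes with weight equal to the number of proteins they share. The
strength of a node is the sum of the weights on its incident links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms import bipartite as nx_bipartite

from .datatypes import ComplexomeDataset, Role

logger = logging.getLogger(__name__)

ROLE_FILTERS = {
    "all": frozenset({Role.CORE, Role.ATTACHMENT}),
    "core_only": frozenset({Role.CORE}),
    "attachment_only": frozenset({Role.ATTACHMENT}),
}

# Node namespacing: a protein and a complex may share an id string, so
# bipartite nodes carry a ("complex"|"protein", id) tag internally.
COMPLEX_SIDE = "complex"
PROTEIN_SIDE = "protein"


@dataclass
class BipartiteGraph:
    """Complex–protein bipartite graph under a role filter."""

    graph: nx.Graph
    role_filter: str
    dropped_complexes: tuple[str, ...] = ()
    dropped_proteins: tuple[str, ...] = ()

    @property
    def complex_nodes(self) -> tuple[str, ...]:
        return tuple(sorted(n[1] for n in self.graph.nodes if n[0] == COMPLEX_SIDE))

    @property
    def protein_nodes(self) -> tuple[str, ...]:
        return tuple(sorted(n[1] for n in self.graph.nodes if n[0] == PROTEIN_SIDE))

    def degree_of(self, side: str, node_id: str) -> int:
        return self.graph.degree[(side, node_id)]


@dataclass
class WeightedProjection:
    """One-mode projection with integer shared-partner weights."""

    graph: nx.Graph
    mode: str  # "protein" or "complex"

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    def weight(self, u: str, v: str) -> int:
        """Shared-partner count of the pair; 0 if not linked."""
        if self.graph.has_edge(u, v):
            return self.graph.edges[u, v]["weight"]
        return 0


@dataclass
class DegreeSummary:
    """Per-node degrees with mean/SD/max and the cumulative distribution."""

    degrees: dict[str, int]
    mean: float
    sd: float
    max: int
    cumulative: dict[int, float] = field(default_factory=dict)

    def as_table(self) -> list[tuple[int, float]]:
        """(k, P(k)) rows, ascending k."""
        return sorted(self.cumulative.items())


def build_bipartite(dataset: ComplexomeDataset, role_filter: str = "all") -> BipartiteGraph:
    """Build the complex–protein bipartite graph.

    Under ``core_only`` / ``attachment_only`` filters, nodes left with no
    edges are dropped from the graph (but reported), so that averages are
    taken over participating nodes only.
    """
    if role_filter not in ROLE_FILTERS:
        raise ValueError(f"unknown role_filter {role_filter!r}")
    roles = ROLE_FILTERS[role_filter]
    g = nx.Graph()
    for m in dataset.memberships:
        if m.role in roles:
            g.add_node((COMPLEX_SIDE, m.complex_id), bipartite=0)
            g.add_node((PROTEIN_SIDE, m.protein_id), bipartite=1)
            g.add_edge((COMPLEX_SIDE, m.complex_id), (PROTEIN_SIDE, m.protein_id))
    present_c = {n[1] for n in g.nodes if n[0] == COMPLEX_SIDE}
    present_p = {n[1] for n in g.nodes if n[0] == PROTEIN_SIDE}
    dropped_c = tuple(sorted(set(dataset.complexes) - present_c))
    dropped_p = tuple(sorted(set(dataset.proteins) - present_p))
    if dropped_c or dropped_p:
        logger.info(
            "role_filter=%s dropped %d complex(es) and %d protein(s) with no edges",
            role_filter,
            len(dropped_c),
            len(dropped_p),
        )
    return BipartiteGraph(
        graph=g,
        role_filter=role_filter,
        dropped_complexes=dropped_c,
        dropped_proteins=dropped_p,
    )


def project(graph: BipartiteGraph, mode: str) -> WeightedProjection:
    """One-mode projection with shared-partner counts as weights."""
    if mode not in (PROTEIN_SIDE, COMPLEX_SIDE):
        raise ValueError(f"unknown projection mode {mode!r}")
    keep = [n for n in graph.graph.nodes if n[0] == mode]
    proj = nx_bipartite.weighted_projected_graph(graph.graph, keep)
    out = nx.Graph()
    out.add_nodes_from(n[1] for n in keep)
    for (su, u), (sv, v), data in proj.edges(data=True):
        out.add_edge(u, v, weight=int(data["weight"]))
    return WeightedProjection(graph=out, mode=mode)


def strength(projection: WeightedProjection, node: str) -> int:
    """Sum of incident link weights s_i = Σ_{j∈V_i} w_ij; 0 if isolated."""
    if node not in projection.graph:
        raise KeyError(f"node {node!r} not in projection")
    return int(sum(d["weight"] for _, _, d in projection.graph.edges(node, data=True)))


def strengths(projection: WeightedProjection) -> dict[str, int]:
    """Strength of every node in the projection."""
    return {n: strength(projection, n) for n in projection.graph.nodes}


def _summarize(degree_map: dict[str, int]) -> DegreeSummary:
    values = np.array(sorted(degree_map.values()), dtype=float)
    n = len(values)
    cumulative: dict[int, float] = {}
    for k in sorted(set(int(v) for v in values)):
        cumulative[k] = float(np.sum(values >= k)) / n
    return DegreeSummary(
        degrees=dict(degree_map),
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        max=int(values.max()),
        cumulative=cumulative,
    )


def degree_summary(
    graph: BipartiteGraph | WeightedProjection, side: str = "n/a"
) -> DegreeSummary:
    """Degree statistics for one side of a bipartite graph, or a projection.

    ``side`` must be ``complex`` or ``protein`` for a bipartite graph and
    is ignored (``n/a``) for projections. The cumulative distribution
    P(k) = Σ_{k'≥k} p(k') is computed on the observed degrees, so
    P(k_min) = 1.
    """
    if isinstance(graph, BipartiteGraph):
        if side not in (COMPLEX_SIDE, PROTEIN_SIDE):
            raise ValueError("side must be 'complex' or 'protein' for bipartite graphs")
        degs = {
            n[1]: graph.graph.degree[n] for n in graph.graph.nodes if n[0] == side
        }
    else:
        degs = {n: graph.graph.degree[n] for n in graph.graph.nodes}
    if not degs:
        raise ValueError("empty node set for degree summary")
    return _summarize(degs)


def connected_components(projection: WeightedProjection) -> list[set[str]]:
    """Components of a projection, largest first (ties by min node id)."""
    comps = [set(c) for c in nx.connected_components(projection.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def top_nodes(metric: dict[str, int | float], n: int = 10) -> list[tuple[str, int | float]]:
    """Top-``n`` nodes by a degree or strength map, ties broken lexically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(metric.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def write_edgelist(projection: WeightedProjection, path) -> None:
    """Write a weighted edge list: ``u<TAB>v<TAB>weight``."""
    lines = [
        f"{min(u, v)}\t{max(u, v)}\t{d['weight']}"
        for u, v, d in projection.graph.edges(data=True)
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(sorted(lines)) + ("\n" if lines else ""))


def write_graphml(graph: BipartiteGraph | WeightedProjection, path) -> None:
    """GraphML export (bipartite node tags flattened to strings)."""
    g = graph.graph
    if isinstance(graph, BipartiteGraph):
        g = nx.relabel_nodes(g, {n: f"{n[0]}:{n[1]}" for n in g.nodes}, copy=True)
    nx.write_graphml(g, path)
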