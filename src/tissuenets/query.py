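"""Subnetwork extraction and coordinated multi-tissue views.

Users typically look at a handful of query genes plus the genes most
strongly connected to them, at a chosen confidence level.  When several
tissues are queried at once, the per-tissue subnetworks share one
deterministic node ordering ("coordinated views") so that a gene common to
several tissues occupies the same position in every view — the layout-free
core of side-by-side network comparison.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .exceptions import DomainError, EmptyQueryError, LabelCollisionError
from .io import Network, canonical_pair, normalize_gene

__all__ = [
    "Subnetwork",
    "CoordinatedViews",
    "filter_by_confidence",
    "query_subnetwork",
    "coordinate_views",
    "views_to_json",
    "subnetwork_to_network",
]


@dataclass
class Subnetwork:
    """A query-centred slice of one tissue network."""

    tissue: str
    query_genes: set[str]
    nodes: list[str]
    edges: dict[tuple[str, str], float]
    threshold: float

    def __post_init__(self):
        node_set = set(self.nodes)
        for (a, b), w in self.edges.items():
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a}, {b}) outside subnetwork nodes")
            if w < self.threshold:
                raise ValueError(f"edge ({a}, {b}) below threshold {self.threshold}")


@dataclass
class CoordinatedViews:
    """Per-tissue subnetworks sharing one node ordering."""

    views: dict[str, Subnetwork]
    union_order: list[str]
    shared: set[str] = field(default_factory=set)


def filter_by_confidence(network: Network, threshold: float) -> Network:
    """Keep edges with weight >= threshold (inclusive); nodes are retained
    even when they become isolated."""
    if not (0.0 <= threshold <= 1.0):
        raise DomainError(f"threshold {threshold} outside [0, 1]")
    edges = {p: w for p, w in network.edges.items() if w >= threshold}
    return Network(tissue=network.tissue, nodes=set(network.nodes), edges=edges)


def query_subnetwork(
    network: Network,
    query_genes,
    max_genes: int,
    threshold: float = 0.0,
) -> Subnetwork:
    """Query genes plus their most strongly connected neighbours.

    Non-query genes are ranked by connectivity to the query — the sum of
    edge weights (at or above ``threshold``) to query genes — and added
    greedily, ties broken lexicographically, until ``max_genes`` nodes are
    reached.  Only genes actually connected to the query are eligible.  The
    returned edges are all pairs among the selected nodes with weight >=
    ``threshold``.
    """
    query = {normalize_gene(g) for g in query_genes}
    present = sorted(query & network.nodes)
    if not present:
        raise EmptyQueryError(query)
    if max_genes < len(present):
        raise DomainError(
            f"max_genes={max_genes} smaller than the {len(present)} query "
            "genes present in the network"
        )

    present_set = set(present)
    connectivity: dict[str, float] = defaultdict(float)
    for (a, b), w in network.edges.items():
        if w < threshold:
            continue
        if a in present_set and b not in present_set:
            connectivity[b] += w
        elif b in present_set and a not in present_set:
            connectivity[a] += w

    ranked = sorted(connectivity, key=lambda g: (-connectivity[g], g))
    selected = ranked[: max_genes - len(present)]
    nodes = present + selected
    node_set = set(nodes)
    edges = {
        (a, b): w
        for (a, b), w in network.edges.items()
        if w >= threshold and a in node_set and b in node_set
    }
    return Subnetwork(
        tissue=network.tissue,
        query_genes=query,
        nodes=nodes,
        edges=edges,
        threshold=threshold,
    )


def coordinate_views(subnetworks: list[Subnetwork]) -> CoordinatedViews:
    """Align several per-tissue subnetworks on one node ordering.

    Shared genes (present in >= 2 views) come first, sorted by the number
    of views containing them (descending) then lexicographically; genes
    unique to one view follow lexicographically.  Each view's node list is
    rewritten as the restriction of this union order, so a shared gene has
    the same union index everywhere.
    """
    if not subnetworks:
        raise ValueError("need at least one subnetwork")
    tissues = [s.tissue for s in subnetworks]
    dupes = [t for t, c in Counter(tissues).items() if c > 1]
    if dupes:
        raise LabelCollisionError(f"duplicate tissue labels: {', '.join(sorted(dupes))}")

    counts: Counter[str] = Counter()
    for s in subnetworks:
        counts.update(set(s.nodes))
    shared = {g for g, c in counts.items() if c >= 2}
    unique = sorted(g for g in counts if g not in shared)
    union_order = sorted(shared, key=lambda g: (-counts[g], g)) + unique

    index = {g: i for i, g in enumerate(union_order)}
    views: dict[str, Subnetwork] = {}
    for s in subnetworks:
        ordered = sorted(s.nodes, key=index.__getitem__)
        views[s.tissue] = Subnetwork(
            tissue=s.tissue,
            query_genes=set(s.query_genes),
            nodes=ordered,
            edges=dict(s.edges),
            threshold=s.threshold,
        )
    return CoordinatedViews(views=views, union_order=union_order, shared=shared)


def subnetwork_to_network(sub: Subnetwork) -> Network:
    """View a Subnetwork as a plain Network (e.g. for edge-list export)."""
    return Network(tissue=sub.tissue, nodes=set(sub.nodes), edges=dict(sub.edges))


def views_to_json(cv: CoordinatedViews) -> str:
    """Renderer-friendly JSON: nodes with union indices and shared flags,
    edges with weights, one block per tissue view."""
    index = {g: i for i, g in enumerate(cv.union_order)}
    doc = {
        "union_order": cv.union_order,
        "shared": sorted(cv.shared),
        "views": {
            tissue: {
                "query_genes": sorted(v.query_genes),
                "threshold": v.threshold,
                "nodes": [
                    {"gene": g, "union_index": index[g], "shared": g in cv.shared}
                    for g in v.nodes
                ],
                "edges": [
                    {"source": a, "target": b, "weight": w}
                    for (a, b), w in sorted(v.edges.items())
                ],
            }
            for tissue, v in sorted(cv.views.items())
        },
    }
    return json.dumps(doc, indent=1, sort_keys=True)
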