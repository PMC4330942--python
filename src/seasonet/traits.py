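"""Trait-centered views of the correlation network.

A trait subgraph is the induced neighborhood of a physiological-trait node
(germination % or survival %): the trait, every node it is directly
correlated with, the signed trait edges, and the edges among the
neighbors.  Sign summaries count positive and negative trait associations,
optionally grouped by compound class; the overlap helper quantifies edges
shared between two state networks (e.g. germination vs dehydration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


@dataclass
class TraitSubgraph:
    """Neighborhood of one trait node, with signed edges and degrees."""

    trait: str
    graph: nx.Graph                  # induced subgraph on {trait} | neighbors
    neighbors: list

    @property
    def trait_edges(self) -> list[tuple]:
        """(neighbor, rho, sign, compound_class) for every edge at the trait."""
        out = []
        for v in self.neighbors:
            d = self.graph.edges[self.trait, v]
            out.append((v, d.get("rho"), d.get("sign", 1),
                        self.graph.nodes[v].get("compound_class", "other")))
        return out


def trait_subgraph(g: nx.Graph, trait: str) -> TraitSubgraph:
    """Induced subgraph on a trait node and its adjacent nodes.

    Node degrees within the subgraph are annotated (attribute ``degree``)
    so downstream rendering can size nodes by connectivity.  A trait with
    no significant correlations yields a singleton subgraph.
    """
    if trait not in g:
        raise KeyError(f"trait node {trait!r} not present in the network")
    neighbors = sorted(g.neighbors(trait), key=str)
    sub = g.subgraph([trait] + neighbors).copy()
    for v, deg in sub.degree():
        sub.nodes[v]["degree"] = int(deg)
    return TraitSubgraph(trait, sub, neighbors)


def sign_summary(sub: TraitSubgraph, by_class: bool = True) -> pd.DataFrame:
    """Count positive / negative trait edges, optionally per compound class.

    Row totals equal the trait's degree in the parent network.  An empty
    neighborhood yields an all-zero single-row table.
    """
    rows: dict[str, list[int]] = {}
    for _, _, sign, cls in sub.trait_edges:
        key = cls if by_class else "all"
        counts = rows.setdefault(key, [0, 0])
        counts[0 if sign >= 0 else 1] += 1
    if not rows:
        rows = {"all": [0, 0]}
    df = pd.DataFrame(
        [(k, pos, neg) for k, (pos, neg) in sorted(rows.items())],
        columns=["compound_class" if by_class else "group",
                 "n_positive", "n_negative"],
    )
    return df


@dataclass
class NetworkOverlap:
    """Edge commonality between two networks over a shared node namespace."""

    edges_a: set
    edges_b: set
    shared: set
    jaccard: float
    sign_mismatches: set = field(default_factory=set)


def _edge_key(u, v) -> tuple:
    return (u, v) if str(u) <= str(v) else (v, u)


def network_overlap(net_a: nx.Graph, net_b: nx.Graph) -> NetworkOverlap:
    """Shared edges (as unordered node pairs) and Jaccard index of edge sets.

    Edges present in both networks but with opposite correlation signs are
    flagged in ``sign_mismatches`` rather than dropped.
    """
    edges_a = {_edge_key(u, v) for u, v in net_a.edges()}
    edges_b = {_edge_key(u, v) for u, v in net_b.edges()}
    shared = edges_a & edges_b
    union = edges_a | edges_b
    jaccard = len(shared) / len(union) if union else 1.0
    mismatches = set()
    for u, v in shared:
        sa = net_a.edges[u, v].get("sign", 1)
        sb = net_b.edges[u, v].get("sign", 1)
        if sa != sb:
            mismatches.add((u, v))
    return NetworkOverlap(edges_a, edges_b, shared, jaccard, mismatches)
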