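"""Signed correlation-network construction and threshold selection.

Edges connect node pairs whose rank correlation passes a dual threshold:
absolute coefficient strictly above ``r_thresh`` and p-value at or below a
cutoff derived from a target FDR level.  The coefficient threshold itself
is chosen by scanning a grid of (r, p) pairs and picking the smallest r at
which four global network properties (average degree, transitivity,
density, diameter) are stable across the p grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .correlate import CorrelationStats, p_threshold_for_q

logger = logging.getLogger(__name__)

PROPERTY_NAMES = ("avg_degree", "clustering", "density", "diameter")


def build_network(cstats: CorrelationStats, r_thresh: float = 0.5,
                  p_thresh: float = 0.05,
                  node_kinds: dict[str, str] | None = None,
                  compound_classes: dict[str, str] | None = None) -> nx.Graph:
    """Build the signed correlation graph under dual thresholds.

    An edge (i, j) exists iff |rho_ij| > r_thresh and p_ij <= p_thresh.
    Isolated nodes are retained so the node set always matches the input
    labels.  Edge attributes: ``weight`` = |rho|, ``sign`` in {+1, -1},
    plus the raw rho, p and q values.
    """
    if not (0 <= r_thresh <= 1):
        raise ValueError("r_thresh must lie in [0, 1]")
    if not (0 <= p_thresh <= 1):
        raise ValueError("p_thresh must lie in [0, 1]")
    node_kinds = node_kinds or {}
    compound_classes = compound_classes or {}
    g = nx.Graph(r_thresh=r_thresh, p_thresh=p_thresh)
    for name in cstats.labels:
        g.add_node(name, kind=node_kinds.get(name, "metabolite"),
                   compound_class=compound_classes.get(name, "other"))
    k = len(cstats.labels)
    for i in range(k):
        for j in range(i + 1, k):
            r, p = cstats.rho[i, j], cstats.pval[i, j]
            if np.isnan(r) or np.isnan(p):
                continue
            if abs(r) > r_thresh and p <= p_thresh:
                g.add_edge(cstats.labels[i], cstats.labels[j],
                           weight=abs(r), sign=1 if r >= 0 else -1,
                           rho=float(r), p=float(p), q=float(cstats.qval[i, j]))
    return g


def network_properties(g: nx.Graph) -> dict[str, float]:
    """Four global summaries: average degree, transitivity, density, diameter.

    Clustering is the global transitivity (3 * triangles / connected
    triples), which avoids per-node 0/0 conventions on sparse graphs.  The
    diameter is the longest shortest path (in hops) within the largest
    connected component; an edgeless graph has diameter 0.
    """
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("network_properties needs at least one node")
    e = g.number_of_edges()
    avg_degree = 2.0 * e / n
    if n < 2:
        warnings.warn("density undefined for a single node; reporting 0",
                      UserWarning, stacklevel=2)
        density = 0.0
    else:
        density = nx.density(g)
    clustering = nx.transitivity(g)
    if e == 0:
        diameter = 0.0
    else:
        comp = max(nx.connected_components(g), key=len)
        diameter = float(nx.diameter(g.subgraph(comp)))
    return {"avg_degree": avg_degree, "clustering": clustering,
            "density": density, "diameter": diameter}


@dataclass
class PropertyScan:
    """Network-property surfaces over an (r, p) threshold grid."""

    r_grid: np.ndarray
    p_grid: np.ndarray
    #: DataFrame indexed by (r, p) with one column per property.
    properties: pd.DataFrame
    stability_scores: pd.Series  # per r: worst normalized range across p
    chosen_r: float
    stability_tol: float
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        return self.properties.reset_index()


def _stability_score(surface: pd.DataFrame, eps: float = 1e-9) -> float:
    """Worst-case normalized range of the four properties across the p grid.

    For each property the score is (max - min) / max(|median|, eps); 0 means
    the property does not move at all as p varies.
    """
    scores = []
    for name in PROPERTY_NAMES:
        vals = surface[name].to_numpy(dtype=float)
        rng = float(np.max(vals) - np.min(vals))
        scale = max(abs(float(np.median(vals))), eps)
        scores.append(rng / scale if rng > 0 else 0.0)
    return max(scores)


def robustness_scan(cstats: CorrelationStats,
                    r_grid=None, p_grid=None,
                    stability_tol: float = 0.1) -> PropertyScan:
    """Choose the correlation threshold by property robustness across p.

    For every candidate r the four properties are computed at each p in
    *p_grid*; r is deemed stable when the worst normalized range across p
    is at most *stability_tol*.  The smallest stable r is selected.  When
    no r qualifies, the r minimizing the score is returned with a warning.

    Default grids: r from 0.30 to 0.95 in steps of 0.05; p from the BH
    thresholds corresponding to q targets 0.01 .. 0.10.
    """
    if stability_tol <= 0:
        raise ValueError("stability_tol must be positive")
    if r_grid is None:
        r_grid = np.round(np.arange(0.30, 0.951, 0.05), 10)
    r_grid = np.asarray(r_grid, dtype=float)
    if p_grid is None:
        pvals = cstats.upper_triangle_pvalues()
        p_grid = sorted({p_threshold_for_q(pvals, q) for q in np.arange(0.01, 0.101, 0.01)})
        p_grid = [p for p in p_grid if p > 0] or [0.0]
    p_grid = np.asarray(sorted(p_grid), dtype=float)
    if r_grid.size == 0 or p_grid.size == 0:
        raise ValueError("threshold grids must be nonempty")
    if np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be strictly ascending")

    rows = []
    for r in r_grid:
        for p in p_grid:
            props = network_properties(build_network(cstats, r, p))
            rows.append({"r": r, "p": p, **props})
    surface = pd.DataFrame(rows).set_index(["r", "p"])

    scores = pd.Series(
        {r: _stability_score(surface.loc[r]) for r in r_grid}, name="stability"
    )
    stable = scores.index[scores <= stability_tol]
    if len(stable):
        chosen, converged = float(stable[0]), True
    else:
        chosen, converged = float(scores.idxmin()), False
        warnings.warn(
            f"no r in the grid meets stability tolerance {stability_tol}; "
            f"falling back to argmin r={chosen:.2f}", UserWarning, stacklevel=2)
    logger.info("robustness scan chose r=%.2f (stable=%s)", chosen, converged)
    return PropertyScan(r_grid, p_grid, surface, scores, chosen, stability_tol, converged)


# ---------------------------------------------------------------------------
# Export


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    """GraphML with degree annotated per node (used for node sizing)."""
    h = g.copy()
    for v, d in h.degree():
        h.nodes[v]["degree"] = int(d)
    nx.write_graphml(h, str(path))


def write_sif(g: nx.Graph, path: str | Path,
              edge_attr_path: str | Path | None = None,
              node_attr_path: str | Path | None = None) -> None:
    """Cytoscape-readable SIF plus optional edge/node attribute tables."""
    lines = []
    for u, v, d in sorted(g.edges(data=True)):
        rel = "pos" if d.get("sign", 1) >= 0 else "neg"
        lines.append(f"{u}\t{rel}\t{v}")
    for v in sorted(g.nodes):
        if g.degree(v) == 0:
            lines.append(str(v))
    Path(path).write_text("\n".join(lines) + "\n")
    if edge_attr_path is not None:
        rows = [{"node_i": u, "node_j": v, **{k: d[k] for k in ("rho", "p", "q", "sign")}}
                for u, v, d in sorted(g.edges(data=True))]
        pd.DataFrame(rows).to_csv(edge_attr_path, index=False)
    if node_attr_path is not None:
        rows = [{"node": v, "kind": d.get("kind", "metabolite"),
                 "compound_class": d.get("compound_class", "other"),
                 "degree": g.degree(v)}
                for v, d in sorted(g.nodes(data=True))]
        pd.DataFrame(rows).to_csv(node_attr_path, index=False)
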