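"""Random-walk community detection and community-significance testing.

The community structure of the correlation network is found with the
walktrap algorithm of Pons and Latapy: short random walks of length ``t``
tend to stay trapped inside densely connected groups, so the Euclidean
distance between walk-probability profiles defines a node metric that an
agglomerative (Ward-style) merging scheme turns into a dendrogram.  The
partition is read off at the modularity-maximizing cut.

Each sufficiently large community is then tested for cohesion: for every
member node, its degree inside the isolated community subgraph is paired
with its degree in the full network after all intra-community edges have
been removed, and the paired samples are compared with a Wilcoxon
signed-rank test (exact null distribution up to 25 nonzero pairs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Modularity


def modularity(g: nx.Graph, assignment: dict, weight: str = "weight") -> float:
    """Weighted Newman modularity of a node partition.

    Q = sum_c [ w_c / W - (s_c / 2W)^2 ] where w_c is the total weight of
    edges inside community c, s_c the summed strength of its nodes and W
    the total edge weight of the graph.
    """
    unknown = set(assignment) - set(g.nodes)
    if unknown:
        raise ValueError(f"assignment references unknown nodes: {sorted(unknown)[:5]}")
    missing = set(g.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment misses nodes: {sorted(missing)[:5]}")
    W = g.size(weight=weight)
    if W == 0:
        return 0.0
    intra: dict = {}
    strength: dict = {}
    for u, v, d in g.edges(data=True):
        w = float(d.get(weight, 1.0))
        cu, cv = assignment[u], assignment[v]
        strength[cu] = strength.get(cu, 0.0) + w
        strength[cv] = strength.get(cv, 0.0) + w
        if cu == cv:
            intra[cu] = intra.get(cu, 0.0) + w
    q = 0.0
    for c in set(assignment.values()):
        q += intra.get(c, 0.0) / W - (strength.get(c, 0.0) / (2.0 * W)) ** 2
    return q


# ---------------------------------------------------------------------------
# Walktrap


@dataclass
class CommunityPartition:
    """Result of the agglomerative random-walk clustering.

    ``assignment`` maps each node to a community id at the best
    (modularity-maximizing) cut; ``dendrogram`` records the merges as
    (community_a, community_b, merged_id, delta_sigma) tuples over internal
    integer ids; ``modularity_trace[i]`` is the modularity of the partition
    after i merges (index 0 = all singletons).
    """

    assignment: dict
    dendrogram: list[tuple[int, int, int, float]]
    modularity_trace: list[float]
    best_cut: int
    newick: str = ""

    @property
    def communities(self) -> dict:
        """community id -> sorted list of member nodes."""
        out: dict = {}
        for node, c in self.assignment.items():
            out.setdefault(c, []).append(node)
        return {c: sorted(members) for c, members in out.items()}

    @property
    def best_modularity(self) -> float:
        return self.modularity_trace[self.best_cut]


def _walk_matrices(g: nx.Graph, nodes: list, weight: str):
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        w = float(d.get(weight, 1.0))
        if w < 0:
            raise ValueError(
                "negative edge weight: random walks need nonnegative weights "
                "(use |rho| as the weight)")
        i, j = pos[u], pos[v]
        a[i, j] += w
        if i != j:
            a[j, i] += w
    walk = a.copy()
    iso = np.flatnonzero(walk.sum(axis=1) == 0)
    walk[iso, iso] = 1.0  # unit self-loop so the walk is defined everywhere
    d = walk.sum(axis=1)
    p = walk / d[:, None]
    return p, d


def walktrap(g: nx.Graph, t: int = 4, weight: str = "weight") -> CommunityPartition:
    """Pons-Latapy walktrap clustering with a modularity-based cut.

    The distance between communities C1, C2 is
    ``r = sqrt(sum_k (P^t_{C1 k} - P^t_{C2 k})^2 / d(k))`` where P is the
    row-normalized weighted adjacency matrix, P^t_{C k} the average t-step
    transition probability from C to node k, and d(k) the (weighted) degree.
    At each step the pair of *adjacent* communities whose merge least
    increases the mean squared node-community distance sigma is merged
    (Ward criterion ``delta = |C1||C2| r^2 / (n (|C1|+|C2|))``); ties break
    on the smallest community-id pair so results are deterministic.

    Only communities joined by an edge merge, so disconnected components
    are never mixed and the dendrogram contains exactly
    ``n_nodes - n_components`` merges.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("walktrap needs a nonempty graph")
    if t < 1:
        raise ValueError("walk length t must be >= 1")
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    p, d = _walk_matrices(g, nodes, weight)
    pt = np.linalg.matrix_power(p, t)
    inv_d = 1.0 / d

    # community state: id -> (member index set, mean walk profile)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    rows: dict[int, np.ndarray] = {i: pt[i] for i in range(n)}
    comm_of = {i: i for i in range(n)}
    # adjacency between communities from graph edges
    pos = {v: i for i, v in enumerate(nodes)}
    adj: dict[int, set] = {i: set() for i in range(n)}
    for u, v in g.edges():
        i, j = pos[u], pos[v]
        if i != j:
            adj[i].add(j)
            adj[j].add(i)

    def delta_sigma(c1: int, c2: int) -> float:
        diff = rows[c1] - rows[c2]
        r2 = float(np.sum(diff * diff * inv_d))
        s1, s2 = len(members[c1]), len(members[c2])
        return s1 * s2 * r2 / ((s1 + s2) * n)

    def current_assignment() -> dict:
        return {nodes[i]: comm_of[i] for i in range(n)}

    dendrogram: list[tuple[int, int, int, float]] = []
    trace = [modularity(g, current_assignment(), weight=weight)]
    newick_parts = {i: str(nodes[i]) for i in range(n)}
    next_id = n

    while True:
        best = None
        for c1 in sorted(adj):
            for c2 in sorted(adj[c1]):
                if c2 <= c1:
                    continue
                ds = delta_sigma(c1, c2)
                if best is None or ds < best[0] - 1e-15 or (
                        abs(ds - best[0]) <= 1e-15 and (c1, c2) < best[1:]):
                    best = (ds, c1, c2)
        if best is None:
            break
        ds, c1, c2 = best
        s1, s2 = len(members[c1]), len(members[c2])
        new = next_id
        next_id += 1
        members[new] = members.pop(c1) + members.pop(c2)
        rows[new] = (s1 * rows.pop(c1) + s2 * rows.pop(c2)) / (s1 + s2)
        neighbors = (adj.pop(c1) | adj.pop(c2)) - {c1, c2}
        adj[new] = neighbors
        for c in neighbors:
            adj[c].discard(c1)
            adj[c].discard(c2)
            adj[c].add(new)
        for i in members[new]:
            comm_of[i] = new
        newick_parts[new] = f"({newick_parts.pop(c1)},{newick_parts.pop(c2)})"
        dendrogram.append((c1, c2, new, ds))
        trace.append(modularity(g, current_assignment(), weight=weight))

    best_cut = int(np.argmax(trace))

    # replay merges up to the best cut to obtain the assignment there
    comm_of = {i: i for i in range(n)}
    parent: dict[int, int] = {}
    for c1, c2, new, _ in dendrogram[:best_cut]:
        parent[c1] = new
        parent[c2] = new

    def root(c: int) -> int:
        while c in parent:
            c = parent[c]
        return c

    raw = {nodes[i]: root(i) for i in range(n)}
    # relabel communities 0, 1, ... by decreasing size then first member
    groups: dict[int, list] = {}
    for v, c in raw.items():
        groups.setdefault(c, []).append(v)
    ordered = sorted(groups, key=lambda c: (-len(groups[c]), sorted(map(str, groups[c]))))
    relabel = {c: i for i, c in enumerate(ordered)}
    assignment = {v: relabel[c] for v, c in raw.items()}

    newick = ";".join(newick_parts[c] for c in sorted(newick_parts)) + ";"
    return CommunityPartition(assignment, dendrogram, trace, best_cut, newick)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (exact distribution handles midrank ties)


def _signed_rank_exact_p(diffs: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact signed-rank p-value by dynamic programming over sign flips.

    Works with tied |differences| (midranks): the null distribution of
    W+ is built by convolving over each rank's two equally likely signs.
    Returns (W_plus, p).
    """
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    # doubled ranks are integers even for .5 midranks
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_ge = float(counts[w2:].sum())
    p_le = float(counts[: w2 + 1].sum())
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return w_plus, p


def _signed_rank_normal_p(diffs: np.ndarray, alternative: str) -> tuple[float, float]:
    """Normal approximation with continuity and tie corrections."""
    ranks = stats.rankdata(np.abs(diffs))
    n = diffs.size
    w_plus = float(ranks[diffs > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return w_plus, 1.0
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (w_plus - mean - 0.5) / sd
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        z = (w_plus - mean + 0.5) / sd
        p = float(stats.norm.cdf(z))
    else:
        z = (w_plus - mean - np.sign(w_plus - mean) * 0.5) / sd
        p = float(2.0 * stats.norm.sf(abs(z)))
    return w_plus, min(1.0, p)


def wilcoxon_signed_rank(x, y, alternative: str = "two-sided",
                         exact_max_n: int = 25) -> tuple[float, float, int]:
    """Paired Wilcoxon signed-rank test with classic zero-dropping.

    Exact sign-flip null distribution (valid under ties) when at most
    *exact_max_n* nonzero pairs remain, otherwise a normal approximation
    with continuity and tie corrections.  Returns (W_plus, p, n_zero).
    A degenerate all-zero difference vector yields p = 1.0.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0, n_zero
    if d.size <= exact_max_n:
        w, p = _signed_rank_exact_p(d, alternative)
    else:
        w, p = _signed_rank_normal_p(d, alternative)
    return w, p, n_zero


# ---------------------------------------------------------------------------
# Community significance


@dataclass
class CommunityTestResult:
    """Cohesion test of one community against its residual connectivity."""

    community: int
    size: int
    members: list
    internal_degrees: dict
    residual_degrees: dict
    statistic: float
    p_value: float
    tested: bool
    degenerate: bool = False
    n_zero_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "community": int(self.community),
            "size": int(self.size),
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "tested": bool(self.tested),
            "degenerate": bool(self.degenerate),
        }


def community_significance(g: nx.Graph, assignment: dict,
                           min_size: int = 9,
                           alternative: str = "two-sided") -> list[CommunityTestResult]:
    """Test each community's internal cohesion with a Wilcoxon signed-rank.

    For every node of a community the degree inside the isolated community
    subgraph is paired with its residual degree — its degree in the full
    network once all intra-community edges are deleted.  Communities with
    at most *min_size* nodes are returned untested (``tested=False``); the
    default of 9 means only communities of more than nine nodes are tested.
    Internal and residual degrees always sum to the full-network degree.
    """
    groups: dict = {}
    for node, c in assignment.items():
        groups.setdefault(c, []).append(node)
    results = []
    for c in sorted(groups, key=str):
        nodes = sorted(groups[c], key=str)
        sub = g.subgraph(nodes)
        internal = {v: sub.degree(v) for v in nodes}
        residual = {v: g.degree(v) - internal[v] for v in nodes}
        size = len(nodes)
        if size <= min_size:
            results.append(CommunityTestResult(
                c, size, nodes, internal, residual,
                statistic=np.nan, p_value=np.nan, tested=False))
            continue
        x = np.array([internal[v] for v in nodes], dtype=float)
        y = np.array([residual[v] for v in nodes], dtype=float)
        w, p, n_zero = wilcoxon_signed_rank(x, y, alternative=alternative)
        degenerate = bool(np.all(x == y))
        if n_zero:
            logger.info("community %s: dropped %d zero-difference pairs", c, n_zero)
        results.append(CommunityTestResult(
            c, size, nodes, internal, residual,
            statistic=w, p_value=p, tested=True,
            degenerate=degenerate, n_zero_dropped=n_zero))
    return results
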