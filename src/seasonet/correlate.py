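"""All-pairs rank correlation among metabolites and traits.

Provides the Shapiro-Wilk normality screen used to justify the choice of
Spearman over Pearson correlation, the correlation matrix itself with
two-sided p-values, and the Benjamini-Hochberg machinery that converts a
target q-value (FDR level) into a p-value threshold for edge selection.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class NormalityReport:
    """Per-variable Shapiro-Wilk results across time points."""

    statistics: pd.Series       # W per variable
    pvalues: pd.Series
    alpha: float
    violation_fraction: float   # share of variables with p < alpha
    recommended_method: str     # "spearman" if most variables non-normal

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "violation_fraction": self.violation_fraction,
            "recommended_method": self.recommended_method,
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
        }


@dataclass
class CorrelationStats:
    """Symmetric correlation, p-value and q-value matrices over named nodes.

    ``n_used`` holds the pairwise-complete sample count behind each entry.
    Undefined correlations (constant variables, too few paired samples) are
    NaN in all matrices.
    """

    labels: list[str]
    rho: np.ndarray
    pval: np.ndarray
    qval: np.ndarray
    n_used: np.ndarray
    method: str

    def __post_init__(self) -> None:
        k = len(self.labels)
        for name in ("rho", "pval", "qval", "n_used"):
            m = getattr(self, name)
            if m.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
        if not np.allclose(self.rho, self.rho.T, equal_nan=True):
            raise ValueError("rho must be symmetric")

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def pair(self, a: str, b: str) -> tuple[float, float, float]:
        """(rho, p, q) for a labeled pair."""
        i, j = self.index_of(a), self.index_of(b)
        return float(self.rho[i, j]), float(self.pval[i, j]), float(self.qval[i, j])

    def upper_triangle_pvalues(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        p = self.pval[iu]
        return p[~np.isnan(p)]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (node_i, node_j, rho, p, q, n) over the upper triangle."""
        rows = []
        k = len(self.labels)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append((self.labels[i], self.labels[j],
                             self.rho[i, j], self.pval[i, j],
                             self.qval[i, j], int(self.n_used[i, j])))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "rho", "p", "q", "n"])


# ---------------------------------------------------------------------------
# Normality screen


def normality_screen(matrix: pd.DataFrame, alpha: float = 0.05) -> NormalityReport:
    """Shapiro-Wilk test per variable across time points.

    Recommends Spearman correlation when more than half of the variables
    violate normality at level *alpha*, mirroring common practice for
    metabolite profiles where the majority of distributions are skewed.
    """
    stats_out, pvals = {}, {}
    for col in matrix.columns:
        x = matrix[col].dropna().to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"normality screen needs >= 3 observations for {col!r}")
        if np.ptp(x) == 0:
            # Shapiro-Wilk undefined on constants; a constant is trivially
            # degenerate and counted as a violation.
            stats_out[col], pvals[col] = np.nan, 0.0
            continue
        res = stats.shapiro(x)
        stats_out[col], pvals[col] = float(res.statistic), float(res.pvalue)
    pseries = pd.Series(pvals)
    violation = float((pseries < alpha).mean())
    method = "spearman" if violation > 0.5 else "pearson"
    return NormalityReport(pd.Series(stats_out), pseries, alpha, violation, method)


# ---------------------------------------------------------------------------
# Correlation matrix


@lru_cache(maxsize=8)
def _spearman_exact_table(n: int) -> np.ndarray:
    """Two-sided p-values of the exact Spearman permutation null.

    For tie-free ranks, rho is a linear function of T = sum_i r_x(i) r_y(i),
    and under the null T is distributed as sum_i i * pi(i) over uniform
    permutations pi.  That distribution is built by dynamic programming
    over subsets: the partial sum distribution for a subset S of ranks
    assigned to the first |S| positions is the convolution of the |S|
    one-step shifts.  Returns an array p[t] = P(|T' - mu| >= |t - mu|)
    indexed by t = 0..n(n+1)(2n+1)/6.

    The t approximation that replaces this for larger n is several-fold
    anti-conservative at the extreme tail probed by FDR correction over
    thousands of pairs, which is why the exact null is the default for
    small samples.
    """
    max_t = n * (n + 1) * (2 * n + 1) // 6
    size = max_t + 1
    dists: dict[int, np.ndarray] = {0: None}
    init = np.zeros(size)
    init[0] = 1.0
    dists[0] = init
    full = (1 << n) - 1
    for mask in range(1, full + 1):
        k = mask.bit_count()
        arr = np.zeros(size)
        rest = mask
        while rest:
            low = rest & -rest
            j = low.bit_length()          # rank value assigned to position k
            prev = dists[mask ^ low]
            step = k * j
            arr[step:] += prev[: size - step]
            rest ^= low
        dists[mask] = arr
    counts = dists[full]
    probs = counts / counts.sum()
    cdf = np.cumsum(probs)
    sf = np.cumsum(probs[::-1])[::-1]
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def _spearman_pvalue_t(rho: float, n: int) -> float:
    """Two-sided p from the t approximation with n-2 degrees of freedom."""
    if n < 3 or not np.isfinite(rho):
        return np.nan
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))

def _spearman_pvalue_exact(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p-value: share of permutations with |rho| >= |rho_obs|.

    Enumerates all n! orderings of y, so only sensible for n <= 9.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    tol = 1e-12
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        if abs(r) >= abs(rho_obs) - tol:
            count += 1
        total += 1
    return count / total


def correlation_matrix(matrix: pd.DataFrame, method: str = "spearman",
                       min_pairs: int = 4, exact_max_n: int = 0,
                       exact_null_max_n: int = 13) -> CorrelationStats:
    """All-pairs correlation with pairwise-complete observations.

    Spearman rho is the Pearson correlation of mid-ranked data (ties get
    average ranks).  Two-sided p-values come from the exact permutation
    null distribution whenever both variables are tie-free and the pair
    has at most ``exact_null_max_n`` complete observations (the regime of
    a 12-month series); otherwise the t approximation with n-2 degrees of
    freedom is used.  ``exact_max_n`` additionally enables a brute-force
    enumeration null (valid under ties) for pairs with at most that many
    observations.

    Constant variables have undefined correlations; their pairs are NaN and
    are logged rather than raised, so a single flat metabolite does not
    abort an analysis.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    labels = list(matrix.columns)
    data = matrix.to_numpy(dtype=float)
    n_rows, k = data.shape
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    n_used = np.zeros((k, k), dtype=int)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pval, 0.0)
    np.fill_diagonal(n_used, n_rows)

    complete = ~np.isnan(data)
    if complete.all() and exact_max_n == 0 and n_rows >= max(min_pairs, 4):
        # fast path: pairwise-complete == listwise-complete, one corrcoef call
        if method == "spearman":
            ranked = np.apply_along_axis(stats.rankdata, 0, data)
        else:
            ranked = data
        sds = ranked.std(axis=0)
        ok = sds > 0
        for name in np.asarray(labels, dtype=object)[~ok]:
            logger.warning("constant variable %r: correlations undefined", name)
        if ok.all():
            rho = np.corrcoef(ranked, rowvar=False)
        else:
            rho[np.ix_(ok, ok)] = np.corrcoef(ranked[:, ok], rowvar=False)
        np.fill_diagonal(rho, 1.0)
        rho = (rho + rho.T) / 2.0
        n_used[:] = n_rows
        r_off = np.clip(rho, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = r_off * np.sqrt((n_rows - 2) / (1.0 - r_off**2))
        pval = 2.0 * stats.t.sf(np.abs(tstat), df=n_rows - 2)
        pval[np.abs(r_off) >= 1.0] = 0.0
        if method == "spearman" and n_rows <= exact_null_max_n:
            expected = np.arange(1, n_rows + 1)
            tie_free = np.array([np.array_equal(np.sort(ranked[:, j]), expected)
                                 for j in range(k)])
            if tie_free.any():
                table = _spearman_exact_table(n_rows)
                t_cross = ranked.T @ ranked
                both = np.outer(tie_free, tie_free)
                np.fill_diagonal(both, False)
                pval[both] = table[np.rint(t_cross[both]).astype(int)]
        pval[np.isnan(rho)] = np.nan
        np.fill_diagonal(pval, 0.0)
        qval = qvalue_matrix(pval)
        return CorrelationStats(labels, rho, pval, qval, n_used, method)

    constant_logged: set[str] = set()
    for i in range(k):
        for j in range(i + 1, k):
            mask = complete[:, i] & complete[:, j]
            n = int(mask.sum())
            n_used[i, j] = n_used[j, i] = n
            if n < min_pairs:
                continue
            x, y = data[mask, i], data[mask, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                for idx, v in ((i, x), (j, y)):
                    if np.ptp(v) == 0 and labels[idx] not in constant_logged:
                        constant_logged.add(labels[idx])
                        logger.warning("constant variable %r: correlations undefined",
                                       labels[idx])
                continue
            if method == "spearman":
                rx, ry = stats.rankdata(x), stats.rankdata(y)
            else:
                rx, ry = x, y
            r = float(np.corrcoef(rx, ry)[0, 1])
            rho[i, j] = rho[j, i] = r
            expected = np.arange(1, n + 1)
            if method == "spearman" and 0 < exact_max_n >= n:
                p = _spearman_pvalue_exact(x, y, r)
            elif (method == "spearman" and n <= exact_null_max_n
                    and np.array_equal(np.sort(rx), expected)
                    and np.array_equal(np.sort(ry), expected)):
                p = float(_spearman_exact_table(n)[int(round(rx @ ry))])
            else:
                p = _spearman_pvalue_t(r, n)
            pval[i, j] = pval[j, i] = p

    qval = qvalue_matrix(pval)
    return CorrelationStats(labels, rho, pval, qval, n_used, method)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up q-values)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def qvalue_matrix(pval: np.ndarray) -> np.ndarray:
    """BH correction over the upper triangle only (m = k(k-1)/2 tests).

    The matrix is symmetric, so each pair is counted once; the corrected
    values are mirrored back into a symmetric q matrix with 0 diagonal.
    """
    k = pval.shape[0]
    iu = np.triu_indices(k, k=1)
    flat = pval[iu]
    finite = ~np.isnan(flat)
    q = np.full(flat.shape, np.nan)
    if finite.any():
        q[finite] = bh_qvalues(flat[finite])
    qmat = np.full((k, k), np.nan)
    qmat[iu] = q
    qmat.T[iu] = q
    np.fill_diagonal(qmat, 0.0)
    return qmat


def p_threshold_for_q(pvals, q_target: float = 0.05) -> float:
    """Largest p-value cutoff whose BH q-value stays at or below *q_target*.

    Sorts the m p-values ascending and returns p(k) for the largest k with
    p(k) <= q_target * k / m, or 0.0 when no test passes.  Every pair with
    p <= the returned threshold then has BH q <= q_target.
    """
    p = np.asarray(list(pvals), dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("p_threshold_for_q needs at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q_target < 1:
        raise ValueError("q_target must lie in (0, 1)")
    p_sorted = np.sort(p)
    m = p.size
    crit = q_target * np.arange(1, m + 1) / m
    passing = np.nonzero(p_sorted <= crit)[0]
    if passing.size == 0:
        return 0.0
    return float(p_sorted[passing[-1]])


def write_correlations_csv(cstats: CorrelationStats, path: str | Path) -> None:
    cstats.to_long_frame().to_csv(path, index=False)
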