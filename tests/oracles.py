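"""Independent brute-force oracles used by the test suite.

Each function here re-derives a quantity by direct enumeration or naive
computation, never through the code paths (or scipy calls) it is used to
check.
"""

from __future__ import annotations

import itertools
from math import comb, sqrt

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
        "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
        "B": "V", "V": "B", "D": "H", "H": "D"}


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def brute_scan(seq: str, motif: str, offset: int) -> set[tuple[int, str]]:
    """Character-by-character double-strand motif match (linear genome).

    Returns {(1-based modified-base position, strand)}.
    """
    hits = set()
    L = len(motif)
    for pat, strand in ((motif, "+"), (revcomp(motif), "-")):
        for start in range(len(seq) - L + 1):
            window = seq[start : start + L]
            if all(w in IUPAC[m] for w, m in zip(window, pat)):
                if strand == "+":
                    hits.add((start + offset + 1, "+"))
                else:
                    hits.add((start + (L - 1 - offset) + 1, "-"))
    return hits


def ranksum_exact_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all rank assignments."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1, n = len(x), len(pooled)
    ranks_x = sum(pooled.index(v) + 1 for v in x)
    stats = [sum(c) for c in itertools.combinations(range(1, n + 1), n1)]
    mu = n1 * (n + 1) / 2.0
    obs_dev = abs(ranks_x - mu)
    extreme = sum(1 for s in stats if abs(s - mu) >= obs_dev - 1e-9)
    return extreme / comb(n, n1)


def kruskal_h(groups) -> float:
    """H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1), mid-ranks, tie-corrected."""
    pooled = sorted(v for g in groups for v in g)
    n = len(pooled)
    rank_of = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        r = (i + 1 + j) / 2.0
        rank_of[pooled[i]] = r
        i = j
    h = 12.0 / (n * (n + 1)) * sum(
        sum(rank_of[v] for v in g) ** 2 / len(g) for g in groups
    ) - 3 * (n + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    denom = 1.0 - tie / (n**3 - n)
    return h / denom if denom > 0 else float("nan")


def anova_f_p(groups) -> tuple[float, float]:
    """One-way F from the explicit sum-of-squares decomposition."""
    from scipy.special import fdtrc  # regularized F survival, not stats.f_oneway

    all_vals = [v for g in groups for v in g]
    n = len(all_vals)
    k = len(groups)
    grand = sum(all_vals) / n
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return f, float(fdtrc(k - 1, n - k, f))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (independent of package)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def hypergeom_two_sided_p(k: int, K: int, n: int, N: int) -> float:
    """Two-sided Fisher p by summing all tables no more probable than observed."""

    def pmf(x: int) -> float:
        return comb(K, x) * comb(N - K, n - x) / comb(N, n)

    lo, hi = max(0, n + K - N), min(K, n)
    p_obs = pmf(k)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def brute_ward(X: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Greedy Ward agglomeration computing the ESS increase of every
    candidate merge directly from the raw points (no Lance-Williams).

    Heights are sqrt(2 * delta-ESS), the Euclidean-distance convention.
    """

    def ess(idx):
        pts = X[list(idx)]
        c = pts.mean(axis=0)
        return float(((pts - c) ** 2).sum())

    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            inc = ess(clusters[a] | clusters[b]) - ess(clusters[a]) - ess(clusters[b])
            if best is None or inc < best[0] - 1e-12:
                best = (inc, a, b)
        inc, a, b = best
        merges.append((clusters[a], clusters[b], sqrt(2.0 * inc)))
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


def best_two_partition_1d(values) -> set[frozenset]:
    """Minimum total within-cluster variance 2-partition by exhaustion."""
    idx = range(len(values))
    arr = np.asarray(values, dtype=float)

    def ssq(members):
        pts = arr[list(members)]
        return float(((pts - pts.mean()) ** 2).sum()) if members else 0.0

    best, best_cost = None, None
    for r in range(1, len(values) // 2 + 1):
        for left in itertools.combinations(idx, r):
            right = tuple(i for i in idx if i not in left)
            cost = ssq(left) + ssq(right)
            if best_cost is None or cost < best_cost:
                best_cost, best = cost, {frozenset(left), frozenset(right)}
    return best
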