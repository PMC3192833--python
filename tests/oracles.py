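"""Independent brute-force / closed-form oracles used by the test suite.

These implementations deliberately share no code with the package: scalar
loops, textbook formulas, and exhaustive enumeration only.
"""

from itertools import combinations

import numpy as np
from scipy import stats


def wc_theta_scalar(ps, ns):
    """Weir-Cockerham theta for one locus, allele-level ANOVA, plain loops."""
    ps = [float(p) for p in ps]
    ns = [float(n) for n in ns]
    r = len(ps)
    n_tot = sum(ns)
    p_bar = sum(n * p for n, p in zip(ns, ps)) / n_tot
    msp = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, ps)) / (r - 1)
    msg = sum(n * p * (1 - p) for n, p in zip(ns, ps)) / sum(n - 1 for n in ns)
    n_c = (n_tot - sum(n * n for n in ns) / n_tot) / (r - 1)
    denom = msp + (n_c - 1) * msg
    if denom == 0:
        return float("nan")
    return (msp - msg) / denom


def chain_regions(positions, merge_bp):
    """Transitive closure of the <=merge_bp adjacency relation, brute force."""
    positions = sorted(positions)
    n = len(positions)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            adj[i, j] = abs(positions[i] - positions[j]) <= merge_bp
    # transitive closure
    reach = adj.copy()
    for k in range(n):
        for i in range(n):
            if reach[i, k]:
                reach[i] |= reach[k]
    seen = set()
    groups = []
    for i in range(n):
        if i in seen:
            continue
        members = sorted(j for j in range(n) if reach[i, j])
        seen.update(members)
        groups.append([positions[j] for j in members])
    return sorted((g[0], g[-1], len(g)) for g in groups)


def window_assignment(positions, window_bp, step_bp, min_snps):
    """Brute-force interval assignment of SNPs to anchored sliding windows."""
    out = []
    if not positions:
        return out
    for start in range(0, max(positions) + 1, step_bp):
        members = [p for p in positions if start <= p < start + window_bp]
        if len(members) >= min_snps:
            out.append((start, start + window_bp, tuple(members)))
    return out


def interval_union(intervals):
    """Union of overlapping-or-abutting half-open intervals, brute force."""
    intervals = sorted(intervals)
    merged = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def bh_stepup(pvals, alpha):
    """Benjamini-Hochberg rejection set by the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_max = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= alpha * rank / m:
            k_max = rank
    rejected = set(order[:k_max])
    return [i in rejected for i in range(m)]


def ehh_direct(haplotypes, a, b):
    """EHH over closed interval [a, b] by pairwise haplotype comparison."""
    lo, hi = min(a, b), max(a, b)
    haps = [tuple(row[lo: hi + 1]) for row in haplotypes]
    n = len(haps)
    same = sum(1 for i, j in combinations(range(n), 2) if haps[i] == haps[j])
    return same / (n * (n - 1) / 2)


def r2_from_haplotypes(h1, h2):
    """Haplotype r^2 from 2x2 haplotype counts, textbook formula."""
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    pa = h1.mean()
    pb = h2.mean()
    pab = np.mean(h1 * h2)
    d = pab - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def t2_regression(x, y):
    """Squared t of the slope via scipy.linregress (independent code path)."""
    res = stats.linregress(x, y)
    if res.stderr == 0:
        return float("inf")
    return (res.slope / res.stderr) ** 2


def maximal_ibs_bruteforce(blocks, positions):
    """Longest bp run of SNPs where every breed block is identically fixed.

    ``blocks``: list of per-breed genotype arrays (samples x loci), -1
    missing.  Returns (start_pos, end_pos_exclusive) or None; all-interval
    enumeration.
    """
    m = len(positions)

    def locus_ok(l):
        consensus = None
        for block in blocks:
            called = [g for g in block[:, l] if g != -1]
            if any(g == 1 for g in called):
                return False
            alleles = {g for g in called}
            if alleles == {0, 2}:
                return False
            if called:
                a = 1 if 2 in alleles else 0
                if consensus is not None and consensus != a:
                    return False
                consensus = a if consensus is None else consensus
        return True

    ok = [locus_ok(l) for l in range(m)]
    best = None
    for i in range(m):
        for j in range(i, m):
            if all(ok[i: j + 1]):
                span = positions[j] + 1 - positions[i]
                if best is None or span > best[0]:
                    best = (span, positions[i], positions[j] + 1)
    if best is None:
        return None
    return best[1], best[2]
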