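"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths: partition
enumeration is recursive, GEV is recomputed from the definition, and the
ANOVA decomposition is written out sum-by-sum.
"""

import itertools

import numpy as np


def set_partitions(items, k):
    """All partitions of ``items`` into exactly k non-empty blocks."""
    items = list(items)
    if k == 1:
        yield [items]
        return
    if len(items) == k:
        yield [[i] for i in items]
        return
    first, rest = items[0], items[1:]
    # first joins an existing block of a (k)-partition of rest
    for part in set_partitions(rest, k):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
    # first is a singleton next to a (k-1)-partition of rest
    for part in set_partitions(rest, k - 1):
        yield [[first]] + part


def partition_gev(maps, weights, blocks):
    """GEV of a partition, computed from the definition.

    Centroid of each block: members sign-aligned to the block's first map,
    averaged, recentred, renormalized.  GEV is the GFP^2-weighted mean
    squared absolute correlation of each map with its block centroid.
    """
    maps = np.asarray(maps, float)
    maps = maps - maps.mean(axis=1, keepdims=True)
    maps = maps / np.linalg.norm(maps, axis=1, keepdims=True)
    w = np.asarray(weights, float)
    num = 0.0
    for block in blocks:
        block = list(block)
        ref = maps[block[0]]
        stack = np.array([m if m @ ref >= 0 else -m for m in maps[block]])
        cen = stack.mean(axis=0)
        cen = cen - cen.mean()
        cen = cen / np.linalg.norm(cen)
        for i in block:
            num += (w[i] * abs(maps[i] @ cen)) ** 2
    return num / np.sum(w**2)


def best_partition_gev(maps, weights, k):
    """Maximum GEV over every partition into k blocks."""
    n = len(maps)
    best = -1.0
    for blocks in set_partitions(range(n), k):
        g = partition_gev(maps, weights, blocks)
        if g > best:
            best = g
    return best


def anova_rm_brute_force(x):
    """One-way repeated-measures ANOVA by explicit sums of squares."""
    x = np.asarray(x, float)
    n, m = x.shape
    grand = x.sum() / (n * m)
    ss_cond = sum(n * (x[:, j].sum() / n - grand) ** 2 for j in range(m))
    ss_subj = sum(m * (x[i, :].sum() / m - grand) ** 2 for i in range(n))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(m))
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = m - 1, (n - 1) * (m - 1)
    f = (ss_cond / df1) / (ss_err / df2)
    from scipy.stats import f as fdist

    return f, (df1, df2), float(fdist.sf(f, df1, df2))


def friedman_chi2(x):
    """Friedman statistic from mid-ranks (no tie correction: used on
    untied data only)."""
    x = np.asarray(x, float)
    n, m = x.shape
    ranks = np.array([np.argsort(np.argsort(row)) + 1.0 for row in x])
    rj = ranks.sum(axis=0)
    return 12.0 / (n * m * (m + 1)) * np.sum(rj**2) - 3.0 * n * (m + 1)


def friedman_exact_p(x):
    """Exact Friedman p by enumerating all (m!)^n rank configurations."""
    x = np.asarray(x, float)
    n, m = x.shape
    observed = friedman_chi2(x)
    perms = list(itertools.permutations(range(1, m + 1)))
    count = total = 0
    for combo in itertools.product(perms, repeat=n):
        ranks = np.array(combo, float)
        rj = ranks.sum(axis=0)
        stat = 12.0 / (n * m * (m + 1)) * np.sum(rj**2) - 3.0 * n * (m + 1)
        count += stat >= observed - 1e-12
        total += 1
    return count / total
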