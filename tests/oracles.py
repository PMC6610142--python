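"""Independent brute-force oracles used to validate the fast
implementations: literal-definition computations that share no code with
the library paths they check."""

from itertools import combinations

import numpy as np
from scipy.special import comb


def unifrac_brute(tree, abund_a, abund_b, weighted, normalized=True):
    """Per-branch enumeration of UniFrac: walk every non-root branch,
    list its descendant tips explicitly and apply the definition."""
    num = den = 0.0
    shared = uni = 0.0
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips(include_self=True)}
        a = sum(abund_a.get(t, 0.0) for t in tips)
        b = sum(abund_b.get(t, 0.0) for t in tips)
        if weighted:
            num += node.length * abs(a - b)
            den += node.length * (a + b)
        else:
            in_a, in_b = a > 0, b > 0
            if in_a != in_b:
                uni += node.length
            if in_a or in_b:
                shared += node.length
    if weighted:
        return num / den if normalized else num
    return uni / shared


def silhouette_brute(d, labels):
    """O(n^2) silhouette straight from the definition."""
    n = len(labels)
    widths = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([d[i, j] for j in own])
        b = min(np.mean([d[i, j] for j in range(n) if labels[j] == c])
                for c in set(labels) if c != labels[i])
        widths[i] = (b - a) / max(a, b)
    return widths


def mannwhitney_exact_brute(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    pooled ranks to the first group (tie-free data only)."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    nx = len(x)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    mu = nx * len(y) / 2
    us = []
    for idx in combinations(range(len(pooled)), nx):
        u = ranks[list(idx)].sum() - nx * (nx + 1) / 2
        us.append(abs(u - mu))
    us = np.array(us)
    return float((us >= abs(u_obs - mu) - 1e-12).mean())


def fisher_exact_brute(table):
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins that are no more probable."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return (comb(c1, k) * comb(n - c1, r1 - k)) / comb(n, r1)

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return float(min(total, 1.0))


def pcit_brute(r):
    """Literal trio enumeration of the PCIT rejection rule."""
    n = r.shape[0]
    mask = np.ones((n, n), dtype=bool)

    def part(a, b, c):
        den = np.sqrt((1 - r[a, c] ** 2) * (1 - r[b, c] ** 2))
        return (r[a, b] - r[a, c] * r[b, c]) / den

    for x in range(n):
        for y in range(n):
            if x == y:
                continue
            for z in range(n):
                if z in (x, y):
                    continue
                if max(abs(r[x, z]), abs(r[y, z])) >= 1:
                    continue
                if min(abs(r[x, y]), abs(r[x, z]), abs(r[y, z])) == 0:
                    continue
                eps = (part(x, y, z) / r[x, y] + part(x, z, y) / r[x, z]
                       + part(y, z, x) / r[y, z]) / 3
                if not np.isfinite(eps):
                    continue
                if (abs(r[x, y]) <= eps * abs(r[x, z])
                        and abs(r[x, y]) <= eps * abs(r[y, z])):
                    mask[x, y] = mask[y, x] = False
    np.fill_diagonal(mask, True)
    return mask
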