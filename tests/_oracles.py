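"""Independent, deliberately naive reference implementations used as oracles.

Everything here is written with plain Python loops and exact enumeration,
separate from the package's vectorized code paths, so agreement between the
two is meaningful.
"""

from __future__ import annotations

from math import comb, erf, sqrt

import numpy as np


def bh_bruteforce(pvals):
    """Literal Benjamini-Hochberg step-up by double loop."""
    p = list(map(float, pvals))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    # q for the k-th smallest = min over m >= k of p_(m) * n / m
    for rank_pos, i in enumerate(order, start=1):
        candidates = [
            p[order[m - 1]] * n / m for m in range(rank_pos, n + 1)
        ]
        q[i] = min(1.0, min(candidates))
    return q


def hypergeom_upper_tail(N, K, n, k):
    """Pr(X >= k) for X ~ Hypergeometric(N, K, n), by exact enumeration."""
    total = comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += comb(K, x) * comb(N - K, n - x)
    return acc / total


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p: sum of table probabilities <= observed."""
    N = a + b + c + d
    row1, col1 = a + b, a + c
    total = comb(N, col1)

    def prob(x):
        if x < 0 or x > row1 or col1 - x > N - row1:
            return 0.0
        return comb(row1, x) * comb(N - row1, col1 - x) / total

    p_obs = prob(a)
    return sum(prob(x) for x in range(0, min(row1, col1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def gsva_oracle(expr, set_genes, bandwidth_factor=4.0, tau=1.0):
    """Step-by-step GSVA ES for one gene set; expr: dict gene -> list of values."""
    genes = list(expr.keys())
    G = len(genes)
    n = len(next(iter(expr.values())))

    def phi_cdf(t):
        return 0.5 * (1.0 + erf(t / sqrt(2.0)))

    z = {}
    for g in genes:
        vals = expr[g]
        mean = sum(vals) / n
        sd = sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
        h = sd / bandwidth_factor
        z[g] = [sum(phi_cdf((vj - vk) / h) for vk in vals) / n for vj in vals]

    es_out = []
    members = set(set_genes)
    for j in range(n):
        scored = [(z[g][j], i, g) for i, g in enumerate(genes)]
        # decreasing statistic, ties by input order
        scored.sort(key=lambda t: (-t[0], t[1]))
        ranks = {g: pos + 1 for pos, (_, _, g) in enumerate(scored)}
        weights = {g: abs(G / 2.0 - ranks[g]) ** tau for g in genes}
        denom_in = sum(weights[g] for g in genes if g in members)
        n_out = G - len([g for g in genes if g in members])
        nu, walk = 0.0, []
        for _, _, g in scored:
            if g in members:
                nu += weights[g] / denom_in
            else:
                nu -= 1.0 / n_out
            walk.append(nu)
        mx = max(max(walk), 0.0)
        mn = min(min(walk), 0.0)
        es_out.append(mx + mn)
    return es_out


def ssgsea_oracle(expr, set_genes, alpha=0.25):
    """Step-by-step unnormalized ssGSEA ES per sample; expr: dict gene -> values."""
    genes = list(expr.keys())
    G = len(genes)
    n = len(next(iter(expr.values())))
    members = set(set_genes)
    out = []
    for j in range(n):
        scored = [(expr[g][j], i, g) for i, g in enumerate(genes)]
        scored.sort(key=lambda t: (-t[0], t[1]))
        n_in = len([g for g in genes if g in members])
        weights = [(G - pos) ** alpha for pos in range(G)]  # rank from bottom
        denom_in = sum(w for (v, i, g), w in zip(scored, weights) if g in members)
        es, cum_in, cum_out = 0.0, 0.0, 0.0
        for (v, i, g), w in zip(scored, weights):
            if g in members:
                cum_in += w / denom_in
            else:
                cum_out += 1.0 / (G - n_in)
            es += cum_in - cum_out
        out.append(es)
    return out


def gsea_walk_oracle(scores, in_set, weight=1.0):
    """Running sum and ES for a preranked list already in rank order."""
    w = [abs(s) ** weight for s in scores]
    denom = sum(wi for wi, m in zip(w, in_set) if m)
    n_out = sum(1 for m in in_set if not m)
    nu, walk = 0.0, []
    for wi, m in zip(w, in_set):
        nu += wi / denom if m else -1.0 / n_out
        walk.append(nu)
    es = max(walk, key=abs)
    return walk, es


def spearman_d2(x, y):
    """Spearman r by the 1 - 6*sum(d^2)/(n(n^2-1)) formula (no ties)."""
    n = len(x)
    rx = {v: r + 1 for r, v in enumerate(sorted(x))}
    ry = {v: r + 1 for r, v in enumerate(sorted(y))}
    d2 = sum((rx[a] - ry[b]) ** 2 for a, b in zip(x, y))
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def nb_moments(mu, phi):
    """Mean and variance of the NB in mean/dispersion form."""
    return mu, mu + mu**2 / phi
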