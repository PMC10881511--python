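"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the vectorized code paths of the package: explicit
loops over allele pairs, direct transcription of the Weir-Cockerham (1984)
component formulas, and exhaustive enumeration of the sweep model.
"""

import numpy as np
from scipy.stats import binom, hypergeom


def alleles_of(code):
    return {0: (0, 0), 1: (0, 1), 2: (1, 1)}.get(code)


def brute_window_pi(geno, site_in_window, window_length):
    """Average over all allele pairs, summed per site, explicit double loop."""
    total = 0.0
    for j in range(geno.shape[1]):
        if not site_in_window[j]:
            continue
        alleles = []
        for g in geno[:, j]:
            a = alleles_of(int(g))
            if a is not None:
                alleles.extend(a)
        n = len(alleles)
        if n < 2:
            continue
        diffs = pairs = 0
        for x in range(n):
            for y in range(x + 1, n):
                pairs += 1
                diffs += alleles[x] != alleles[y]
        total += diffs / pairs
    return total / window_length


def brute_theta_w(geno, site_in_window, window_length):
    """Watterson estimator with window-median allele number."""
    S = 0
    ns = []
    for j in range(geno.shape[1]):
        if not site_in_window[j]:
            continue
        alleles = []
        for g in geno[:, j]:
            a = alleles_of(int(g))
            if a is not None:
                alleles.extend(a)
        n = len(alleles)
        if n >= 2 and 0 < sum(alleles) < n:
            S += 1
            ns.append(n)
    if S == 0:
        return 0.0
    n_med = int(np.median(ns))
    a = sum(1.0 / i for i in range(1, n_med))
    return S / (a * window_length)


def wc84_site(ga, gb):
    """WC84 a, b, c for one site and two pops (direct transcription)."""
    def stats(g):
        alleles, het = [], 0
        n_ind = 0
        for code in g:
            a = alleles_of(int(code))
            if a is None:
                continue
            n_ind += 1
            alleles.extend(a)
            het += a[0] != a[1]
        return n_ind, (sum(alleles) / len(alleles) if alleles else None), \
            (het / n_ind if n_ind else None)

    n1, p1, h1 = stats(ga)
    n2, p2, h2 = stats(gb)
    if n1 < 1 or n2 < 1 or n1 + n2 < 2:
        return None
    r = 2
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return None
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    if pbar in (0.0, 1.0):
        return None
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def brute_fst(ga, gb):
    """Ratio of summed WC84 components over usable sites."""
    num = den = 0.0
    any_site = False
    for j in range(ga.shape[1]):
        res = wc84_site(ga[:, j], gb[:, j])
        if res is None:
            continue
        any_site = True
        a, b, c = res
        num += a
        den += a + b + c
    if not any_site or den == 0:
        return None
    return num / den


def sweep_prob_enumeration(k, n, pe, phi):
    """Exhaustive enumeration of the star-like sweep model.

    phi: background probabilities over derived counts 1..n-1.
    """
    full = np.zeros(n + 1)
    full[1:n] = phi
    mass = np.zeros(n + 1)
    for b in range(n + 1):
        wb = binom.pmf(b, n, pe)
        if wb == 0:
            continue
        if b == n:
            mass += wb * full
            continue
        m = b + 1
        for kp in range(m + 1):
            pr = sum(full[kk] * hypergeom.pmf(kp, n, kk, m) for kk in range(n + 1))
            if pr == 0:
                continue
            p_trapped_derived = kp / m
            if kp >= 1:
                mass[kp - 1 + n - b] += wb * pr * p_trapped_derived
            mass[kp] += wb * pr * (1 - p_trapped_derived)
    poly = mass[1:n].sum()
    return mass[k] / poly if poly > 0 else 0.0


def random_additive_distance(n, rng):
    """Distance matrix of a random binary tree with random edge lengths."""
    active = list(range(n))
    leafdist = {i: {i: 0.0} for i in range(n)}
    dist = np.zeros((n, n))
    nxt = n
    while len(active) > 1:
        i, j = rng.choice(len(active), 2, replace=False)
        a, b = active[i], active[j]
        la, lb = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        for x, dx in leafdist[a].items():
            for y, dy in leafdist[b].items():
                dist[x, y] = dist[y, x] = dx + la + dy + lb
        leafdist[nxt] = {x: d + la for x, d in leafdist[a].items()}
        leafdist[nxt].update({y: d + lb for y, d in leafdist[b].items()})
        active = [v for v in active if v not in (a, b)] + [nxt]
        nxt += 1
    return dist


def tree_pairwise_distances(tree):
    """Leaf-to-leaf path lengths, via per-edge bipartition contributions."""
    leaves = sorted(tree.leaf_names())
    idx = {l: i for i, l in enumerate(leaves)}
    M = np.zeros((len(leaves), len(leaves)))
    allset = set(leaves)

    def walk(node):
        if node.is_leaf:
            return {node.name}
        below = set()
        for c in node.children:
            sub = walk(c)
            for x in sub:
                for y in allset - sub:
                    M[idx[x], idx[y]] += c.length
                    M[idx[y], idx[x]] += c.length
            below |= sub
        return below

    walk(tree)
    return leaves, M
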