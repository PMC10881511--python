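"""Neighbor-joining phylogeny on homozygous SNP matrices, with bootstrap.

Sites are restricted to those homozygous and non-missing in every sample
(each sample then contributes one base per site), pairwise distances are
mismatch fractions with optional Jukes-Cantor correction, trees come from
Saitou-Nei neighbor joining, and internal-edge supports from site
resampling. The unrooted NJ tree is represented with a trifurcating root;
outgroup rooting splits the edge separating the outgroup.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .core_io import GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "Node",
    "select_tree_sites",
    "pairwise_distance",
    "nj",
    "bootstrap_support",
    "clade_support",
    "root_with_outgroup",
    "write_newick",
    "to_newick",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")
        if (m < -1e-12).any():
            raise ValueError("negative distances")


@dataclass(eq=False)
class Node:
    """Tree node; ``length`` is the branch to the parent, ``support`` in %."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(n.name for n in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def total_length(self) -> float:
        return sum(n.length for n in self.walk() if n is not self)


# ---------------------------------------------------------------------------
# site selection and distances
# ---------------------------------------------------------------------------


def select_tree_sites(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep sites homozygous (code 0 or 2) in every sample."""
    ok = ((gm.geno == 0) | (gm.geno == 2)).all(axis=0)
    if not ok.any():
        raise ValueError(
            "no homozygous complete site retained; check input filtering"
        )
    return gm.take_sites(ok)


def pairwise_distance(gm: GenotypeMatrix, model: str = "jc",
                      weights: np.ndarray | None = None) -> DistanceMatrix:
    """Pairwise distances over a homozygous complete matrix.

    ``p`` is the mismatch fraction (one base per sample per site);
    ``jc`` applies the Jukes-Cantor correction -(3/4) ln(1 - 4p/3).
    ``weights`` are per-site multiplicities (used by the bootstrap).
    """
    if model not in ("p", "jc"):
        raise ValueError(f"unknown model {model!r}")
    g = gm.geno
    if not ((g == 0) | (g == 2)).all():
        raise ValueError("matrix contains het or missing calls; "
                         "run select_tree_sites first")
    a = (g == 2).astype(np.float64)
    if weights is None:
        weights = np.ones(gm.n_sites)
    total = float(weights.sum())
    if total == 0:
        raise ValueError("zero total site weight")
    aw = a * weights[None, :]
    # mismatch(i,j) = sum_s w_s * (a_i + a_j - 2 a_i a_j)
    row = aw.sum(axis=1)
    cross = aw @ a.T
    mism = row[:, None] + row[None, :] - cross - cross.T
    p = mism / total
    np.fill_diagonal(p, 0.0)
    if model == "p":
        d = p
    else:
        if (p >= 0.75 - 1e-15).any():
            i, j = np.unravel_index(np.argmax(p), p.shape)
            raise ValueError(
                f"p >= 3/4 between {gm.sample_ids[i]!r} and "
                f"{gm.sample_ids[j]!r}: Jukes-Cantor distance undefined "
                "(saturated pair; consider model='p' or excluding the taxon)"
            )
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
        np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(gm.sample_ids), d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj(dm: DistanceMatrix) -> Node:
    """Saitou-Nei neighbor joining; returns a trifurcating unrooted root.

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sister edge (their sum is preserved), so additive matrices
    are recovered exactly.
    """
    m = len(dm.labels)
    if m < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [Node(name=l) for l in dm.labels]
    D = dm.matrix.copy()
    active = list(range(m))
    while len(active) > 3:
        a = np.array(active)
        sub = D[np.ix_(a, a)]
        r = sub.sum(axis=1)
        mm = len(a)
        Q = (mm - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        i, j = a[i_], a[j_]
        dij = D[i, j]
        li = dij / 2.0 + (r[i_] - r[j_]) / (2.0 * (mm - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        if lj < 0:
            li, lj = dij, 0.0
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        new = Node(children=[ni, nj_])
        newdist = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            newdist[k] = (D[i, k] + D[j, k] - dij) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newdist
        D[:-1, -1] = newdist
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    i, j, k = active
    li = (D[i, j] + D[i, k] - D[j, k]) / 2.0
    lj = (D[i, j] + D[j, k] - D[i, k]) / 2.0
    lk = (D[i, k] + D[j, k] - D[i, j]) / 2.0
    for idx, ln in zip((i, j, k), (li, lj, lk)):
        nodes[idx].length = max(ln, 0.0)
    return Node(children=[nodes[i], nodes[j], nodes[k]])


# ---------------------------------------------------------------------------
# bipartitions and bootstrap
# ---------------------------------------------------------------------------


def _canonical(side: frozenset, all_leaves: frozenset):
    comp = all_leaves - side
    return min(tuple(sorted(side)), tuple(sorted(comp)))


def bipartitions(tree: Node) -> dict:
    """Canonical internal bipartitions -> node carrying the edge."""
    all_leaves = tree.leaf_names()
    out = {}
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        out[_canonical(node.leaf_names(), all_leaves)] = node
    return out


def _replicate_trees(gm: GenotypeMatrix, B: int, seed: int, model: str):
    rng = np.random.default_rng(seed)
    S = gm.n_sites
    for _ in range(B):
        w = rng.multinomial(S, np.full(S, 1.0 / S)).astype(np.float64)
        dm = pairwise_distance(gm, model=model, weights=w)
        yield nj(dm)


def bootstrap_support(gm: GenotypeMatrix, B: int = 100, seed: int = 0,
                      model: str = "jc") -> Node:
    """NJ tree with internal-edge supports from ``B`` site resamples.

    Support is the percentage of replicates whose NJ tree contains the same
    bipartition.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    gm = select_tree_sites(gm)
    tree = nj(pairwise_distance(gm, model=model))
    bips = bipartitions(tree)
    counts = dict.fromkeys(bips, 0)
    all_leaves = tree.leaf_names()
    for rep in _replicate_trees(gm, B, seed, model):
        rep_bips = set()
        for node in rep.walk():
            if node is rep or node.is_leaf:
                continue
            rep_bips.add(_canonical(node.leaf_names(), all_leaves))
        for b in counts:
            if b in rep_bips:
                counts[b] += 1
    for b, node in bips.items():
        node.support = 100.0 * counts[b] / B
    return tree


def clade_support(gm: GenotypeMatrix, in_taxa, out_taxa, B: int = 100,
                  seed: int = 0, model: str = "jc") -> float:
    """Percent of bootstrap replicates in which some clade separates
    all ``in_taxa`` from all ``out_taxa``.

    This is a monophyly-style support, robust to unstable placement of taxa
    outside both sets (e.g. recent hybrids of the two sides).
    """
    gm = select_tree_sites(gm)
    in_set, out_set = set(in_taxa), set(out_taxa)
    hits = 0
    for rep in _replicate_trees(gm, B, seed, model):
        all_leaves = rep.leaf_names()
        found = False
        for node in rep.walk():
            if node is rep:
                continue
            side = node.leaf_names()
            for s in (side, all_leaves - side):
                if in_set <= s and not (out_set & s):
                    found = True
                    break
            if found:
                break
        hits += found
    return 100.0 * hits / B


# ---------------------------------------------------------------------------
# rooting and Newick output
# ---------------------------------------------------------------------------


def smallest_clade_containing(tree: Node, taxa) -> Node:
    """Smallest clade (by leaf count) whose leaf set contains ``taxa``."""
    taxa = set(taxa)
    best = tree
    for node in tree.walk():
        names = node.leaf_names()
        if taxa <= names and len(names) < len(best.leaf_names()):
            best = node
    return best


def root_with_outgroup(tree: Node, outgroup_samples) -> Node:
    """Root on the edge separating the outgroup; errors if not monophyletic."""
    out_set = frozenset(outgroup_samples)
    all_leaves = tree.leaf_names()
    if not out_set or not out_set <= all_leaves:
        raise ValueError("outgroup samples missing from tree")
    tree = copy.deepcopy(tree)
    target = None
    for node in tree.walk():
        if node is tree:
            continue
        side = node.leaf_names()
        if side == out_set or side == all_leaves - out_set:
            target = node
            break
    if target is None:
        raise ValueError(
            f"outgroup not monophyletic in the unrooted tree: {sorted(out_set)}"
        )
    parents = {}
    for node in tree.walk():
        for c in node.children:
            parents[c] = node
    half = target.length / 2.0
    sup = target.support
    parent = parents[target]
    parent.children.remove(target)
    target.length = half
    # invert the chain from parent back to the old (trifurcating) root
    chain = [parent]
    while chain[-1] is not tree:
        chain.append(parents[chain[-1]])
    upper = parent
    carry_len, carry_sup = half, sup
    prev = None
    for node in chain:
        if prev is not None:
            node.children.remove(prev)
        prev_len, prev_sup = node.length, node.support
        node.length, node.support = carry_len, carry_sup
        carry_len, carry_sup = prev_len, prev_sup
        if prev is not None:
            prev.children.append(node)
        prev = node
    new_root = Node(children=[target, upper])
    # a trifurcating NJ root keeps >= 2 children after the inversion; if a
    # binary-rooted tree was passed, splice out the resulting degree-1 node
    old_root = chain[-1]
    if len(old_root.children) == 1:
        child = old_root.children[0]
        child.length += old_root.length
        for n in new_root.walk():
            if old_root in n.children:
                n.children[n.children.index(old_root)] = child
                break
    return new_root


def to_newick(tree: Node) -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            body = f"({inner}){label}"
        return body + f":{node.length:.8g}"

    inner = ",".join(fmt(c) for c in tree.children)
    label = "" if tree.support is None else f"{tree.support:g}"
    return f"({inner}){label};"


def write_newick(tree: Node, path) -> None:
    """Write Newick with branch lengths and percent supports as node labels."""
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
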