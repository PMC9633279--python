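"""Individual-level p-distance matrices and neighbor-joining trees.

The p-distance between two diploid individuals is the mean, over
pairwise-complete sites, of |g_i − g_j| / 2 — the proportion of allele
differences under dosage coding (so opposite homozygotes are at distance 1,
a homozygote and a heterozygote at 1/2, two heterozygotes at 0 by default;
the het–het convention is configurable).  The tree is built with the classic
Saitou–Nei neighbor-joining agglomeration, which is exact on additive
distance matrices.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "p_distance_matrix",
    "neighbor_joining",
    "to_newick",
    "write_newick",
    "tree_distance_matrix",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with sample labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if np.any(self.d < 0):
            raise ValueError("negative distances")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("asymmetric distance matrix")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in df.columns], d=df.to_numpy())


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree represented with an arbitrary internal node as root."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.name or "")
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out


def p_distance_matrix(gm: GenotypeMatrix, het_het: float = 0.0) -> DistanceMatrix:
    """Pairwise p-distances d(i,j) = mean over shared sites of |g_i − g_j|/2.

    ``het_het`` overrides the per-site distance when both individuals are
    heterozygous (0 under the plain dosage-difference convention; 0.5 under
    the allele-mismatch-probability convention).  A pair with no shared
    non-missing site is an error.
    """
    n = gm.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    g = gm.dosage.astype(float)
    called = gm.dosage != MISSING
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = called[i] & called[j]
            if not ok.any():
                raise ValueError(
                    f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share no called site"
                )
            per_site = np.abs(g[i, ok] - g[j, ok]) / 2.0
            if het_het != 0.0:
                both_het = (gm.dosage[i, ok] == 1) & (gm.dosage[j, ok] == 1)
                per_site[both_het] = het_het
            d[i, j] = d[j, i] = per_site.mean()
    return DistanceMatrix(labels=list(gm.samples), d=d)


def _min_leaf(node: TreeNode) -> str:
    if node.is_leaf:
        return node.name or ""
    return min(_min_leaf(child) for child, _ in node.children)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    Repeatedly joins the pair minimising
    Q(i,j) = (r−2)·d(i,j) − R_i − R_j (R the row sums over active nodes),
    with ties broken by the lexicographically smallest pair of subtree labels.
    Negative branch lengths are clamped to 0.  Exact on additive matrices.
    """
    r = len(dm.labels)
    if r < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    keys: list[str] = [lab for lab in dm.labels]
    d = dm.d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        rowsum = d.sum(axis=1)
        best: tuple | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - rowsum[i] - rowsum[j]
                tie_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (rowsum[i] - rowsum[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [_min_leaf(parent)]
        d = d2
    # terminal 3-star: closed-form branch lengths
    (x, y, z) = nodes
    lx = max(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]), 0.0)
    ly = max(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]), 0.0)
    lz = max(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]), 0.0)
    root = TreeNode(children=[(x, lx), (y, ly), (z, lz)])
    return Tree(root=root)


_NEWICK_UNSAFE = set(" \t\n()[]{}':;,")


def _quote(label: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: Tree, sigfigs: int = 6) -> str:
    fmt = f"%.{sigfigs}g"

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote(node.name or "")
        inner = ",".join(f"{render(c)}:{fmt % ln}" for c, ln in node.children)
        return f"({inner})"

    return render(tree.root) + ";"


def write_newick(tree: Tree, path, sigfigs: int = 6) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_newick(tree, sigfigs=sigfigs) + "\n")


def tree_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances induced by the tree's branch lengths."""
    leaf_depth: dict[str, float] = {}
    leaf_path: dict[str, list[tuple[int, float]]] = {}

    def walk2(node: TreeNode, depth: float, chain: list[tuple[int, float]]) -> None:
        chain = chain + [(id(node), depth)]
        if node.is_leaf:
            leaf_depth[node.name or ""] = depth
            leaf_path[node.name or ""] = chain
        for child, ln in node.children:
            walk2(child, depth + ln, chain)

    walk2(tree.root, 0.0, [])
    labels = sorted(leaf_depth)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ci = {nid: dep for nid, dep in leaf_path[labels[i]]}
            lca_depth = max(dep for nid, dep in leaf_path[labels[j]] if nid in ci)
            d[i, j] = d[j, i] = leaf_depth[labels[i]] + leaf_depth[labels[j]] - 2 * lca_depth
    return DistanceMatrix(labels=labels, d=d)
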