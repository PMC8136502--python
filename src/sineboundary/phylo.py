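"""Pairwise p-distances and neighbor-joining trees.

The classic Saitou-Nei agglomeration over a symmetric distance matrix;
on additive matrices the tree reproduces all pairwise path lengths exactly.
Negative branch-length estimates are clamped to zero and the total clamped
deficit is recorded on the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import CLASSIFY_SCORING, global_align


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # substitutions per site

    def validate(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("p-distances must lie in [0, 1]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.matrix[i, j])


def p_distance(a: str, b: str) -> float:
    """Mismatches over aligned (non-gap) sites of a global pairwise alignment."""
    if not a or not b:
        raise ValueError("empty sequence")
    aln = global_align(a.upper(), b.upper(), CLASSIFY_SCORING)
    qi = si = cols = mism = 0
    for op, n in aln.ops:
        if op == "M":
            cols += n
            mism += sum(
                1 for x, y in zip(a[qi : qi + n].upper(), b[si : si + n].upper())
                if x != y
            )
            qi += n
            si += n
        elif op == "D":
            qi += n
        else:
            si += n
    return mism / cols if cols else 0.0


def p_distance_matrix(seqs: dict[str, str] | list[str]) -> DistanceMatrix:
    if isinstance(seqs, dict):
        labels, sequences = list(seqs), list(seqs.values())
    else:
        labels = [f"seq{i}" for i in range(len(seqs))]
        sequences = list(seqs)
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(sequences)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = p_distance(sequences[i], sequences[j])
    dm = DistanceMatrix(labels, m)
    dm.validate()
    return dm


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree rendered from a degree-3 root (standard NJ output)."""

    root: TreeNode
    clamped_deficit: float = 0.0  # total negative branch length clamped to 0

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf():
                out.append(node.name)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return sorted(out)

    def newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf():
                return node.name
            inner = ",".join(
                f"{render(child)}:{length:.10g}" for child, length in node.children
            )
            return f"({inner})"

        return render(self.root) + ";"

    def leaf_distances(self) -> DistanceMatrix:
        """Path lengths between every leaf pair (for additivity checks)."""
        rows: dict[str, dict[str, float]] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            # distances from every leaf under `node` up to `node`
            if node.is_leaf():
                return {node.name: 0.0}
            below: list[dict[str, float]] = []
            for child, length in node.children:
                sub = walk(child)
                below.append({k: v + length for k, v in sub.items()})
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for a, da in below[i].items():
                        for b, db in below[j].items():
                            rows.setdefault(a, {})[b] = da + db
                            rows.setdefault(b, {})[a] = da + db
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self.root)
        labels = self.leaves()
        n = len(labels)
        m = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    m[i, j] = rows[a][b]
        return DistanceMatrix(labels, m)

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions (one side listed), for topology comparison."""
        all_leaves = frozenset(self.leaves())
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                canon = below if sorted(below)[0] <= sorted(other)[0] else other
                out.add(canon)
            return below

        for child, _ in self.root.children:
            walk(child)
        return out


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining."""
    d.validate()
    n = len(d.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in d.labels]
    dist = d.matrix.astype(float).copy()
    active = list(range(n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        i, j = active[i_], active[j_]
        dij = dist[i, j]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        # distances from the new node to the remaining ones
        new_row = np.zeros(dist.shape[0] + 1)
        for k_, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (dist[i, k] + dist[j, k] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row[:-1]
        dist[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [dist.shape[0] - 1]

    # final 3-way join by the three-point formulas
    a, b, c = active
    dab, dac, dbc = dist[a, b], dist[a, c], dist[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = TreeNode(
        children=[(nodes[a], clamp(la)), (nodes[b], clamp(lb)), (nodes[c], clamp(lc))]
    )
    return Tree(root=root, clamped_deficit=deficit)
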