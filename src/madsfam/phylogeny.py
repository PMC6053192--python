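"""Distance phylogeny: p-distance, neighbor joining, bootstrap, clade calls.

Distances are uncorrected p-distances (proportion of differing sites) with
pairwise or complete gap deletion; trees are built with the Saitou–Nei
neighbor-joining algorithm.  Negative NJ branch-length estimates are clamped
to zero for output with the raw estimate retained (the display convention of
MEGA).  Bootstrap supports are obtained by resampling alignment columns with
replacement and mapping bipartition frequencies onto the full-data tree; no
majority-rule consensus is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

GAP_CHARS = set("-.")

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "p_distance",
    "neighbor_joining",
    "bootstrap_support",
    "assign_clades",
]


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with named taxa.

    ``missing`` holds taxon pairs with zero comparable sites under pairwise
    deletion (their entries are NaN).
    """

    taxa: list[str]
    matrix: np.ndarray
    missing: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(np.nan_to_num(m), np.nan_to_num(m.T)):
            raise ValueError("distance matrix must be symmetric")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)


@dataclass
class TreeNode:
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0       # branch length to parent, clamped >= 0
    raw_length: float = 0.0   # NJ estimate before clamping
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary (trifurcating) root."""

    root: TreeNode

    def leaf_names(self) -> frozenset:
        return self.root.leaf_names()

    def internal_nodes(self) -> list[TreeNode]:
        out = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            if not n.is_leaf() and n is not self.root:
                out.append(n)
            stack.extend(n.children)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the canonical side (the side
        not containing the lexicographically smallest leaf)."""
        all_leaves = self.leaf_names()
        anchor = min(all_leaves)
        out = set()
        for node in self.internal_nodes():
            side = node.leaf_names()
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def clade_sides(self) -> list[frozenset]:
        """Every edge side of the unrooted tree, as leaf sets (both sides of
        every edge), smallest first."""
        all_leaves = self.leaf_names()
        sides = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            for c in n.children:
                s = c.leaf_names()
                if 0 < len(s) < len(all_leaves):
                    sides.add(s)
                    sides.add(all_leaves - s)
                stack.append(c)
        return sorted(sides, key=lambda s: (len(s), sorted(s)))

    def path_distances(self) -> dict[frozenset, float]:
        """Leaf-to-leaf path lengths (using clamped branch lengths)."""
        # depth-first accumulation of distances from every leaf
        adj: dict[int, list[tuple[int, float]]] = {}
        nodes: list[TreeNode] = []

        def index(n: TreeNode) -> int:
            nodes.append(n)
            return len(nodes) - 1

        def walk(n: TreeNode, idx: int):
            for c in n.children:
                ci = index(c)
                adj.setdefault(idx, []).append((ci, c.length))
                adj.setdefault(ci, []).append((idx, c.length))
                walk(c, ci)

        ri = index(self.root)
        walk(self.root, ri)
        leaf_idx = [i for i, n in enumerate(nodes) if n.is_leaf()]
        out: dict[frozenset, float] = {}
        for i in leaf_idx:
            dist = {i: 0.0}
            stack = [i]
            while stack:
                u = stack.pop()
                for v, w in adj.get(u, []):
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j in leaf_idx:
                if j != i:
                    out[frozenset((nodes[i].name, nodes[j].name))] = dist[j]
        return out

    def newick(self, with_support: bool = False) -> str:
        def fmt(n: TreeNode) -> str:
            if n.is_leaf():
                return f"{n.name}:{n.length:.6f}"
            inner = ",".join(fmt(c) for c in n.children)
            label = ""
            if with_support and n.support is not None:
                label = f"{n.support:g}"
            return f"({inner}){label}:{n.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def p_distance(msa: dict[str, str], deletion: str = "pairwise"
               ) -> DistanceMatrix:
    """Proportion of differing sites between every pair of aligned rows.

    ``pairwise`` deletion compares, per pair, only the sites where neither
    row is gapped; ``complete`` deletion restricts every comparison to
    globally ungapped columns.  Pairs with no comparable site get NaN and are
    recorded in ``missing``.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    taxa = list(msa)
    if len(taxa) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("alignment is not rectangular")
    arr = np.array([list(msa[t]) for t in taxa])
    gap = np.isin(arr, list(GAP_CHARS))
    if deletion == "complete":
        keep = ~gap.any(axis=0)
        arr = arr[:, keep]
        gap = gap[:, keep]
    n = len(taxa)
    d = np.zeros((n, n))
    missing: set[frozenset] = set()
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            m = int(ok.sum())
            if m == 0:
                d[i, j] = d[j, i] = np.nan
                missing.add(frozenset((taxa[i], taxa[j])))
            else:
                diff = int((arr[i, ok] != arr[j, ok]).sum())
                d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(taxa=taxa, matrix=d, missing=missing)


def _node_key(node: TreeNode) -> str:
    return min(l.name for l in node.leaves())


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    Q-matrix ties are broken by the lexicographically smallest pair of
    subtree labels (the smallest leaf name under each working node), so the
    result is independent of input order.  Requires a complete matrix;
    missing entries abort with an instruction to rerun with complete
    deletion.
    """
    if len(dm.taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dm.missing or np.isnan(dm.matrix).any():
        raise ValueError(
            "distance matrix has missing entries (pairs with no comparable "
            "sites); recompute distances with complete deletion")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    d: dict[tuple[int, int], float] = {}
    for i in range(len(dm.taxa)):
        for j in range(i + 1, len(dm.taxa)):
            d[(i, j)] = float(dm.matrix[i, j])

    def dist(i: int, j: int) -> float:
        return d[(i, j) if i < j else (j, i)]

    active = list(range(len(nodes)))
    next_id = len(nodes)
    node_of: dict[int, TreeNode] = {i: nodes[i] for i in active}
    key_of: dict[int, str] = {i: nodes[i].name for i in active}

    while len(active) > 3:
        r = len(active)
        R = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dist(i, j) - R[i] - R[j]
                key = tuple(sorted((key_of[i], key_of[j])))
                cand = (q, key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * dist(i, j) + (R[i] - R[j]) / (2 * (r - 2))
        lj = dist(i, j) - li
        ni, nj = node_of[i], node_of[j]
        ni.raw_length, nj.raw_length = li, lj
        ni.length, nj.length = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[ni, nj])
        u = next_id
        next_id += 1
        node_of[u] = parent
        key_of[u] = min(key_of[i], key_of[j])
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
            d[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    # final trifurcation
    a, b, c = active
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = TreeNode()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        n = node_of[k]
        n.raw_length = lk
        n.length = max(lk, 0.0)
        root.children.append(n)
    # deterministic child order
    root.children.sort(key=_node_key)
    return Tree(root=root)


def bootstrap_support(msa: dict[str, str], n_reps: int = 1000,
                      seed: int | None = None,
                      deletion: str = "pairwise") -> Tree:
    """NJ tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of each internal edge of the full-data tree is the percentage of
    replicate trees containing the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(p_distance(msa, deletion))
    taxa = list(msa)
    length = len(next(iter(msa.values())))
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        rep = {t: "".join(msa[t][c] for c in cols) for t in taxa}
        try:
            rep_tree = neighbor_joining(p_distance(rep, deletion))
        except ValueError:
            continue  # replicate with a missing pair is skipped
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_leaves = tree.leaf_names()
    anchor = min(all_leaves)
    for node in tree.internal_nodes():
        side = node.leaf_names()
        if anchor in side:
            side = all_leaves - side
        if side in counts:
            node.support = 100.0 * counts[side] / n_reps
    return tree


def assign_clades(tree: Tree, reference_labels: dict[str, str]
                  ) -> dict[str, str]:
    """Assign each non-reference leaf the subfamily of its nearest references.

    For each gene the smallest clade (edge side of the unrooted tree)
    containing the gene and at least one reference taxon is found; the gene
    receives that clade's subfamily if all references inside belong to a
    single subfamily, otherwise ``"unassigned"``.
    """
    present = tree.leaf_names()
    refs = {t: lab for t, lab in reference_labels.items() if t in present}
    if not refs:
        raise ValueError("no reference taxon present in the tree")
    sides = tree.clade_sides()
    out: dict[str, str] = {}
    for gene in sorted(present - set(refs)):
        label = "unassigned"
        for side in sides:  # smallest first
            if gene not in side:
                continue
            inside = {refs[t] for t in side if t in refs}
            if not inside:
                continue
            label = inside.pop() if len(inside) == 1 else "unassigned"
            break
        out[gene] = label
    return out
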