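"""Working phylogenies and per-column parsimony substitution counts.

The aggregation layer needs, for every base pair, the minimum number of
substitutions implied by the alignment on a tree (the Lancaster weight).
A neighbor-joining tree on Jukes-Cantor distances is entirely adequate for
that purpose — only integer Fitch counts are consumed downstream, never the
branch lengths themselves — so no likelihood-based inference is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from helixcov.msa_io import Alignment

#: JC69 distance assigned when the mismatch fraction saturates (>= 0.75)
MAX_JC_DISTANCE = 3.0


@dataclass
class PhyloTree:
    """A rooted binary tree over the alignment's sequence names.

    Nodes ``0 .. n_leaves-1`` are the leaves (in ``leaf_names`` order);
    internal nodes follow. ``parent[k]`` is the parent of node ``k`` (-1 for
    the root) and ``branch_lengths[k]`` the length of the edge above ``k``
    in expected substitutions per site.
    """

    leaf_names: list[str]
    parent: np.ndarray
    branch_lengths: np.ndarray

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)
        if self.parent.shape != self.branch_lengths.shape:
            raise ValueError("parent and branch_lengths must have the same shape")
        if (self.parent == -1).sum() != 1:
            raise ValueError("tree must have exactly one root")
        if not np.all(np.isfinite(self.branch_lengths)) or np.any(self.branch_lengths < 0):
            raise ValueError("branch lengths must be finite and >= 0")
        n = self.n_nodes
        if np.any((self.parent < -1) | (self.parent >= n)):
            raise ValueError("parent indices out of range")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for k, p in enumerate(self.parent):
            if p >= 0:
                out[int(p)].append(k)
        return out

    def postorder(self) -> list[int]:
        """Node indices, children always before parents."""
        children = self.children()
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(children[node])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    # -- Newick interchange (via scikit-bio) --------------------------------

    def to_skbio(self):
        from skbio import TreeNode

        children = self.children()

        def build(k: int) -> "TreeNode":
            node = TreeNode(
                name=self.leaf_names[k] if k < self.n_leaves else None,
                length=float(self.branch_lengths[k]) if self.parent[k] >= 0 else None,
            )
            for c in children[k]:
                node.append(build(c))
            return node

        return build(self.root)

    @classmethod
    def from_skbio(cls, tree) -> "PhyloTree":
        leaves = list(tree.tips())
        leaf_names = [t.name for t in leaves]
        index: dict[int, int] = {id(t): i for i, t in enumerate(leaves)}
        nodes = [n for n in tree.postorder() if not n.is_tip()]
        for n in nodes:
            index[id(n)] = len(index)
        n_nodes = len(index)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        lengths = np.zeros(n_nodes, dtype=float)
        for node in tree.postorder():
            k = index[id(node)]
            if node.parent is not None:
                parent[k] = index[id(node.parent)]
                lengths[k] = max(0.0, float(node.length or 0.0))
        return cls(leaf_names=leaf_names, parent=parent, branch_lengths=lengths)

    def to_newick(self) -> str:
        import io

        buf = io.StringIO()
        self.to_skbio().write(buf, format="newick")
        return buf.getvalue().strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def read_newick(cls, path) -> "PhyloTree":
        from skbio import TreeNode

        return cls.from_skbio(TreeNode.read(str(path), format="newick"))


def jc_distance_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise Jukes-Cantor distances, gaps/N excluded pairwise.

    Saturated pairs (mismatch fraction >= 0.75) are capped at
    ``MAX_JC_DISTANCE`` with a warning; a pair with no overlapping ungapped
    columns is an error.
    """
    mat = aln.to_matrix()
    n = aln.n_seqs
    valid = mat != 4
    dist = np.zeros((n, n), dtype=float)
    saturated = False
    for a in range(n):
        for b in range(a + 1, n):
            both = valid[a] & valid[b]
            n_both = int(both.sum())
            if n_both == 0:
                raise ValueError(
                    f"sequences {aln.names[a]!r} and {aln.names[b]!r} share no "
                    "ungapped columns; cannot compute a distance"
                )
            p = float((mat[a, both] != mat[b, both]).sum()) / n_both
            if p >= 0.75:
                saturated = True
                d = MAX_JC_DISTANCE
            else:
                d = -0.75 * np.log1p(-4.0 * p / 3.0)
            dist[a, b] = dist[b, a] = d
    if saturated:
        warnings.warn(
            f"saturated JC distance(s) capped at {MAX_JC_DISTANCE}", RuntimeWarning
        )
    return dist


def build_nj_tree(aln: Alignment) -> PhyloTree:
    """Neighbor-joining tree on JC-corrected distances, midpoint-rooted.

    Negative NJ branch lengths are clamped to zero. Deterministic given the
    alignment's sequence order.
    """
    if aln.n_seqs < 2:
        raise ValueError("need at least 2 sequences to build a tree")
    dist = jc_distance_matrix(aln)
    if aln.n_seqs == 2:
        half = dist[0, 1] / 2.0
        return PhyloTree(
            leaf_names=list(aln.names),
            parent=np.array([2, 2, -1]),
            branch_lengths=np.array([half, half, 0.0]),
        )
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(dist, ids=aln.names)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    try:
        tree = tree.root_at_midpoint()
    except Exception:  # zero-length trees cannot be midpoint rooted; keep as-is
        pass
    ptree = resolve_multifurcations(PhyloTree.from_skbio(tree))
    _require_binary(ptree)
    return ptree


def resolve_multifurcations(tree: PhyloTree) -> PhyloTree:
    """Arbitrarily resolve nodes with more than two children by chaining the
    extra children below zero-length internal edges (parsimony-neutral)."""
    children = tree.children()
    if all(len(k) in (0, 2) for k in children):
        return tree
    parent = list(tree.parent)
    lengths = list(tree.branch_lengths)
    for node in range(tree.n_nodes):
        kids = children[node]
        while len(kids) > 2:
            a = kids.pop()
            b = kids.pop()
            new = len(parent)
            parent.append(node)
            lengths.append(0.0)
            for c in (a, b):
                parent[c] = new
                # c keeps its own branch length
            kids.append(new)
    return PhyloTree(
        leaf_names=list(tree.leaf_names),
        parent=np.asarray(parent),
        branch_lengths=np.asarray(lengths),
    )


def _require_binary(tree: PhyloTree) -> None:
    """Verify the tree is usable for Fitch counting (binary internal nodes)."""
    for node, kids in enumerate(tree.children()):
        if kids and len(kids) != 2:
            raise ValueError(
                f"internal node {node} has {len(kids)} children; Fitch counting "
                "requires a binary tree (see resolve_multifurcations)"
            )


def _leaf_order_for(tree: PhyloTree, aln: Alignment) -> np.ndarray:
    if set(tree.leaf_names) != set(aln.names):
        raise ValueError("tree leaf set does not match alignment sequence names")
    name_to_row = {n: r for r, n in enumerate(aln.names)}
    return np.array([name_to_row[n] for n in tree.leaf_names], dtype=np.int64)


def fitch_counts(tree: PhyloTree, aln: Alignment) -> np.ndarray:
    """Fitch small-parsimony substitution counts for every column at once.

    Gaps and N are missing data: such leaves carry the full state set
    {A, C, G, U} and never force a substitution. Returns an int array of
    length ``aln.length`` (1-based column c is entry c-1). Multifurcating
    trees are resolved with zero-length edges first (parsimony-neutral).
    """
    tree = resolve_multifurcations(tree)
    _require_binary(tree)
    mat = aln.to_matrix()[_leaf_order_for(tree, aln)]
    L = aln.length
    n_nodes = tree.n_nodes
    # bitmask state sets: bit k = residue k present; 15 = wildcard (missing)
    masks = np.zeros((n_nodes, L), dtype=np.uint8)
    leaf_masks = np.where(mat == 4, 15, np.left_shift(1, mat.astype(np.int32))).astype(np.uint8)
    masks[: tree.n_leaves] = leaf_masks
    counts = np.zeros(L, dtype=np.int64)
    children = tree.children()
    for node in tree.postorder():
        kids = children[node]
        if not kids:
            continue
        a, b = masks[kids[0]], masks[kids[1]]
        inter = a & b
        empty = inter == 0
        counts += empty
        masks[node] = np.where(empty, a | b, inter)
    all_missing = np.all(mat == 4, axis=0)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} column(s) contain only gaps/N; "
            "their substitution count is 0",
            RuntimeWarning,
        )
    return counts


def fitch_column_count(tree: PhyloTree, aln: Alignment, col: int) -> int:
    """Fitch parsimony substitution count for one 1-based column."""
    if not 1 <= col <= aln.length:
        raise IndexError(f"column {col} out of range 1..{aln.length}")
    return int(fitch_counts(tree, aln)[col - 1])


def pair_substitution_count(tree: PhyloTree, aln: Alignment, pair: tuple[int, int]) -> int:
    """Substitutions for a base pair: the sum of its two per-column Fitch counts."""
    i, j = pair
    counts = fitch_counts(tree, aln)
    if not (1 <= i <= aln.length and 1 <= j <= aln.length):
        raise IndexError(f"pair ({i}, {j}) out of range 1..{aln.length}")
    return int(counts[i - 1] + counts[j - 1])
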