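"""Neighbor-joining tree construction, bootstrap supports and monophyly tests.

Trees are unrooted; the stored root is merely the last join and carries no
biological meaning.  Monophyly is therefore the bipartition criterion: a tip
set is a clade iff it (or its complement) is exactly one side of some edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .distances import DistanceMatrix, distances_from_codes
from .errors import DegenerateAlignmentError, InputError
from .io_formats import LocusAlignment


@dataclass
class Node:
    name: Optional[str] = None
    length: Optional[float] = None  # edge length to parent; None for the root
    support: Optional[float] = None  # bootstrap percentage on the parent edge
    children: list["Node"] = field(default_factory=list)

    def add_child(self, child: "Node") -> None:
        self.children.append(child)

    @property
    def is_tip(self) -> bool:
        return not self.children


class BarcodeTree:
    """Unrooted tree over sample ids with branch lengths in subs/site."""

    def __init__(self, root: Node):
        self.root = root
        self._tipsets: Optional[dict[int, frozenset[str]]] = None

    # -- traversal -------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[str]:
        return [n.name for n in self.preorder() if n.is_tip]

    @property
    def tip_set(self) -> frozenset[str]:
        return frozenset(self.tips())

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.preorder() if n is not self.root)

    # -- bipartitions ----------------------------------------------------
    def _tipset_below(self) -> dict[int, frozenset[str]]:
        if self._tipsets is None:
            sets: dict[int, frozenset[str]] = {}

            def walk(node: Node) -> frozenset[str]:
                if node.is_tip:
                    result = frozenset({node.name})
                else:
                    result = frozenset().union(*(walk(c) for c in node.children))
                sets[id(node)] = result
                return result

            walk(self.root)
            self._tipsets = sets
        return self._tipsets

    def edges(self) -> Iterator[tuple[Node, frozenset[str]]]:
        """Yield (node, tip set below its parent edge) for every non-root node."""
        sets = self._tipset_below()
        for node in self.preorder():
            if node is not self.root:
                yield node, sets[id(node)]

    def bipartitions(self) -> set[frozenset[str]]:
        """Canonical internal bipartitions (the side not containing the
        lexicographically smallest tip), one per internal edge."""
        all_tips = self.tip_set
        anchor = min(all_tips)
        out = set()
        for _, below in self.edges():
            if 1 < len(below) < len(all_tips) - 1:
                side = below if anchor not in below else all_tips - below
                out.add(side)
        return out

    def clade_sides(self) -> set[frozenset[str]]:
        """Every candidate clade: both sides of every edge plus the full set."""
        all_tips = self.tip_set
        out = {all_tips}
        for _, below in self.edges():
            out.add(below)
            comp = all_tips - below
            if comp:
                out.add(comp)
        return out

    def invalidate(self) -> None:
        self._tipsets = None


def is_clade(tree: BarcodeTree, tip_subset: Sequence[str] | frozenset[str]) -> bool:
    """Bipartition monophyly test on the unrooted tree.

    Singletons and the full tip set are always clades; the test is invariant
    under complementation of the subset.
    """
    subset = frozenset(tip_subset)
    if not subset:
        raise InputError("empty tip subset")
    all_tips = tree.tip_set
    unknown = subset - all_tips
    if unknown:
        raise InputError(f"tips not in tree: {sorted(unknown)}")
    if len(subset) in (1, len(all_tips)):
        return True
    for _, below in tree.edges():
        if below == subset or below == all_tips - subset:
            return True
    return False


def _zero_groups(ids: tuple[str, ...], d: np.ndarray) -> list[list[str]]:
    """Connected components of the exact-zero-distance relation.

    For matrices produced by this package zero distance means identical rows,
    so the relation is an equivalence and components are pairwise-zero sets.
    """
    n = len(ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] == 0.0:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ids[i])
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def _leaf_node(members: list[str]) -> Node:
    """A quotient-tree leaf: a tip, or a zero-length fan of identical tips."""
    if len(members) == 1:
        return Node(name=members[0])
    fan = Node()
    for m in members:
        fan.add_child(Node(name=m, length=0.0))
    return fan


def nj_build(dmat: DistanceMatrix) -> BarcodeTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Groups of samples at exact zero distance are collapsed to one
    representative before joining and re-expanded afterwards as zero-length
    fans, so identical sequences are always monophyletic regardless of how
    non-additivity elsewhere in the matrix would have steered the joins.
    Ties in the Q criterion are broken by the lexicographically smallest pair
    of representative ids (a joined node is represented by the smallest id it
    contains).  Negative branch lengths are clamped to zero with the deficit
    moved to the sibling edge.
    """
    undefined = dmat.saturated_pairs
    if undefined:
        raise InputError(
            f"distance undefined (saturated) for pair {undefined[0]!r}; "
            "cannot build a tree"
        )
    if np.any(np.isnan(dmat.d)):
        raise InputError("distance matrix contains undefined entries")
    if dmat.n_samples < 3:
        raise InputError("neighbor joining requires at least 3 samples")

    groups = _zero_groups(dmat.sample_ids, dmat.d)
    index_of = {sid: i for i, sid in enumerate(dmat.sample_ids)}
    n = len(groups)
    if n == 1:
        root = Node()
        for member in groups[0]:
            root.add_child(Node(name=member, length=0.0))
        return BarcodeTree(root)
    rep_idx = [index_of[g[0]] for g in groups]
    d0 = dmat.d[np.ix_(rep_idx, rep_idx)]
    if n == 2:
        half = float(d0[0, 1]) / 2.0
        root = Node()
        for g in groups:
            leaf = _leaf_node(g)
            leaf.length = half
            root.add_child(leaf)
        return BarcodeTree(root)

    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = d0
    nodes: dict[int, Node] = {i: _leaf_node(g) for i, g in enumerate(groups)}
    reps: dict[int, str] = {i: g[0] for i, g in enumerate(groups)}
    active = list(range(n))
    next_index = n

    while len(active) > 2:
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = len(active)
        rowsum = sub.sum(axis=1)
        Q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        # Q is symmetric up to rounding; normalize tie candidates to a < b
        qmin = Q.min()
        ties = {(min(a, b), max(a, b)) for a, b in np.argwhere(Q <= qmin) if a != b}
        best = None
        for a, b in sorted(ties):
            key = tuple(sorted((reps[active[a]], reps[active[b]])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = sub[ai, bi]
        li = 0.5 * dij + (rowsum[ai] - rowsum[bi]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
            li = max(li, 0.0)
        parent = Node()
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = float(li), float(lj)
        parent.add_child(child_i)
        parent.add_child(child_j)
        u = next_index
        next_index += 1
        nodes[u] = parent
        reps[u] = min(reps[i], reps[j])
        others = [k for k in active if k != i and k != j]
        for k in others:
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - dij)
        active = others + [u]

    a, b = active
    final = max(D[a, b], 0.0)
    node_a, node_b = nodes[a], nodes[b]
    if not node_a.is_tip:
        root, other = node_a, node_b
    else:
        root, other = node_b, node_a
    other.length = float(final)
    root.add_child(other)
    root.length = None
    return BarcodeTree(root)


def bootstrap_supports(
    alignment: LocusAlignment,
    tree: BarcodeTree,
    n_reps: int,
    seed: int,
) -> BarcodeTree:
    """Nonparametric bootstrap over alignment columns.

    Columns of the complete-deletion alignment are resampled with replacement
    and the full distance + NJ pipeline is re-run per replicate; the support
    of each internal edge of ``tree`` is the percentage of successful
    replicates whose tree contains the same bipartition.  Replicates whose
    distance matrix has a saturated pair are skipped (and not counted in the
    denominator).  The input tree is annotated in place and returned.
    """
    from .distances import complete_deletion, is_degenerate

    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    clean = complete_deletion(alignment)
    if is_degenerate(clean):
        raise DegenerateAlignmentError("cannot bootstrap a degenerate alignment")
    codes = clean.encode()
    n, L = codes.shape
    ids = clean.sample_ids
    reference = tree.bipartitions()
    counts = {bp: 0 for bp in reference}
    rng = np.random.default_rng(seed)
    n_ok = 0
    for _ in range(n_reps):
        draw = rng.integers(0, L, size=L)
        try:
            d, saturated, params = distances_from_codes(codes[:, draw])
        except DegenerateAlignmentError:  # pragma: no cover - L >= 1 here
            continue
        if saturated.any():
            continue
        rep_tree = nj_build(
            DistanceMatrix(sample_ids=ids, d=d, pooled=params, n_sites=L)
        )
        n_ok += 1
        rep_bps = rep_tree.bipartitions()
        for bp in reference:
            if bp in rep_bps:
                counts[bp] += 1
    if n_ok == 0:
        raise InputError("all bootstrap replicates failed (saturated distances)")
    all_tips = tree.tip_set
    anchor = min(all_tips)
    for node, below in tree.edges():
        if 1 < len(below) < len(all_tips) - 1:
            side = below if anchor not in below else all_tips - below
            node.support = 100.0 * counts[side] / n_ok
    return tree
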