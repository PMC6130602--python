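"""Reading, writing, validating and re-rooting phylogenetic trees.

Trees are held as :class:`PhyloTree`, a thin validated wrapper around a
:class:`dendropy.Tree`.  Rooting operations (midpoint and minimal ancestor
deviation) work on an unrooted adjacency view of the tree so that the two
edges incident to a bifurcating root are treated as the single unrooted
branch they represent.  All rooting operations preserve the multiset of
tip labels and every tip-to-tip path length.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "PhyloTree",
    "TreeError",
    "NewickParseError",
    "read_newick",
    "write_newick",
    "midpoint_root",
    "mad_root",
    "ancestor_deviation",
]


class TreeError(ValueError):
    """Invalid tree structure (duplicate labels, negative lengths, ...)."""


class NewickParseError(TreeError):
    """Newick text could not be parsed."""


class PhyloTree:
    """A rooted phylogeny with branch lengths and uniquely labelled tips.

    Parameters
    ----------
    tree:
        A ``dendropy.Tree``.  The tree is validated on construction: tip
        labels must be unique and non-empty, every non-root edge must carry
        a finite non-negative length (a missing root-edge length is treated
        as zero), and there must be a single root.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, source: str) -> "PhyloTree":
        """Parse a Newick string or file path into a validated tree."""
        text = source
        if "(" not in source and ";" not in source:
            with open(source) as fh:
                text = fh.read()
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"could not parse Newick input: {exc}") from exc
        return cls(tree)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        root = self._tree.seed_node
        for leaf in self._tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else leaf.label
            if not label:
                raise TreeError("tip with empty label")
            if label in seen:
                raise TreeError(f"duplicate tip label: {label!r}")
            seen.add(label)
        for node in self._tree.preorder_node_iter():
            length = node.edge.length
            if node is root:
                if length is None:
                    continue
            elif length is None:
                raise TreeError(f"missing branch length above node {node}")
            if length is not None and (not math.isfinite(length) or length < 0):
                raise TreeError(f"invalid branch length {length!r}")

    # -- accessors ----------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def total_length(self) -> float:
        return sum(
            node.edge.length or 0.0 for node in self._tree.preorder_node_iter()
        )

    def tip_distances(self) -> tuple[list[str], list[list[float]]]:
        """All pairwise tip-to-tip path lengths (label order, matrix)."""
        graph = _Ugraph.from_phylo(self)
        labels = sorted(graph.tip_index)
        mat = [[0.0] * len(labels) for _ in labels]
        for i, a in enumerate(labels):
            dist = graph.distances_from(graph.tip_index[a])
            for j, b in enumerate(labels):
                mat[i][j] = dist[graph.tip_index[b]]
        return labels, mat

    def prune_to(self, labels) -> "PhyloTree":
        """Restrict to a subset of tips, suppressing degree-2 nodes.

        Branch lengths of suppressed nodes are summed, so pairwise path
        lengths among retained tips are preserved exactly.
        """
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        # dendropy sums edge lengths when suppressing unifurcations
        return PhyloTree(clone)

    # -- output -------------------------------------------------------

    def to_newick(self) -> str:
        out = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        )
        return out.strip() + "\n"

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips})"


def read_newick(path_or_text: str) -> PhyloTree:
    return PhyloTree.from_newick(path_or_text)


def write_newick(tree: PhyloTree, path: str) -> None:
    tree.write(path)


# ---------------------------------------------------------------------
# Unrooted adjacency view used by the rooting operations
# ---------------------------------------------------------------------


@dataclass
class _Ugraph:
    """Unrooted weighted adjacency view of a tree.

    Nodes are integers; tips carry labels.  If the source tree's root is
    a bifurcation it is suppressed so that its two incident edges become
    one branch, mirroring the unrooted topology.
    """

    adj: dict = field(default_factory=dict)  # node -> list[(nbr, length)]
    tip_index: dict = field(default_factory=dict)  # label -> node
    edges: list = field(default_factory=list)  # [(u, v, length)] post-order

    @classmethod
    def from_phylo(cls, tree: PhyloTree) -> "_Ugraph":
        g = cls()
        dtree = tree.dendropy_tree
        ids: dict = {}

        def nid(node):
            if id(node) not in ids:
                ids[id(node)] = len(ids)
                g.adj[ids[id(node)]] = []
            return ids[id(node)]

        root = dtree.seed_node
        for node in dtree.postorder_node_iter():
            u = nid(node)
            if node.is_leaf():
                g.tip_index[node.taxon.label] = u
            if node is not root:
                v = nid(node.parent_node)
                length = node.edge.length or 0.0
                g.adj[u].append((v, length))
                g.adj[v].append((u, length))
                g.edges.append((u, v, length))
        # suppress a bifurcating root: merge its two edges into one branch
        r = ids[id(root)]
        if len(g.adj[r]) == 2:
            (a, la), (b, lb) = g.adj[r]
            g.adj[a] = [(x, l) for x, l in g.adj[a] if x != r] + [(b, la + lb)]
            g.adj[b] = [(x, l) for x, l in g.adj[b] if x != r] + [(a, la + lb)]
            del g.adj[r]
            g.edges = [(u, v, l) for u, v, l in g.edges if r not in (u, v)]
            g.edges.append((a, b, la + lb))
        return g

    def distances_from(self, start: int) -> dict:
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, length in self.adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + length
                    stack.append(v)
        return dist

    def side_tips(self, u: int, v: int) -> set:
        """Tips reachable from ``v`` without crossing edge (u, v)."""
        seen = {u, v}
        stack = [v]
        while stack:
            a = stack.pop()
            for b, _ in self.adj[a]:
                if b not in seen:
                    seen.add(b)
                    stack.append(b)
        seen.discard(u)
        labels = {lab for lab, n in self.tip_index.items() if n in seen}
        return labels

    def root_at(self, u: int, v: int, x_from_v: float) -> PhyloTree:
        """Build a rooted tree with the root on edge (u, v), ``x_from_v``
        away from ``v``.  A zero-length child branch at either end keeps
        the path-length multiset unchanged."""
        length = next(l for (n, l) in self.adj[v] if n == u)
        x_from_v = min(max(x_from_v, 0.0), length)
        label_of = {n: lab for lab, n in self.tip_index.items()}

        def newick(node: int, parent: int, blen: float) -> str:
            children = [(n, l) for n, l in self.adj[node] if n != parent]
            if not children and node in label_of:
                return f"{label_of[node]}:{blen:.17g}"
            parts = ",".join(newick(n, node, l) for n, l in children)
            return f"({parts}):{blen:.17g}"

        left = newick(v, u, x_from_v)
        right = newick(u, v, length - x_from_v)
        return PhyloTree.from_newick(f"({left},{right});")


# ---------------------------------------------------------------------
# Rooting methods
# ---------------------------------------------------------------------


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest tip-to-tip path.

    Ties between equally long paths are broken by lexical tip-label
    order, so the result is deterministic.
    """
    if tree.n_tips < 2:
        raise TreeError("midpoint rooting needs at least 2 tips")
    g = _Ugraph.from_phylo(tree)
    best = None  # (dist, a_label, b_label, dist_map_from_a)
    for a in sorted(g.tip_index):
        dist = g.distances_from(g.tip_index[a])
        for b in sorted(g.tip_index):
            if b <= a:
                continue
            d = dist[g.tip_index[b]]
            if best is None or d > best[0] + 1e-15:
                best = (d, a, b, dist)
    if best is None or best[0] <= 0:
        raise TreeError("all branch lengths are zero; midpoint undefined")
    d, a, b, dist_a = best
    half = d / 2.0
    # walk from b towards a until the cumulative distance reaches half
    target = g.tip_index[a]
    node = g.tip_index[b]
    walked = 0.0
    while True:
        # neighbour on the path towards a: the one with dist_a smaller by length
        nxt = None
        for n, length in g.adj[node]:
            if abs(dist_a[n] + length - dist_a[node]) <= 1e-9 * max(1.0, d):
                nxt = (n, length)
                break
        if nxt is None:  # pragma: no cover - path always exists
            raise TreeError("internal error walking midpoint path")
        n, length = nxt
        if walked + length >= half - 1e-15:
            return g.root_at(n, node, half - walked)
        walked += length
        node = n
        if node == target:  # pragma: no cover
            raise TreeError("internal error: midpoint beyond path end")


def ancestor_deviation(tree: PhyloTree) -> float:
    """Root-mean-square relative deviation of ancestor–descendant distances.

    For every tip pair (i, j) with most recent common ancestor ``m`` under
    the current rooting, the deviation is ``|2 d(i, m) / d(i, j) - 1|``; the
    statistic is the RMS over all pairs (pairs at zero distance contribute
    zero).  A perfectly clock-like tree rooted at its true root scores 0.
    """
    dtree = tree.dendropy_tree
    depth: dict = {}
    below: dict = {}
    devs: list[float] = []
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [(node.taxon.label, depth[id(node)])]
            continue
        groups = [below[id(c)] for c in node.child_nodes()]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for _, di in groups[gi]:
                    for _, dj in groups[gj]:
                        dij = di + dj - 2.0 * depth[id(node)]
                        if dij <= 0:
                            devs.append(0.0)
                        else:
                            devs.append(abs(2.0 * (di - depth[id(node)]) / dij - 1.0))
        merged = [t for grp in groups for t in grp]
        below[id(node)] = merged
    if not devs:
        raise TreeError("tree has fewer than 2 tips")
    return math.sqrt(sum(v * v for v in devs) / len(devs))


def mad_root(tree: PhyloTree) -> PhyloTree:
    """Minimal-ancestor-deviation rooting.

    Every branch of the unrooted tree is a candidate root location; on a
    branch the deviation statistic is quadratic in the root position, so
    the within-branch optimum has a closed form.  The branch (and
    position) minimising :func:`ancestor_deviation` wins; ties keep the
    first branch encountered in post-order.  The returned tree carries
    the objective value as ``mad_objective``.

    Falls back to midpoint rooting (with a warning attribute) for star
    trees, where every internal position scores identically.
    """
    if tree.n_tips < 3:
        raise TreeError("MAD rooting needs at least 3 tips")
    if tree.total_length <= 0:
        raise TreeError("MAD rooting needs positive total branch length")
    g = _Ugraph.from_phylo(tree)
    tip_of = {n: lab for lab, n in g.tip_index.items()}
    dist = {lab: g.distances_from(n) for lab, n in g.tip_index.items()}

    best: tuple | None = None  # (objective, u, v, x_from_v)
    for u, v, length in g.edges:
        side_v = g.side_tips(u, v)
        side_u = set(tip_of.values()) - side_v
        if not side_v or not side_u:
            continue
        # spanning pairs: deviation 2 (d_bv + x) / d_bc - 1 linear in x
        sm, sam = 0.0, 0.0
        for b in side_v:
            d_bv = dist[b][v]
            for c in side_u:
                d_bc = dist[b][g.tip_index[c]]
                if d_bc <= 0:
                    continue
                a_coef = 2.0 * d_bv / d_bc - 1.0
                m_coef = 2.0 / d_bc
                sm += m_coef * m_coef
                sam += a_coef * m_coef
        if sm > 0 and length > 0:
            x = min(max(-sam / sm, 0.0), length)
        else:
            x = length / 2.0
        candidate = g.root_at(u, v, x)
        obj = ancestor_deviation(candidate)
        if best is None or obj < best[0] - 1e-12:
            best = (obj, candidate)
    if best is None:  # star tree with no internal structure
        rooted = midpoint_root(tree)
        rooted.mad_objective = ancestor_deviation(rooted)
        rooted.mad_fallback = "star tree: fell back to midpoint rooting"
        return rooted
    obj, rooted = best
    rooted.mad_objective = obj
    return rooted
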