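"""Unrooted binary tree topologies: enumeration, bipartitions, Newick.

Trees are stored as plain adjacency maps over integer node ids with leaves
labelled by taxon names.  Leaf node ids are the indices of the sorted taxon
list, internal ids follow.  This deliberately lightweight container exists
because topology enumeration and split bookkeeping are on the hot path of the
parsimony search; conversion to/from Newick interoperates with standard
readers (dendropy re-parses everything this module writes).
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

__all__ = [
    "UnrootedTree",
    "enumerate_topologies",
    "n_unrooted_topologies",
]


def n_unrooted_topologies(n_taxa: int) -> int:
    """(2n-5)!! -- the number of distinct unrooted binary topologies."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    count = 1
    for m in range(3, 2 * n_taxa - 4, 2):
        count *= m
    return count


class UnrootedTree:
    """An unrooted binary tree over named taxa.

    Parameters
    ----------
    edges : iterable of (int, int)
        Undirected edges over node ids.  Leaves must have degree 1 and be
        ids ``0 .. n_taxa-1``; internal nodes degree 3.
    taxa : sequence of str
        Taxon names; name ``taxa[i]`` labels leaf node ``i``.  Stored sorted
        relative ordering is the caller's responsibility; use
        :meth:`from_newick` or :func:`enumerate_topologies` for canonical
        construction.
    """

    def __init__(self, edges: Iterable[tuple[int, int]], taxa: Sequence[str]):
        self.taxa = list(taxa)
        self.edges = [tuple(sorted(e)) for e in edges]
        adj: dict[int, list[int]] = {}
        for u, v in self.edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        self.adj = {u: sorted(vs) for u, vs in adj.items()}
        n = len(self.taxa)
        if n >= 3:
            for i in range(n):
                if len(self.adj.get(i, [])) != 1:
                    raise ValueError(f"leaf node {i} must have degree 1")
            for u, vs in self.adj.items():
                if u >= n and len(vs) != 3:
                    raise ValueError(f"internal node {u} must have degree 3")
        self._splits: frozenset[frozenset[str]] | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def leaf_node(self, name: str) -> int:
        try:
            return self.taxa.index(name)
        except ValueError:
            raise KeyError(f"unknown taxon {name!r}") from None

    def neighbors(self, node: int, exclude: int | None = None) -> list[int]:
        return [v for v in self.adj[node] if v != exclude]

    # -- splits ------------------------------------------------------------

    def _leafset_below(self, node: int, parent: int) -> frozenset[str]:
        if node < self.n_taxa:
            return frozenset([self.taxa[node]])
        out: set[str] = set()
        stack = [(node, parent)]
        while stack:
            cur, par = stack.pop()
            if cur < self.n_taxa:
                out.add(self.taxa[cur])
                continue
            for nxt in self.adj[cur]:
                if nxt != par:
                    stack.append((nxt, cur))
        return frozenset(out)

    def split_of_edge(self, u: int, v: int) -> frozenset[str]:
        """Canonical split key of edge (u, v): the side NOT containing the
        alphabetically first taxon."""
        ref = min(self.taxa)
        side = self._leafset_below(u, v)
        if ref in side:
            side = frozenset(self.taxa) - side
        return side

    def splits(self, include_trivial: bool = False) -> frozenset[frozenset[str]]:
        """Nontrivial bipartitions (splits) of the topology."""
        if include_trivial:
            return frozenset(self.split_of_edge(u, v) for u, v in self.edges)
        if self._splits is None:
            n = self.n_taxa
            self._splits = frozenset(
                self.split_of_edge(u, v)
                for u, v in self.edges
                if u >= n and v >= n
            )
        return self._splits

    # -- canonical form ----------------------------------------------------

    def canonical_newick(self) -> str:
        """Topology-only Newick in a canonical (sorted) form.

        The tree is written rooted at the alphabetically first taxon with
        subtrees sorted lexicographically, so two `UnrootedTree`s describe
        the same unrooted topology iff their canonical strings are equal.
        """
        root = self.leaf_node(min(self.taxa))

        def rec(node: int, parent: int) -> str:
            if node < self.n_taxa:
                return self.taxa[node]
            kids = sorted(rec(c, node) for c in self.adj[node] if c != parent)
            return "(" + ",".join(kids) + ")"

        child = self.adj[root][0]
        return f"({self.taxa[root]},{rec(child, root)});"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UnrootedTree):
            return NotImplemented
        return self.canonical_newick() == other.canonical_newick()

    def __hash__(self) -> int:
        return hash(self.canonical_newick())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"UnrootedTree({self.canonical_newick()!r})"

    # -- conversion --------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "UnrootedTree":
        """Parse a (possibly rooted) Newick string into an unrooted topology.

        Uses dendropy for parsing; a rooted bifurcation at the top is
        collapsed (derooted) so the result is a proper unrooted binary tree.
        """
        import dendropy

        dtree = dendropy.Tree.get(data=newick, schema="newick")
        dtree.deroot()
        taxa = sorted(lf.taxon.label.replace(" ", "_") for lf in dtree.leaf_node_iter())
        index = {name: i for i, name in enumerate(taxa)}
        next_id = len(taxa)
        ids: dict[int, int] = {}
        edges: list[tuple[int, int]] = []
        for node in dtree.preorder_node_iter():
            if node.is_leaf():
                ids[id(node)] = index[node.taxon.label.replace(" ", "_")]
            else:
                ids[id(node)] = next_id
                next_id += 1
            if node.parent_node is not None:
                edges.append((ids[id(node.parent_node)], ids[id(node)]))
        return cls(edges, taxa)


def enumerate_topologies(taxa: Sequence[str]) -> Iterator[UnrootedTree]:
    """Yield every distinct unrooted binary topology over ``taxa``.

    Stepwise addition: the i-th taxon is attached to every edge of every
    partial topology, which generates each of the (2n-5)!! topologies exactly
    once.  Order is deterministic for a given taxon ordering.
    """
    taxa = sorted(taxa)
    n = len(taxa)
    if n < 4:
        if n == 3:
            yield UnrootedTree([(0, 3), (1, 3), (2, 3)], taxa)
            return
        raise ValueError("need at least 3 taxa to build an unrooted topology")

    def grow(edges: list[tuple[int, int]], leaf: int) -> Iterator[list[tuple[int, int]]]:
        new_node = n + leaf - 2  # internal ids n .. 2n-3
        for i, (u, v) in enumerate(edges):
            yield edges[:i] + edges[i + 1:] + [(u, new_node), (new_node, v), (leaf, new_node)]

    partials: list[list[tuple[int, int]]] = [[(0, n), (1, n), (2, n)]]
    for leaf in range(3, n):
        partials = [g for edges in partials for g in grow(edges, leaf)]
    for edges in partials:
        yield UnrootedTree(edges, taxa)
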