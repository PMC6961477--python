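"""Continuous-character (linear/Manhattan cost) parsimony on cluster abundances.

The tree length of a real-valued character under linear cost is minimised by
the classic interval algorithm: a postorder pass assigns every internal node
the interval spanned by the intersection (or, when disjoint, the gap) of its
children's intervals, accumulating each gap into the length.  The optimum is
exact for binary trees and is independent of the traversal root.

Searching is exhaustive: all (2n-5)!! unrooted binary topologies are scored,
which is the intended regime for the small numbers of taxa (<= 9) these
repeat-abundance matrices contain.  Node supports come from character
resampling -- either the classic bootstrap or symmetric reweighting (each
character independently up-weighted, down-weighted or kept) -- with the
support of an edge defined as the fraction of replicates whose strict
consensus of most-parsimonious trees contains that bipartition.

A key economy: a character's length on a fixed topology does not depend on
the resampling weights, so every replicate's total is a weighted sum of
precomputed per-character lengths and support estimation for thousands of
replicates reduces to one matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .matrices import CharacterMatrix
from .trees import UnrootedTree, enumerate_topologies

__all__ = [
    "ScoredTree",
    "farris_length",
    "character_lengths",
    "exhaustive_search",
    "root_on_outgroup",
    "resample_support",
    "write_tree",
    "tree_to_newick",
]

_TIE_TOL = 1e-9


@dataclass
class ScoredTree:
    """A topology with its parsimony score and drawing metadata.

    edge_lengths maps each edge's split key (see
    :meth:`UnrootedTree.split_of_edge`) to the summed per-character step
    change across that edge.  supports maps internal splits to percents.
    """

    tree: UnrootedTree
    total_length: float
    edge_lengths: dict[frozenset[str], float]
    root: str | None = None
    supports: dict[frozenset[str], float] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return self.tree.taxa

    def splits(self) -> frozenset[frozenset[str]]:
        return self.tree.splits()


# ---------------------------------------------------------------------------
# scoring


def _aligned_values(matrix: CharacterMatrix, taxa_sorted: list[str]) -> np.ndarray:
    if sorted(matrix.taxa) != taxa_sorted:
        raise ValueError(
            f"matrix taxa {sorted(matrix.taxa)} do not match tree leaves {taxa_sorted}")
    return matrix.data.loc[taxa_sorted].to_numpy(dtype=float)


def _interval_pass(tree: UnrootedTree, X: np.ndarray):
    """Postorder interval computation.

    Returns (per-character lengths, lo, hi, traversal root leaf, its
    neighbour).  X rows follow ``tree.taxa`` order.
    """
    n_chars = X.shape[1]
    lengths = np.zeros(n_chars)
    root = tree.leaf_node(min(tree.taxa))
    start = tree.neighbors(root)[0]
    lo: dict[int, np.ndarray] = {}
    hi: dict[int, np.ndarray] = {}

    # iterative postorder over (node, parent)
    stack: list[tuple[int, int, bool]] = [(start, root, False)]
    while stack:
        node, parent, expanded = stack.pop()
        if node < tree.n_taxa:
            lo[node] = hi[node] = X[node]
            continue
        kids = tree.neighbors(node, parent)
        if not expanded:
            stack.append((node, parent, True))
            for k in kids:
                stack.append((k, node, False))
            continue
        l1, h1 = lo[kids[0]], hi[kids[0]]
        l2, h2 = lo[kids[1]], hi[kids[1]]
        a = np.maximum(l1, l2)
        b = np.minimum(h1, h2)
        np.add(lengths, np.maximum(a - b, 0.0), out=lengths)
        lo[node] = np.minimum(a, b)
        hi[node] = np.maximum(a, b)

    v0 = X[root]
    np.add(lengths, np.maximum(lo[start] - v0, 0.0), out=lengths)
    np.add(lengths, np.maximum(v0 - hi[start], 0.0), out=lengths)
    return lengths, lo, hi, root, start


def character_lengths(tree: UnrootedTree, matrix: CharacterMatrix) -> np.ndarray:
    """Minimum linear-cost length of each character on ``tree``."""
    X = _aligned_values(matrix, tree.taxa)
    lengths, *_ = _interval_pass(tree, X)
    return lengths


def farris_length(tree: UnrootedTree, matrix: CharacterMatrix,
                  weights: np.ndarray | None = None):
    """Total parsimony length and a per-edge decomposition.

    The total is the exact minimum.  Per-edge lengths additionally require a
    point assignment within each node's optimal interval; the deterministic
    convention used here assigns, in preorder from the traversal root (the
    alphabetically first taxon, whose "interval" is its observed value), each
    node the point of its interval closest to its parent's assigned value.
    The per-edge decomposition always sums to the total; the decomposition
    itself (not the total) depends on this convention.

    Returns
    -------
    (total_length, edge_lengths) where edge_lengths maps split keys to
    non-negative floats.
    """
    X = _aligned_values(matrix, tree.taxa)
    n_chars = X.shape[1]
    w = np.ones(n_chars) if weights is None else np.asarray(weights, dtype=float)
    lengths, lo, hi, root, start = _interval_pass(tree, X)
    total = float(lengths @ w)

    assigned: dict[int, np.ndarray] = {root: X[root]}
    edge_lengths: dict[frozenset[str], float] = {}
    stack = [(start, root)]
    while stack:
        node, parent = stack.pop()
        a = np.clip(assigned[parent], lo[node], hi[node])
        assigned[node] = a
        edge_lengths[tree.split_of_edge(node, parent)] = float(
            np.abs(a - assigned[parent]) @ w)
        if node >= tree.n_taxa:
            for k in tree.neighbors(node, parent):
                stack.append((k, node))

    decomposed = sum(edge_lengths.values())
    if not np.isclose(decomposed, total, rtol=1e-9, atol=1e-6):
        raise AssertionError(
            f"edge decomposition {decomposed} != total {total}")
    return total, edge_lengths


# ---------------------------------------------------------------------------
# search


def _gap_matrix(matrix: CharacterMatrix):
    """All topologies over the matrix taxa and their per-character lengths.

    Returns (topologies, G) with G of shape (n_topologies, n_characters).
    """
    taxa = sorted(matrix.taxa)
    X = _aligned_values(matrix, taxa)
    topologies = list(enumerate_topologies(taxa))
    G = np.empty((len(topologies), X.shape[1]))
    for i, t in enumerate(topologies):
        G[i], *_ = _interval_pass(t, X)
    return topologies, G


def exhaustive_search(matrix: CharacterMatrix, max_taxa: int = 9,
                      weights: np.ndarray | None = None) -> list[ScoredTree]:
    """Score every unrooted binary topology; return all minimum-length trees.

    Ties are preserved; the result is sorted by canonical Newick string.
    Refuses more than ``max_taxa`` taxa, where the (2n-5)!! search space
    stops being enumerable at a desk -- use fewer taxa or raise ``max_taxa``
    explicitly if you accept the cost.
    """
    n = len(matrix.taxa)
    if n < 4:
        raise ValueError("exhaustive search needs at least 4 taxa")
    if n > max_taxa:
        raise ValueError(
            f"{n} taxa would require scoring {np.prod(range(3, 2 * n - 4, 2))} "
            f"topologies; max_taxa={max_taxa}. Reduce the taxon set or pass a "
            "larger max_taxa explicitly.")
    topologies, G = _gap_matrix(matrix)
    w = (np.ones(G.shape[1]) if weights is None
         else np.asarray(weights, dtype=float))
    totals = G @ w
    best = totals.min()
    tol = _TIE_TOL * max(1.0, abs(best))
    winners = [topologies[i] for i in np.flatnonzero(totals <= best + tol)]
    winners.sort(key=lambda t: t.canonical_newick())
    return [ScoredTree(t, *farris_length(t, matrix, weights=w)) for t in winners]


def root_on_outgroup(tree: ScoredTree, outgroup: str) -> ScoredTree:
    """Root on the outgroup's pendant edge; lengths and total unchanged."""
    if outgroup not in tree.taxa:
        raise KeyError(f"outgroup {outgroup!r} is not a leaf of the tree")
    return replace(tree, root=outgroup)


# ---------------------------------------------------------------------------
# support


def resample_support(matrix: CharacterMatrix,
                     reference: ScoredTree | None = None,
                     n_reps: int = 10_000,
                     scheme: str = "symmetric",
                     p_change: float = 0.33,
                     seed: int | None = None,
                     max_taxa: int = 9,
                     return_replicates: bool = False):
    """Per-edge resampling supports on the most-parsimonious tree.

    scheme="bootstrap" draws character weights from a multinomial (classic
    bootstrap); scheme="symmetric" independently reweights each character to
    0 or 2 with probability ``p_change/2`` each, else 1.  Every replicate is
    solved exactly (exhaustive search); an internal edge of the reference
    tree is supported by a replicate iff the strict consensus of that
    replicate's most-parsimonious trees contains the bipartition.

    Returns a dict mapping internal splits to support percents, and also
    records them on ``reference.supports`` when a reference is given.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(matrix.taxa) > max_taxa:
        raise ValueError(f"too many taxa for exhaustive resampling "
                         f"(max_taxa={max_taxa})")
    topologies, G = _gap_matrix(matrix)
    n_chars = G.shape[1]
    rng = np.random.default_rng(seed)
    if scheme == "bootstrap":
        W = rng.multinomial(n_chars, np.full(n_chars, 1.0 / n_chars),
                            size=n_reps).T.astype(float)
    elif scheme == "symmetric":
        W = rng.choice([0.0, 2.0, 1.0],
                       p=[p_change / 2, p_change / 2, 1.0 - p_change],
                       size=(n_chars, n_reps))
    else:
        raise ValueError(f"unknown resampling scheme {scheme!r}")

    if reference is None:
        reference = exhaustive_search(matrix)[0]
    ref_splits = reference.splits()

    split_sets = [t.splits() for t in topologies]
    totals = G @ W  # (n_topologies, n_reps)
    mins = totals.min(axis=0)
    tols = _TIE_TOL * np.maximum(1.0, np.abs(mins))
    counts = {s: 0 for s in ref_splits}
    replicate_consensus: list[frozenset[frozenset[str]]] = []
    for r in range(W.shape[1]):
        mp = np.flatnonzero(totals[:, r] <= mins[r] + tols[r])
        consensus = frozenset.intersection(*(split_sets[i] for i in mp))
        if return_replicates:
            replicate_consensus.append(consensus)
        for s in ref_splits & consensus:
            counts[s] += 1
    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    reference.supports.update(supports)
    if return_replicates:
        return supports, replicate_consensus
    return supports


# ---------------------------------------------------------------------------
# output


def tree_to_newick(tree: ScoredTree, digits: int = 6) -> str:
    """Newick with branch lengths and integer percent supports as internal
    node labels.

    Rooted trees are written with the root bisecting the outgroup's pendant
    edge (half the edge length on either side); unrooted trees are written
    from the internal node next to the alphabetically first taxon, as a basal
    trifurcation.
    """
    utree = tree.tree
    lengths = tree.edge_lengths

    def fmt(x: float) -> str:
        return f"{x:.{digits}g}"

    def edge_len(child: int, parent: int) -> float:
        return lengths.get(utree.split_of_edge(child, parent), 0.0)

    def label(child: int, parent: int) -> str:
        if child < utree.n_taxa:
            return ""
        s = utree.split_of_edge(child, parent)
        if s in tree.supports:
            return str(int(round(tree.supports[s])))
        return ""

    def rec(node: int, parent: int) -> str:
        if node < utree.n_taxa:
            return f"{utree.taxa[node]}:{fmt(edge_len(node, parent))}"
        kids = sorted(rec(c, node) for c in utree.neighbors(node, parent))
        return (f"({','.join(kids)}){label(node, parent)}"
                f":{fmt(edge_len(node, parent))}")

    if tree.root is not None:
        og = utree.leaf_node(tree.root)
        inner = utree.adj[og][0]
        half = edge_len(og, inner) / 2.0
        kids = sorted(rec(c, inner) for c in utree.neighbors(inner, og))
        sub = f"({','.join(kids)}):{fmt(half)}"
        return f"({tree.root}:{fmt(half)},{sub});"

    anchor = utree.adj[utree.leaf_node(min(utree.taxa))][0]
    parts = sorted(rec(c, anchor) for c in utree.adj[anchor])
    return f"({','.join(parts)});"


def write_tree(tree: ScoredTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")
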