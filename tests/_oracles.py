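"""Independent brute-force oracles for the test suite.

These deliberately avoid the package's optimized code paths: alignment is a
plain full-matrix Smith-Waterman with traceback, k-mer sharing uses string
sets, and parsimony lengths come from exhaustive minimisation over internal
node states (restricted to observed tip values, which is sufficient for
linear costs).
"""

from __future__ import annotations

from itertools import product

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def smith_waterman(a: str, b: str, match: int = 1, mismatch: int = -2,
                   gap: int = -3):
    """Full local alignment DP over every cell (no bands, no seeds).

    Returns (score, matches, aligned columns) of the canonical optimal
    alignment: maximum score, then maximum matches among co-optimal paths
    (cell-level predecessor preference diagonal > up > left > restart) --
    the same selection convention the similarity contract defines, computed
    here by an independent full-matrix implementation.
    """
    la, lb = len(a), len(b)
    Hp = [0] * (lb + 1)
    Mp = [0] * (lb + 1)
    Lp = [0] * (lb + 1)
    best = (0, 0, 0)
    for i in range(1, la + 1):
        Hc = [0] * (lb + 1)
        Mc = [0] * (lb + 1)
        Lc = [0] * (lb + 1)
        ai = a[i - 1]
        for j in range(1, lb + 1):
            eq = 1 if ai == b[j - 1] else 0
            h = Hp[j - 1] + (match if eq else mismatch)
            m = Mp[j - 1] + eq
            c = Lp[j - 1] + 1
            if Hp[j] + gap > h:
                h, m, c = Hp[j] + gap, Mp[j], Lp[j] + 1
            if Hc[j - 1] + gap > h:
                h, m, c = Hc[j - 1] + gap, Mc[j - 1], Lc[j - 1] + 1
            if h < 0:
                h, m, c = 0, 0, 0
            Hc[j], Mc[j], Lc[j] = h, m, c
            if h > best[0] or (h == best[0] and m > best[1]):
                best = (h, m, c)
        Hp, Mp, Lp = Hc, Mc, Lc
    return best


def best_alignment_either_strand(a: str, b: str, **kw):
    """Best of forward-forward and forward-revcomp alignments."""
    fwd = smith_waterman(a, b, **kw)
    rev = smith_waterman(a, rc(b), **kw)
    return max(fwd, rev)


def canonical_kmers(seq: str, k: int = 17) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        out.add(min(kmer, rc(kmer)))
    return out


def oracle_hit_pairs(reads, min_identity=0.90, min_overlap_frac=0.55, k=17):
    """All-pairs brute-force hit set under the similarity contract: shares a
    k-mer on either strand AND best local alignment reaches the identity
    over ceil(min_overlap_frac x shorter read) columns."""
    import math

    items = sorted((str(i), str(s)) for i, s in reads)
    kmers = {rid: canonical_kmers(seq, k) for rid, seq in items}
    hits = set()
    for x in range(len(items)):
        ida, a = items[x]
        for y in range(x + 1, len(items)):
            idb, b = items[y]
            if not (kmers[ida] & kmers[idb]):
                continue
            min_cols = math.ceil(min_overlap_frac * min(len(a), len(b)))
            score, matches, cols = best_alignment_either_strand(a, b)
            if cols >= min_cols and matches / cols + 1e-12 >= min_identity:
                hits.add((ida, idb))
    return hits


def brute_force_parsimony(tree, values: dict[str, float]) -> float:
    """Minimum summed |change| over edges, minimising internal node states
    over the set of observed tip values (sufficient for linear cost)."""
    internal = sorted(n for n in tree.adj if n >= tree.n_taxa)
    states = sorted(set(values.values()))
    leaf_assign = {tree.leaf_node(t): v for t, v in values.items()}
    best = float("inf")
    for combo in product(states, repeat=len(internal)):
        assign = dict(leaf_assign)
        assign.update(zip(internal, combo))
        cost = sum(abs(assign[u] - assign[v]) for u, v in tree.edges)
        if cost < best:
            best = cost
    return best


def brute_force_parsimony_grid(tree, values: dict[str, float],
                               refine: int = 40) -> float:
    """Grid-refinement check of the same minimum over a dense value grid."""
    lo = min(values.values())
    hi = max(values.values())
    if lo == hi:
        return 0.0
    internal = sorted(n for n in tree.adj if n >= tree.n_taxa)
    grid = [lo + (hi - lo) * i / refine for i in range(refine + 1)]
    grid = sorted(set(grid) | set(values.values()))
    leaf_assign = {tree.leaf_node(t): v for t, v in values.items()}
    best = float("inf")
    for combo in product(grid, repeat=len(internal)):
        assign = dict(leaf_assign)
        assign.update(zip(internal, combo))
        cost = sum(abs(assign[u] - assign[v]) for u, v in tree.edges)
        if cost < best:
            best = cost
    return best
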