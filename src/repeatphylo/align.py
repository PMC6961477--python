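"""Pairwise read similarity engine: k-mer seeding + banded local alignment.

The clustering stage needs every read pair whose best local alignment
reaches 90% identity over at least 55% of the shorter read.  At desk scale
this is done with a shared-k-mer prefilter (default k=17, both strands)
followed by a banded Smith-Waterman (match +1, mismatch -2, gap -3) around
the seeded diagonals.  Identity is matches / aligned columns of the
canonical optimal alignment: maximum score, and among co-optimal paths the
one with the most matches (cell-level preference diagonal > up > left).
The engine is deliberately self-contained and swappable: `find_hits` is the
only entry point the clustering module uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["SimilarityHit", "find_hits", "encode", "revcomp", "ReferenceIndex"]

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i

_NEG = -(10 ** 9)


def encode(seq: str) -> np.ndarray:
    """2-bit-style encoding: A,C,G,T -> 0..3; anything else -> 4 (never matches)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    mask = out < 4
    out[mask] = 3 - out[mask]
    return out


def revcomp_str(seq: str) -> str:
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(comp)[::-1]


@dataclass(frozen=True)
class SimilarityHit:
    """One passing pairwise alignment; read ids are ordered (read_a < read_b)."""

    read_a: str
    read_b: str
    identity: float
    overlap_len: int
    score: float
    same_strand: bool = True

    def __post_init__(self):
        if self.read_a == self.read_b:
            raise ValueError("self-hits are not allowed")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")


@njit(cache=True)
def _banded_sw(a, b, dlo, dhi, match, mismatch, gap):  # pragma: no cover - jit
    """Local alignment restricted to diagonals d = i-j in [dlo, dhi].

    Returns (best score, matches on best path, aligned columns on best path).
    Ties in score prefer more matches; path ties prefer diagonal moves.
    """
    la = a.shape[0]
    lb = b.shape[0]
    Hp = np.zeros(lb + 1, np.int64)
    Mp = np.zeros(lb + 1, np.int64)
    Lp = np.zeros(lb + 1, np.int64)
    Hc = np.empty(lb + 1, np.int64)
    Mc = np.zeros(lb + 1, np.int64)
    Lc = np.zeros(lb + 1, np.int64)
    best = 0
    bm = 0
    bc = 0
    for i in range(1, la + 1):
        jlo = i - dhi
        jhi = i - dlo
        if jlo < 1:
            jlo = 1
        if jhi > lb:
            jhi = lb
        for j in range(lb + 1):
            Hc[j] = _NEG
        if jlo > jhi:
            for j in range(lb + 1):
                Hp[j] = Hc[j]
            continue
        Hc[jlo - 1] = 0
        Mc[jlo - 1] = 0
        Lc[jlo - 1] = 0
        for j in range(jlo, jhi + 1):
            eq = 1 if a[i - 1] == b[j - 1] else 0
            sub = match if eq == 1 else mismatch
            h = Hp[j - 1] + sub
            m = Mp[j - 1] + eq
            c = Lp[j - 1] + 1
            if Hp[j] + gap > h:
                h = Hp[j] + gap
                m = Mp[j]
                c = Lp[j] + 1
            if Hc[j - 1] + gap > h:
                h = Hc[j - 1] + gap
                m = Mc[j - 1]
                c = Lc[j - 1] + 1
            if h < 0:
                h = 0
                m = 0
                c = 0
            Hc[j] = h
            Mc[j] = m
            Lc[j] = c
            if h > best or (h == best and m > bm):
                best = h
                bm = m
                bc = c
        for j in range(lb + 1):
            Hp[j] = Hc[j]
            Mp[j] = Mc[j]
            Lp[j] = Lc[j]
    return best, bm, bc


def _kmer_entries(codes: np.ndarray, k: int):
    """Yield (canonical_kmer_int, position, sign) for every k-mer of a read.

    sign is +1 when the canonical form is the forward k-mer, -1 when it is
    the reverse complement.  k-mers containing non-ACGT bases are skipped.
    """
    n = codes.shape[0]
    if n < k:
        return
    fwd = 0
    rev = 0
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    valid = 0
    for pos in range(n):
        c = int(codes[pos])
        if c > 3:
            valid = 0
            fwd = 0
            rev = 0
            continue
        fwd = ((fwd << 2) | c) & mask
        rev = (rev >> 2) | ((3 - c) << shift)
        valid += 1
        if valid >= k:
            start = pos - k + 1
            if fwd <= rev:
                yield fwd, start, 1
            else:
                yield rev, start, -1


def _seed_index(code_list: list[np.ndarray], k: int) -> dict:
    index: dict[int, list[tuple[int, int, int]]] = {}
    for idx, codes in enumerate(code_list):
        for key, pos, sign in _kmer_entries(codes, k):
            index.setdefault(key, []).append((idx, pos, sign))
    return index


def _group_diagonals(votes: dict[int, int], band: int) -> list[int]:
    """Merge voted diagonals closer than the band; keep each group's
    top-voted diagonal (ties: smaller absolute diagonal, then smaller)."""
    diags = sorted(votes)
    groups: list[int] = []
    cur: list[int] = []
    for d in diags:
        if cur and d - cur[-1] > band:
            groups.append(_best_diag(cur, votes))
            cur = []
        cur.append(d)
    if cur:
        groups.append(_best_diag(cur, votes))
    return groups


def _best_diag(ds: list[int], votes: dict[int, int]) -> int:
    return min(ds, key=lambda d: (-votes[d], abs(d), d))


def _align_pair(a: np.ndarray, b_fwd: np.ndarray, b_rev: np.ndarray,
                orients: dict[bool, dict[int, int]],
                band: int, match: int, mismatch: int, gap: int):
    """Best banded alignment over all seeded orientations/diagonal groups."""
    best = None
    for same_strand, votes in orients.items():
        b = b_fwd if same_strand else b_rev
        for diag in _group_diagonals(votes, band):
            score, m, cols = _banded_sw(a, b, diag - band, diag + band,
                                        match, mismatch, gap)
            cand = (score, m, cols, same_strand)
            if cols and (best is None or cand[:2] > best[:2]):
                best = cand
    return best


def _as_read_list(reads) -> list[tuple[str, str]]:
    out = []
    for r in reads:
        if isinstance(r, tuple):
            out.append((str(r[0]), str(r[1])))
        else:  # Bio.SeqRecord or anything with .id / .seq
            out.append((str(r.id), str(r.seq)))
    return out


def find_hits(reads, min_identity: float = 0.90, min_overlap_frac: float = 0.55,
              k: int = 17, band: int = 10,
              match: int = 1, mismatch: int = -2, gap: int = -3) -> list[SimilarityHit]:
    """All read pairs sharing a k-mer (either strand) whose best local
    alignment reaches ``min_identity`` over at least
    ceil(min_overlap_frac x shorter read length) columns.

    Deterministic for a given input order-insensitive read set: hits are
    keyed by sorted id pairs and returned sorted.
    """
    items = sorted(_as_read_list(reads))
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read ids in pool")
    fwd = [encode(s) for _, s in items]
    rev = [revcomp(c) for c in fwd]
    index = _seed_index(fwd, k)

    # candidate pairs with per-orientation diagonal votes
    pairs: dict[tuple[int, int], dict[bool, dict[int, int]]] = {}
    for entries in index.values():
        if len(entries) < 2:
            continue
        for x in range(len(entries)):
            i, pi, si = entries[x]
            for y in range(x + 1, len(entries)):
                j, pj, sj = entries[y]
                if i == j:
                    continue
                if i < j:
                    a_idx, pa, sa, b_idx, pb, sb = i, pi, si, j, pj, sj
                else:
                    a_idx, pa, sa, b_idx, pb, sb = j, pj, sj, i, pi, si
                same = sa == sb
                if same:
                    diag = pa - pb
                else:
                    diag = pa - (fwd[b_idx].shape[0] - k - pb)
                orients = pairs.setdefault((a_idx, b_idx), {})
                votes = orients.setdefault(same, {})
                votes[diag] = votes.get(diag, 0) + 1

    hits: list[SimilarityHit] = []
    for (i, j), orients in pairs.items():
        shorter = min(fwd[i].shape[0], fwd[j].shape[0])
        min_cols = math.ceil(min_overlap_frac * shorter)
        best = _align_pair(fwd[i], fwd[j], rev[j], orients,
                           band, match, mismatch, gap)
        if best is None:
            continue
        score, matches, cols, same_strand = best
        if cols < min_cols:
            continue
        identity = matches / cols
        if identity + 1e-12 < min_identity:
            continue
        hits.append(SimilarityHit(ids[i], ids[j], identity, cols,
                                  float(score), same_strand))
    hits.sort(key=lambda h: (h.read_a, h.read_b))
    return hits


class ReferenceIndex:
    """Seed-and-align screening of reads against one reference sequence
    (e.g. a plastid genome used as the contaminant database)."""

    def __init__(self, sequence: str, k: int = 17, band: int = 10,
                 match: int = 1, mismatch: int = -2, gap: int = -3):
        if not sequence:
            raise ValueError("reference sequence must be non-empty")
        self.codes = encode(sequence)
        self.k = k
        self.band = band
        self.scoring = (match, mismatch, gap)
        self._index: dict[int, list[tuple[int, int]]] = {}
        for key, pos, sign in _kmer_entries(self.codes, k):
            self._index.setdefault(key, []).append((pos, sign))

    def matches(self, read: str, min_identity: float = 0.90,
                min_overlap_frac: float = 0.55) -> bool:
        """True iff the read aligns to the reference at ``min_identity``
        over at least ceil(min_overlap_frac x read length) columns."""
        codes = encode(read)
        la = codes.shape[0]
        min_cols = math.ceil(min_overlap_frac * la)
        orients: dict[bool, dict[int, int]] = {}
        for key, pos, sign in _kmer_entries(codes, self.k):
            for rpos, rsign in self._index.get(key, ()):  # noqa: B905
                same = sign == rsign
                if same:
                    diag = rpos - pos
                else:
                    # query is the read's reverse complement: its k-mer at
                    # pos sits at la - k - pos in reversed coordinates
                    diag = rpos - (la - self.k - pos)
                votes = orients.setdefault(same, {})
                votes[diag] = votes.get(diag, 0) + 1
        match, mismatch, gap = self.scoring
        for same, votes in orients.items():
            query = codes if same else revcomp(codes)
            for diag in _group_diagonals(votes, self.band):
                lo = max(0, diag - self.band)
                hi = min(self.codes.shape[0], diag + la + self.band)
                window = self.codes[lo:hi]
                score, m, cols = _banded_sw(window, query,
                                            (diag - lo) - self.band,
                                            (diag - lo) + self.band,
                                            match, mismatch, gap)
                if cols >= min_cols and m / cols + 1e-12 >= min_identity:
                    return True
        return False
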