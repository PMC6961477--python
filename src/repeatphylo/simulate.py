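"""Synthetic progenitor/allopolyploid repeat genomes and read emission.

The generator evolves a root repeat profile along a species history that
contains one allopolyploidisation: copy numbers drift multiplicatively
(log-normal), named branches can carry amplification bursts or deletions,
and family consensus sequences accumulate substitutions.  At the
allopolyploidy node the profile is the exact element-wise sum of the two
parental profiles (additive inheritance); everything after that node is
lineage-specific evolution.  Reads are then drawn in proportion to genomic
composition at a fixed coverage, with satellites sampled from a circular
tandem array of their monomer and dispersed elements from a linear
consensus, plus a single-copy background per species.  Every read's true
(species, family) origin is recorded in a TruthTable so each downstream
stage of the pipeline can be validated against ground truth.

The ``repandae6`` preset mirrors a six-taxon allotetraploid system: two
diploid progenitor relatives (maternal-like SYLV, paternal-like OBTU) and
four allotetraploids on the topology (OBTU,(SYLV,(NUDI,(REPA,(NESO,STOC))))),
with a chromovirus-like and a satellite burst on the branch leading to
(REPA,(NESO,STOC)) and net repeat loss (genome downsizing) on the NUDI
branch.  Genomes are miniaturised (the paperback ratios between the taxa are
kept, absolute sizes are megabase-scale) so a full run stays desk-sized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matrices import AbundanceMatrix

__all__ = [
    "RepeatFamily",
    "EvolModel",
    "SpeciesHistory",
    "SpeciesProfile",
    "TruthTable",
    "ConfigurationError",
    "GenerationError",
    "simulate_profiles",
    "emit_reads",
    "repandae6_history",
    "repandae6_families",
    "repandae6_model",
    "simulate_repandae6",
    "REPANDAE6_TREE",
    "BACKGROUND_ID",
    "BP_PER_PG",
]

#: 1 pg of DNA in base pairs (standard conversion constant).
BP_PER_PG = 978_000_000

#: pseudo-family id used in truth records for single-copy background reads.
BACKGROUND_ID = "__background__"

REPEAT_CLASSES = {
    "Ty3-Gypsy-chromovirus", "Ty1-Copia", "satellite",
    "DNA-transposon", "other", "plastid-like",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    """An event or tree reference that does not exist in the configuration."""


class GenerationError(RuntimeError):
    """Read emission impossible for the requested parameters."""


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
    out = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (out == 255).any():
        raise ValueError("sequence must be over the alphabet {A,C,G,T}")
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# domain types


@dataclass
class RepeatFamily:
    """One repeat family of the root profile.

    Satellites are represented by their monomer (50-400 bp); dispersed
    elements (retroelements, DNA transposons, anything else) by a full
    consensus of 300-3000 bp.
    """

    family_id: str
    repeat_class: str
    consensus: str
    base_copies: int

    def __post_init__(self):
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")
        if not self.consensus:
            raise ValueError("consensus must be non-empty")
        _encode(self.consensus)  # alphabet check
        if self.base_copies < 0:
            raise ValueError("base_copies must be >= 0")
        n = len(self.consensus)
        if self.repeat_class == "satellite":
            if not 50 <= n <= 400:
                raise ValueError("satellite monomer must be 50-400 bp")
        elif not 300 <= n <= 3000:
            raise ValueError("dispersed-element consensus must be 300-3000 bp")

    @property
    def is_satellite(self) -> bool:
        return self.repeat_class == "satellite"


@dataclass
class EvolModel:
    """Per-branch copy-number and sequence evolution.

    drift_sd : log-copy drift standard deviation, scalar applied to every
        branch or a {branch: sd} map (missing branches drift with 0).
    bursts : list of (branch, family_id, multiplicative factor > 0).
    deletions : list of (branch, family_id, retained fraction in [0, 1]).
    divergence : per-base substitution probability per branch, scalar or map.
    seed : integer seed for all stochastic evolution.
    """

    drift_sd: float | dict[str, float] = 0.0
    bursts: list[tuple[str, str, float]] = field(default_factory=list)
    deletions: list[tuple[str, str, float]] = field(default_factory=list)
    divergence: float | dict[str, float] = 0.0
    seed: int = 0

    def __post_init__(self):
        for _, _, f in self.bursts:
            if f <= 0:
                raise ValueError("burst factors must be > 0")
        for _, _, r in self.deletions:
            if not 0.0 <= r <= 1.0:
                raise ValueError("retained fractions must be in [0, 1]")

    def branch_drift(self, branch: str) -> float:
        if isinstance(self.drift_sd, dict):
            return self.drift_sd.get(branch, 0.0)
        return float(self.drift_sd)

    def branch_divergence(self, branch: str) -> float:
        if isinstance(self.divergence, dict):
            return self.divergence.get(branch, 0.0)
        return float(self.divergence)


@dataclass
class SpeciesHistory:
    """Rooted species history with one flagged allopolyploidy node.

    children maps each node to its child nodes (tree edges); the
    allopolyploid node appears only in ``allopolyploid`` =
    (node, maternal_parent_node, paternal_parent_node) and may itself have
    children.  Branches are named by their child node.  Leaves are species
    and must carry four-letter codes.
    """

    root: str
    children: dict[str, list[str]]
    allopolyploid: tuple[str, str, str] | None = None

    def __post_init__(self):
        nodes = self.nodes()
        if self.allopolyploid is not None:
            node, mat, pat = self.allopolyploid
            for p in (mat, pat):
                if p not in nodes or p == node:
                    raise ConfigurationError(
                        f"allopolyploidy parent {p!r} is not a tree node")
            if mat == pat:
                raise ConfigurationError("maternal and paternal parents must differ")
            in_children = {c for cs in self.children.values() for c in cs}
            if node in in_children:
                raise ConfigurationError(
                    f"allopolyploid node {node!r} must not also be a tree child")
        for leaf in self.leaves():
            if not (len(leaf) == 4 and leaf.isalpha()):
                raise ConfigurationError(
                    f"leaf {leaf!r} must be a four-letter species code")

    def nodes(self) -> set[str]:
        out = {self.root}
        for parent, cs in self.children.items():
            out.add(parent)
            out.update(cs)
        if self.allopolyploid is not None:
            out.add(self.allopolyploid[0])
        return out

    def leaves(self) -> list[str]:
        out = [n for n in sorted(self.nodes())
               if not self.children.get(n)]
        return out

    def branches(self) -> set[str]:
        """Branch names = every node reached along an edge (child nodes)."""
        out = {c for cs in self.children.values() for c in cs}
        return out


@dataclass
class SpeciesProfile:
    """A species' realised repeat landscape.

    copies maps family_id to integer copy number per 1C; family_seqs carries
    the species' (diverged) consensus per family, classes their repeat
    class, and background the single-copy fraction as one sequence.
    """

    species_code: str
    copies: dict[str, int]
    genome_size_pg: float
    family_seqs: dict[str, str] = field(default_factory=dict, repr=False)
    classes: dict[str, str] = field(default_factory=dict)
    background: str = field(default="", repr=False)

    def __post_init__(self):
        if any(c < 0 for c in self.copies.values()):
            raise ValueError("copy numbers must be >= 0")

    @property
    def repeat_bp(self) -> int:
        return sum(self.copies[f] * len(self.family_seqs[f]) for f in self.copies)

    @property
    def genome_size_bp(self) -> int:
        return self.repeat_bp + len(self.background)

    def validate(self) -> None:
        implied = self.genome_size_bp / BP_PER_PG
        if not math.isclose(implied, self.genome_size_pg, rel_tol=0.01):
            raise ValueError(
                f"{self.species_code}: genome_size_pg {self.genome_size_pg} "
                f"inconsistent with sequence content ({implied:.6g} pg)")


@dataclass
class TruthTable:
    """Ground truth for one simulation run.

    reads maps each emitted read id to its (species_code, family_id); the
    background pseudo-family is recorded as ``__background__``.
    """

    reads: dict[str, tuple[str, str]]
    tree_newick: str
    profiles: dict[str, SpeciesProfile]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tspecies_code\tfamily_id\n")
            for rid in sorted(self.reads):
                sp, fam = self.reads[rid]
                fh.write(f"{rid}\t{sp}\t{fam}\n")

    def family_counts(self, include_background: bool = True) -> AbundanceMatrix:
        """Per-species read counts per true family, as an AbundanceMatrix."""
        import pandas as pd

        rows: dict[str, dict[str, int]] = {}
        for sp, fam in self.reads.values():
            if not include_background and fam == BACKGROUND_ID:
                continue
            rows.setdefault(sp, {})
            rows[sp][fam] = rows[sp].get(fam, 0) + 1
        df = pd.DataFrame(rows).T.fillna(0.0).sort_index()
        return AbundanceMatrix(df[sorted(df.columns)])


# ---------------------------------------------------------------------------
# profile evolution


@dataclass
class _NodeState:
    copies: dict[str, int]
    seqs: dict[str, np.ndarray]
    background: np.ndarray


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0.0:
        return codes
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size == 0:
        return codes
    out = codes.copy()
    out[hit] = (out[hit] + rng.integers(1, 4, hit.size)) % 4
    return out


def _evolve_branch(state: _NodeState, branch: str, model: EvolModel,
                   rng: np.random.Generator) -> _NodeState:
    sd = model.branch_drift(branch)
    div = model.branch_divergence(branch)
    copies: dict[str, int] = {}
    for fam in sorted(state.copies):
        c = float(state.copies[fam])
        if sd > 0.0 and c > 0:
            c *= math.exp(rng.normal(0.0, sd))
        copies[fam] = max(0, _round_half_up(c))
    for b, fam, factor in model.bursts:
        if b == branch:
            copies[fam] = max(0, _round_half_up(copies[fam] * factor))
    for b, fam, retained in model.deletions:
        if b == branch:
            copies[fam] = max(0, _round_half_up(copies[fam] * retained))
    seqs = {fam: _mutate(state.seqs[fam], div, rng) for fam in sorted(state.seqs)}
    background = _mutate(state.background, div, rng)
    return _NodeState(copies, seqs, background)


def _combine_parents(maternal: _NodeState, paternal: _NodeState) -> _NodeState:
    """Additive inheritance at the allopolyploidy node: copies sum exactly;
    the retained consensus per family is the higher-copy parent's variant
    (maternal on ties -- homeologs are not tracked separately); the
    single-copy complement is the union (concatenation) of both parents'."""
    copies = {f: maternal.copies.get(f, 0) + paternal.copies.get(f, 0)
              for f in sorted(set(maternal.copies) | set(paternal.copies))}
    seqs = {}
    for f in copies:
        if maternal.copies.get(f, 0) >= paternal.copies.get(f, 0):
            seqs[f] = maternal.seqs[f]
        else:
            seqs[f] = paternal.seqs[f]
    background = np.concatenate([maternal.background, paternal.background])
    return _NodeState(copies, seqs, background)


def simulate_profiles(history: SpeciesHistory,
                      root_profile: list[RepeatFamily],
                      model: EvolModel,
                      background_bp: int = 1_200_000) -> dict[str, SpeciesProfile]:
    """Evolve the root profile along the history; return per-species profiles.

    On each branch (named by its child node) the order of operations is
    log-normal drift, then bursts, then deletions, then sequence
    substitutions.  The allopolyploidy node's profile is the exact sum of
    its two parents' states at that time (no drift on the hybridisation
    itself).
    """
    fams = {f.family_id: f for f in root_profile}
    if len(fams) != len(root_profile):
        raise ConfigurationError("duplicate family ids in root profile")
    branches = history.branches() | (
        {history.allopolyploid[0]} if history.allopolyploid else set())
    for b, fam, _ in list(model.bursts) + list(model.deletions):
        if b not in branches:
            raise ConfigurationError(f"event references unknown branch {b!r}")
        if fam not in fams:
            raise ConfigurationError(f"event references unknown family {fam!r}")
        if history.allopolyploid and b == history.allopolyploid[0]:
            raise ConfigurationError(
                "events cannot target the allopolyploidy node itself: its "
                "profile is defined as the parental sum")

    rng = np.random.default_rng(model.seed)
    root_state = _NodeState(
        copies={fid: fam.base_copies for fid, fam in fams.items()},
        seqs={fid: _encode(fam.consensus) for fid, fam in fams.items()},
        background=rng.integers(0, 4, background_bp, dtype=np.uint8),
    )

    states: dict[str, _NodeState] = {history.root: root_state}

    def walk(node: str) -> None:
        for child in history.children.get(node, []):
            states[child] = _evolve_branch(states[node], child, model, rng)
            walk(child)

    walk(history.root)
    if history.allopolyploid is not None:
        hybrid, mat, pat = history.allopolyploid
        states[hybrid] = _combine_parents(states[mat], states[pat])
        walk(hybrid)

    classes = {fid: fam.repeat_class for fid, fam in fams.items()}
    out: dict[str, SpeciesProfile] = {}
    for leaf in history.leaves():
        st = states[leaf]
        repeat_bp = sum(st.copies[f] * st.seqs[f].size for f in st.copies)
        genome_bp = repeat_bp + st.background.size
        out[leaf] = SpeciesProfile(
            species_code=leaf,
            copies=dict(st.copies),
            genome_size_pg=genome_bp / BP_PER_PG,
            family_seqs={f: _decode(s) for f, s in st.seqs.items()},
            classes=classes,
            background=_decode(st.background),
        )
    return out


# ---------------------------------------------------------------------------
# read emission


def emit_reads(profiles: dict[str, SpeciesProfile],
               read_len: int = 95,
               coverage: float = 0.01,
               divergence: float = 0.02,
               seed: int = 0,
               both_strands: bool = True,
               tree_newick: str = "",
               out_dir: str | Path | None = None,
               fastq: bool = False):
    """Draw per-species reads at fixed genome coverage with ground truth.

    Per species the read count is round(coverage x genome_bp / read_len).
    Sources (families + background) are sampled in proportion to their
    genomic base-pair share; satellite reads come from a circular tandem
    array of the monomer (so junction-spanning reads exist), dispersed and
    background reads from a uniform start on the linear sequence.  Each read
    then receives independent per-base substitutions at ``divergence`` and,
    if ``both_strands``, a random orientation.  Read ids are
    ``<CODE>_<serial>`` -- already carrying the four-letter species prefix
    used for pooling.

    Returns (reads, truth): reads maps species code to a list of
    (read_id, sequence); truth is the matching TruthTable.  When ``out_dir``
    is given, per-species FASTA (or FASTQ at uniform Q40) plus the truth TSV
    are written there.
    """
    if read_len < 30:
        raise ValueError("read_len must be >= 30")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    comp = str.maketrans("ACGT", "TGCA")

    reads: dict[str, list[tuple[str, str]]] = {}
    truth: dict[str, tuple[str, str]] = {}
    for code in sorted(profiles):
        prof = profiles[code]
        sources: list[tuple[str, str, int, bool]] = []  # id, seq, bp, satellite?
        for fam in sorted(prof.copies):
            n_copies = prof.copies[fam]
            if n_copies == 0:
                continue
            seq = prof.family_seqs[fam]
            sat = prof.classes.get(fam) == "satellite"
            if not sat and len(seq) < read_len:
                raise GenerationError(
                    f"{code}/{fam}: consensus ({len(seq)} bp) shorter than "
                    f"read length {read_len}")
            sources.append((fam, seq, n_copies * len(seq), sat))
        if prof.background:
            if len(prof.background) < read_len:
                raise GenerationError(
                    f"{code}: background shorter than read length")
            sources.append((BACKGROUND_ID, prof.background,
                            len(prof.background), False))
        genome_bp = prof.genome_size_bp
        n_reads = _round_half_up(coverage * genome_bp / read_len)
        species_reads: list[tuple[str, str]] = []
        if n_reads == 0:
            import warnings
            warnings.warn(f"{code}: coverage {coverage} yields 0 reads")
        else:
            weights = np.array([bp for _, _, bp, _ in sources], dtype=float)
            counts = rng.multinomial(n_reads, weights / weights.sum())
            serial = 0
            for (fam, seq, _, sat), cnt in zip(sources, counts):
                if cnt == 0:
                    continue
                if sat:
                    mono = len(seq)
                    tiled = seq * (read_len // mono + 2)
                    starts = rng.integers(0, mono, cnt)
                    source_str = tiled
                else:
                    starts = rng.integers(0, len(seq) - read_len + 1, cnt)
                    source_str = seq
                for s in starts:
                    frag = source_str[s:s + read_len]
                    hit = np.flatnonzero(rng.random(read_len) < divergence)
                    if hit.size:
                        chars = list(frag)
                        subs = rng.integers(1, 4, hit.size)
                        for pos, shift in zip(hit, subs):
                            chars[pos] = "ACGT"[("ACGT".index(chars[pos]) + shift) % 4]
                        frag = "".join(chars)
                    if both_strands and rng.random() < 0.5:
                        frag = frag.translate(comp)[::-1]
                    rid = f"{code}_{serial:06d}"
                    serial += 1
                    species_reads.append((rid, frag))
                    truth[rid] = (code, fam)
        reads[code] = species_reads

    table = TruthTable(reads=truth, tree_newick=tree_newick,
                       profiles=dict(profiles))
    if out_dir is not None:
        _write_outputs(reads, table, Path(out_dir), fastq)
    return reads, table


def _write_outputs(reads, table: TruthTable, out_dir: Path, fastq: bool) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out_dir.mkdir(parents=True, exist_ok=True)
    for code, recs in reads.items():
        if fastq:
            records = [
                SeqRecord(Seq(seq), id=rid, description="",
                          letter_annotations={"phred_quality": [40] * len(seq)})
                for rid, seq in recs]
            SeqIO.write(records, out_dir / f"{code}.fastq", "fastq")
        else:
            records = [SeqRecord(Seq(seq), id=rid, description="")
                       for rid, seq in recs]
            SeqIO.write(records, out_dir / f"{code}.fasta", "fasta")
    table.to_tsv(out_dir / "truth.tsv")
    if table.tree_newick:
        (out_dir / "true_tree.nwk").write_text(table.tree_newick + "\n")
    with open(out_dir / "profiles.tsv", "w") as fh:
        fh.write("species_code\tfamily_id\trepeat_class\tcopies\tgenome_size_pg\n")
        for code in sorted(table.profiles):
            prof = table.profiles[code]
            for fam in sorted(prof.copies):
                fh.write(f"{code}\t{fam}\t{prof.classes.get(fam, 'other')}\t"
                         f"{prof.copies[fam]}\t{prof.genome_size_pg:.6g}\n")


# ---------------------------------------------------------------------------
# the six-taxon allotetraploid preset


REPANDAE6_TREE = "(OBTU,(SYLV,(NUDI,(REPA,(NESO,STOC)))));"

#: (family_id, repeat_class, consensus length, root copies).  Copy numbers
#: keep every family dense enough at 0.01x coverage that reads tile the
#: consensus, while the summed genome stays megabase-scale.
REPANDAE6_FAMILIES = [
    ("gypA1", "Ty3-Gypsy-chromovirus", 800, 175),
    ("gypA2", "Ty3-Gypsy-chromovirus", 700, 120),
    ("gypB1", "Ty3-Gypsy-chromovirus", 600, 140),
    ("gypB2", "Ty3-Gypsy-chromovirus", 500, 170),
    ("gypC1", "Ty3-Gypsy-chromovirus", 450, 190),
    ("gypC2", "Ty3-Gypsy-chromovirus", 400, 210),
    ("copA1", "Ty1-Copia", 600, 140),
    ("copA2", "Ty1-Copia", 500, 170),
    ("copB1", "Ty1-Copia", 400, 210),
    ("copB2", "Ty1-Copia", 350, 240),
    ("satNNES", "satellite", 180, 100),
    ("satB1", "satellite", 350, 240),
    ("satB2", "satellite", 300, 280),
    ("dtA1", "DNA-transposon", 400, 210),
    ("dtA2", "DNA-transposon", 350, 240),
    ("dtB1", "DNA-transposon", 300, 280),
    ("dtB2", "DNA-transposon", 320, 260),
    ("othA1", "other", 600, 140),
    ("othA2", "other", 500, 170),
    ("othB1", "other", 450, 190),
    ("othB2", "other", 400, 210),
    ("othC1", "other", 350, 240),
    ("othC2", "other", 300, 280),
    ("plastidA", "plastid-like", 600, 280),
]

REPANDAE6_BACKGROUND_BP = 1_200_000


def repandae6_history() -> SpeciesHistory:
    """Two diploid progenitor lineages and a four-species polyploid clade.

    The allopolyploid ancestor ALLO is the child of the maternal (SYLV) and
    paternal (OBTU) ancestral lineages; NUDI is sister to
    (REPA,(NESO,STOC)) within the polyploid clade.
    """
    return SpeciesHistory(
        root="root",
        children={
            "root": ["SYLV_anc", "OBTU_anc"],
            "SYLV_anc": ["SYLV"],
            "OBTU_anc": ["OBTU"],
            "ALLO": ["NUDI", "REP_mrca"],
            "REP_mrca": ["REPA", "ISL_mrca"],
            "ISL_mrca": ["NESO", "STOC"],
        },
        allopolyploid=("ALLO", "SYLV_anc", "OBTU_anc"),
    )


def repandae6_families(seed: int = 0) -> list[RepeatFamily]:
    """Root repeat profile with random consensus sequences."""
    rng = np.random.default_rng(seed)
    fams = []
    for fid, cls, length, copies in REPANDAE6_FAMILIES:
        seq = _decode(rng.integers(0, 4, length, dtype=np.uint8))
        fams.append(RepeatFamily(fid, cls, seq, copies))
    return fams


def repandae6_model(seed: int = 0,
                    branch_divergence: float = 0.005) -> EvolModel:
    """Evolution preset: maternal-lineage expansion before hybridisation,
    chromovirus + satellite bursts on the (REPA,(NESO,STOC)) stem, and
    genome downsizing (including near-total satellite loss) on NUDI."""
    # drift scales roughly with branch duration: the polyploid clade radiated
    # ~5 Mya while the island pair split only ~0.2 Mya, so the island stem
    # carries nearly a full lineage's worth of drift and the island tips
    # almost none.
    drift = {
        "SYLV_anc": 0.15, "OBTU_anc": 0.15, "SYLV": 0.15, "OBTU": 0.15,
        "NUDI": 0.20, "REP_mrca": 0.10, "ISL_mrca": 0.30,
        "REPA": 0.20, "NESO": 0.02, "STOC": 0.02,
    }
    bursts = [
        ("SYLV_anc", "gypA1", 3.2),
        ("SYLV_anc", "gypA2", 3.2),
        ("SYLV_anc", "copA1", 2.5),
        ("SYLV_anc", "copA2", 2.5),
        ("SYLV_anc", "satB1", 2.0),
        ("REP_mrca", "gypA1", 1.6),
        ("REP_mrca", "gypA2", 1.6),
        ("REP_mrca", "gypB1", 1.5),
        ("REP_mrca", "gypB2", 1.5),
        ("REP_mrca", "copB2", 1.5),
        ("REP_mrca", "satNNES", 8.0),
        ("ISL_mrca", "gypC1", 1.8),
        ("ISL_mrca", "copB1", 1.7),
        ("ISL_mrca", "satB2", 1.6),
        ("ISL_mrca", "othC1", 1.5),
        ("ISL_mrca", "dtB1", 1.6),
        ("ISL_mrca", "othB1", 1.5),
        ("ISL_mrca", "dtB2", 1.5),
    ]
    # genome downsizing in NUDI is broad, touching most dispersed families
    deletions = [
        ("OBTU_anc", "gypA1", 0.7),
        ("OBTU_anc", "gypA2", 0.7),
        ("OBTU_anc", "othA1", 0.6),
        ("NUDI", "satNNES", 0.02),
        ("NUDI", "gypA1", 0.6),
        ("NUDI", "gypA2", 0.6),
        ("NUDI", "gypB1", 0.65),
        ("NUDI", "gypB2", 0.7),
        ("NUDI", "copA1", 0.7),
        ("NUDI", "copA2", 0.75),
        ("NUDI", "othA1", 0.7),
        ("NUDI", "othA2", 0.75),
        ("NUDI", "dtA1", 0.7),
        ("NUDI", "dtA2", 0.75),
        ("NUDI", "othB1", 0.8),
    ]
    return EvolModel(drift_sd=drift, bursts=bursts, deletions=deletions,
                     divergence=branch_divergence, seed=seed)


def copy_number_matrix(profiles: dict[str, SpeciesProfile]) -> AbundanceMatrix:
    """Per-species family copy numbers as an abundance matrix (the
    noise-free, copy-number-level analogue of the read-count matrix)."""
    import pandas as pd

    taxa = sorted(profiles)
    fams = sorted({f for p in profiles.values() for f in p.copies})
    data = {f: [float(profiles[sp].copies.get(f, 0)) for sp in taxa]
            for f in fams}
    return AbundanceMatrix(pd.DataFrame(data, index=taxa))


@dataclass
class SimulationRun:
    """Everything one synthetic run produced."""

    profiles: dict[str, SpeciesProfile]
    reads: dict[str, list[tuple[str, str]]]
    truth: TruthTable
    root_families: list[RepeatFamily] = field(default_factory=list)

    @property
    def plastid_reference(self) -> str:
        """Root consensus of the plastid-like family (the contaminant
        screening database for this run)."""
        return next(f.consensus for f in self.root_families
                    if f.repeat_class == "plastid-like")

    def pooled(self) -> list[tuple[str, str]]:
        """All reads pooled across species (ids carry species prefixes)."""
        return [rt for code in sorted(self.reads) for rt in self.reads[code]]


def simulate_repandae6(seed: int = 0,
                       coverage: float = 0.01,
                       read_len: int = 95,
                       read_divergence: float = 0.02,
                       null_model: bool = False,
                       out_dir: str | Path | None = None,
                       fastq: bool = False) -> SimulationRun:
    """Run the six-taxon preset end to end (profiles + reads + truth).

    ``null_model`` switches off all post-root evolution (no drift, bursts,
    deletions or sequence divergence), giving the pure additive-inheritance
    null in which every species equals the root profile and the polyploids
    are exactly the parental sums.
    """
    master = np.random.default_rng(seed)
    cons_seed, evol_seed, emit_seed = (int(s) for s in
                                       master.integers(0, 2 ** 31, size=3))
    families = repandae6_families(cons_seed)
    if null_model:
        model = EvolModel(seed=evol_seed)
    else:
        model = repandae6_model(evol_seed)
    history = repandae6_history()
    profiles = simulate_profiles(history, families, model,
                                 background_bp=REPANDAE6_BACKGROUND_BP)
    reads, truth = emit_reads(profiles, read_len=read_len, coverage=coverage,
                              divergence=read_divergence, seed=emit_seed,
                              tree_newick=REPANDAE6_TREE, out_dir=out_dir,
                              fastq=fastq)
    if out_dir is not None:
        out_dir = Path(out_dir)
        with open(out_dir / "genome_sizes.tsv", "w") as fh:
            fh.write("species_code\t1C_pg\n")
            for code in sorted(profiles):
                fh.write(f"{code}\t{profiles[code].genome_size_pg!r}\n")
        plastid = next(f for f in families if f.repeat_class == "plastid-like")
        with open(out_dir / "plastid_ref.fasta", "w") as fh:
            fh.write(f">{plastid.family_id} synthetic plastid-like reference\n")
            fh.write(plastid.consensus + "\n")
    return SimulationRun(profiles=profiles, reads=reads, truth=truth,
                         root_families=families)
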