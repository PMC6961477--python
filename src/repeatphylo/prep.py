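"""Read preprocessing ahead of clustering.

Mirrors the standard genome-skimming recipe for comparative repeat analysis:
quality-screen (Q20 over 95% of the read), trim to a common 95 bp, down-sample
every species to the same genome coverage (default 0.01x, so each species'
read share of a cluster estimates the genome proportion directly), prefix
read ids with a four-letter species code, and pool.
"""

from __future__ import annotations

import gzip
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .simulate import BP_PER_PG, ConfigurationError

__all__ = [
    "PrepParams",
    "SpeciesLibrary",
    "ParseError",
    "quality_filter",
    "trim_reads",
    "downsample",
    "prefix_and_pool",
    "read_fastx",
    "load_genome_sizes",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed sequence input, reported with the failing record index."""


@dataclass
class PrepParams:
    quality_threshold: int = 20      # phred
    quality_fraction: float = 0.95   # fraction of read length at/above it
    target_read_len: int = 95        # bp
    coverage: float = 0.01           # genome coverage after down-sampling
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.quality_fraction <= 1.0:
            raise ValueError("quality_fraction must be in (0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass
class SpeciesLibrary:
    """One species' read set with its code and 1C genome size."""

    species_code: str
    reads: list[SeqRecord] = field(repr=False)
    genome_size_pg: float

    def __post_init__(self):
        if not (len(self.species_code) == 4 and self.species_code.isalpha()):
            raise ValueError(
                f"species_code must be four letters, got {self.species_code!r}")
        if self.genome_size_pg <= 0:
            raise ValueError("genome_size_pg must be positive")

    @property
    def genome_size_bp(self) -> int:
        return round(self.genome_size_pg * BP_PER_PG)

    def __len__(self) -> int:
        return len(self.reads)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def read_fastx(path: str | Path) -> list[SeqRecord]:
    """Read FASTA or FASTQ (gzip-aware, sniffed from the first byte)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        head = fh.read(1)
        fh.seek(0)
        fmt = "fastq" if head == "@" else "fasta"
        out = []
        try:
            for i, rec in enumerate(SeqIO.parse(fh, fmt)):
                out.append(rec)
        except ValueError as exc:
            raise ParseError(
                f"{path.name}: malformed {fmt.upper()} at record "
                f"{len(out)}: {exc}") from exc
    return out


def load_genome_sizes(path: str | Path) -> dict[str, float]:
    """Two-column TSV (species_code, 1C in pg); '#' comments allowed."""
    sizes: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, pg = line.split("\t")[:2]
        if code.lower() in ("species_code", "code"):
            continue
        sizes[code] = float(pg)
    return sizes


def quality_filter(reads: list[SeqRecord], params: PrepParams | None = None) -> list[SeqRecord]:
    """Keep reads with >= quality_fraction of bases at/above the threshold.

    A read passes iff (bases with Q >= quality_threshold) / read length >=
    quality_fraction.  Input order is preserved.  Records without per-base
    qualities (FASTA input) skip the screen with a logged notice.
    """
    params = params or PrepParams()
    out = []
    n_skipped = 0
    for i, rec in enumerate(reads):
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None:
            n_skipped += 1
            out.append(rec)
            continue
        n = len(rec)
        if n == 0:
            continue
        good = sum(1 for q in quals if q >= params.quality_threshold)
        if good / n >= params.quality_fraction:
            out.append(rec)
    if n_skipped:
        logger.info("quality_filter: %d records had no base qualities "
                    "(FASTA input); passed through unscreened", n_skipped)
    return out


def trim_reads(reads: list[SeqRecord], target_read_len: int = 95) -> list[SeqRecord]:
    """Cut reads to their first ``target_read_len`` bases (the 5' end, where
    Illumina quality is best); discard reads shorter than the target."""
    out = []
    n_short = 0
    for rec in reads:
        if len(rec) < target_read_len:
            n_short += 1
            continue
        out.append(rec[:target_read_len] if len(rec) > target_read_len else rec)
    if n_short:
        logger.info("trim_reads: discarded %d reads shorter than %d bp",
                    n_short, target_read_len)
    return out


def downsample(library: SpeciesLibrary, params: PrepParams | None = None) -> SpeciesLibrary:
    """Sample reads without replacement down to the target genome coverage.

    The kept count is N = round(coverage x genome_size_bp / target_read_len),
    rounded half away from zero.  Sampling is uniform under ``params.seed``
    and preserves the original read order.
    """
    params = params or PrepParams()
    n = _round_half_up(params.coverage * library.genome_size_bp
                       / params.target_read_len)
    if n == 0:
        warnings.warn(f"{library.species_code}: requested coverage "
                      f"{params.coverage} yields 0 reads")
        return SpeciesLibrary(library.species_code, [], library.genome_size_pg)
    if n > len(library.reads):
        raise ValueError(
            f"{library.species_code}: need {n} reads for coverage "
            f"{params.coverage} but only {len(library.reads)} available")
    rng = np.random.default_rng(params.seed)
    idx = np.sort(rng.choice(len(library.reads), size=n, replace=False))
    return SpeciesLibrary(library.species_code,
                          [library.reads[i] for i in idx],
                          library.genome_size_pg)


def prefix_and_pool(libraries: list[SpeciesLibrary]) -> list[SeqRecord]:
    """Pool libraries with species-prefixed read ids.

    Each id becomes ``<CODE>_<original_id>``; ids already carrying their own
    library's prefix (as the synthetic generator emits) are left unchanged,
    so the operation is idempotent.  Duplicate codes are a configuration
    error.
    """
    codes = [lib.species_code for lib in libraries]
    if len(set(codes)) != len(codes):
        raise ConfigurationError(f"duplicate species codes in pool: {codes}")
    pooled: list[SeqRecord] = []
    for lib in libraries:
        prefix = lib.species_code + "_"
        for rec in lib.reads:
            rid = rec.id if rec.id.startswith(prefix) else prefix + rec.id
            out = rec[:]
            out.id = rid
            out.name = rid
            out.description = ""
            pooled.append(out)
    return pooled
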