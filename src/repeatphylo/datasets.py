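"""Published bookkeeping for the six-taxon *Nicotiana* sect. *Repandae* study.

These are the study's printed inputs -- per-species down-sampled read counts
(each representing 0.01x of that species' genome) and approximate 1C genome
sizes -- used for reproducing the pooled-dataset arithmetic without access
to the underlying SRA read sets.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["NicotianaSpecies", "SECT_REPANDAE", "pooled_read_total"]


@dataclass(frozen=True)
class NicotianaSpecies:
    code: str
    species: str
    downsampled_reads: int      # reads kept at 0.01x coverage
    genome_size_pg: float       # approximate 1C value
    role: str                   # diploid-maternal / diploid-paternal / polyploid


#: The six libraries of the published analysis.  SYLV and OBTU are the
#: closest extant relatives of the maternal and paternal progenitors; the
#: other four are the allotetraploids.
SECT_REPANDAE: dict[str, NicotianaSpecies] = {
    "SYLV": NicotianaSpecies("SYLV", "Nicotiana sylvestris", 277_472, 2.6,
                             "diploid-maternal"),
    "OBTU": NicotianaSpecies("OBTU", "Nicotiana obtusifolia", 159_052, 1.6,
                             "diploid-paternal"),
    "NUDI": NicotianaSpecies("NUDI", "Nicotiana nudicaulis", 366_000, 3.5,
                             "polyploid"),
    "REPA": NicotianaSpecies("REPA", "Nicotiana repanda", 560_000, 5.0,
                             "polyploid"),
    "STOC": NicotianaSpecies("STOC", "Nicotiana stocktonii", 514_526, 5.0,
                             "polyploid"),
    "NESO": NicotianaSpecies("NESO", "Nicotiana nesophila", 518_106, 5.0,
                             "polyploid"),
}


def pooled_read_total() -> int:
    """Size of the pooled clustering input: the sum of the six per-species
    down-sampled read counts."""
    return sum(sp.downsampled_reads for sp in SECT_REPANDAE.values())
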