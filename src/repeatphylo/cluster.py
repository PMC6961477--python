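"""Graph-based clustering of pooled reads into repeat families.

Reads become vertices; a pair is joined whenever its best local alignment
reaches 90% identity over at least 55% of the shorter read (see
:mod:`repeatphylo.align` for the engine).  Connected components of this
similarity graph are the repeat clusters; each cluster's per-species read
share at equal genome coverage estimates the percent of the 1C genome the
family occupies.  Clusters matching a user-supplied contaminant reference
(typically a plastid genome) are screened out before the abundance matrix is
assembled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .align import ReferenceIndex, SimilarityHit, find_hits
from .matrices import AbundanceMatrix

__all__ = [
    "RepeatCluster",
    "AccountingError",
    "build_graph",
    "cluster_graph",
    "genome_proportions",
    "plastid_screen",
    "top_n_matrix",
    "cluster_reads",
    "species_of_read",
    "clusters_to_tsv",
    "membership_to_tsv",
]

logger = logging.getLogger(__name__)


class AccountingError(ValueError):
    """A read id whose prefix does not map to any known species library."""


@dataclass
class RepeatCluster:
    """A connected community of reads interpreted as one repeat family."""

    cluster_id: str
    members: list[str] = field(repr=False)
    species_counts: dict[str, int] = field(default_factory=dict)
    proportions: dict[str, float] = field(default_factory=dict)  # percent of 1C
    annotation: str | None = None
    plastid_flag: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


def species_of_read(read_id: str) -> str:
    """The four-letter species prefix of a pooled read id."""
    return read_id.split("_", 1)[0]


def build_graph(hits: list[SimilarityHit], read_ids: list[str]) -> nx.Graph:
    """Similarity graph: one vertex per pooled read (singletons kept), one
    weighted edge per passing hit."""
    g = nx.Graph()
    g.add_nodes_from(read_ids)
    for h in hits:
        g.add_edge(h.read_a, h.read_b, weight=h.score, identity=h.identity)
    return g


def cluster_graph(graph: nx.Graph, refine: bool = False,
                  modularity_threshold: float = 0.3) -> list[RepeatCluster]:
    """Connected components, optionally split by greedy modularity.

    With ``refine``, any component whose greedy-modularity partition scores
    above ``modularity_threshold`` is replaced by its communities (off by
    default: at fixture divergence levels plain components recover families).
    Clusters are ranked by size descending, ties broken by the smallest
    member read id, and labelled CL1, CL2, ...
    """
    groups: list[list[str]] = []
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        if refine and len(comp) > 3:
            sub = graph.subgraph(comp)
            if sub.number_of_edges() > 0:
                parts = list(nx.community.greedy_modularity_communities(sub))
                if len(parts) > 1:
                    q = nx.community.modularity(sub, parts)
                    if q > modularity_threshold:
                        logger.info("splitting component of %d reads into %d "
                                    "communities (modularity %.2f)",
                                    len(comp), len(parts), q)
                        groups.extend(sorted(p) for p in parts)
                        continue
        groups.append(comp)
    groups.sort(key=lambda ms: (-len(ms), ms[0]))
    clusters = []
    for rank, members in enumerate(groups, start=1):
        counts: dict[str, int] = {}
        for rid in members:
            sp = species_of_read(rid)
            counts[sp] = counts.get(sp, 0) + 1
        clusters.append(RepeatCluster(f"CL{rank}", members, counts))
    return clusters


def genome_proportions(clusters: list[RepeatCluster],
                       pooled_counts: dict[str, int]) -> list[RepeatCluster]:
    """Fill per-species genome proportions (percent).

    proportion(species, cluster) = 100 x cluster reads from that species /
    that species' total pooled reads.  Because every species is at equal
    genome coverage this estimates the percent of its 1C genome the cluster
    occupies.  ``pooled_counts`` maps species code to its pooled read count.
    """
    for cl in clusters:
        unknown = set(cl.species_counts) - set(pooled_counts)
        if unknown:
            raise AccountingError(
                f"{cl.cluster_id}: read prefixes {sorted(unknown)} match no "
                "species library")
        cl.proportions = {
            sp: 100.0 * cl.species_counts.get(sp, 0) / pooled_counts[sp]
            for sp in pooled_counts if pooled_counts[sp] > 0}
    return clusters


def plastid_screen(clusters: list[RepeatCluster],
                   reads: dict[str, str],
                   reference: str,
                   min_identity: float = 0.90,
                   min_overlap_frac: float = 0.55,
                   min_frac_reads: float = 0.5,
                   sample_cap: int = 50,
                   seed: int = 0):
    """Flag and remove clusters matching a contaminant reference.

    A cluster is removed iff at least ``min_frac_reads`` of a size-capped
    sample of its member reads align to the reference at ``min_identity``
    over at least ``min_overlap_frac`` of the read.  Returns
    (kept, removed); removed cluster ids are logged.
    """
    index = ReferenceIndex(reference)
    rng = np.random.default_rng(seed)
    kept, removed = [], []
    for cl in clusters:
        members = sorted(cl.members)
        if len(members) > sample_cap:
            pick = np.sort(rng.choice(len(members), sample_cap, replace=False))
            members = [members[i] for i in pick]
        n_hit = sum(index.matches(reads[rid], min_identity, min_overlap_frac)
                    for rid in members)
        cl.plastid_flag = n_hit >= min_frac_reads * len(members)
        (removed if cl.plastid_flag else kept).append(cl)
    if removed:
        logger.info("plastid screen removed %d clusters: %s",
                    len(removed), [c.cluster_id for c in removed])
    return kept, removed


def top_n_matrix(clusters: list[RepeatCluster], taxa: list[str],
                 n: int = 1000, min_frac: float = 0.0) -> AbundanceMatrix:
    """Per-species read counts of the min(n, #clusters) largest clusters.

    ``min_frac`` additionally drops clusters holding less than that fraction
    of the listed clusters' total reads (RepeatExplorer-style size floor).
    At full data scale the top-n largest clusters are all far above any such
    floor, but on desk-scale pools tiny orthologous-locus clusters of 2-3
    reads would otherwise slip into the character matrix as pure noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = sum(c.size for c in clusters)
    floor = min_frac * total
    ordered = [c for c in sorted(clusters, key=lambda c: (-c.size, min(c.members)))
               if c.size >= floor][:n]
    data = {cl.cluster_id: [cl.species_counts.get(sp, 0) for sp in taxa]
            for cl in ordered}
    return AbundanceMatrix(pd.DataFrame(data, index=list(taxa), dtype=float))


def cluster_reads(pooled, pooled_counts: dict[str, int] | None = None,
                  min_identity: float = 0.90, min_overlap_frac: float = 0.55,
                  k: int = 17, refine: bool = False) -> list[RepeatCluster]:
    """find_hits -> build_graph -> cluster_graph (+ proportions) in one call.

    ``pooled`` is a list of (read_id, sequence) pairs or SeqRecords.
    """
    items = [(str(r[0]), str(r[1])) if isinstance(r, tuple)
             else (str(r.id), str(r.seq)) for r in pooled]
    hits = find_hits(items, min_identity=min_identity,
                     min_overlap_frac=min_overlap_frac, k=k)
    graph = build_graph(hits, [rid for rid, _ in items])
    clusters = cluster_graph(graph, refine=refine)
    if pooled_counts is None:
        pooled_counts = {}
        for rid, _ in items:
            sp = species_of_read(rid)
            pooled_counts[sp] = pooled_counts.get(sp, 0) + 1
    return genome_proportions(clusters, pooled_counts)


# ---------------------------------------------------------------------------
# tabular output


def clusters_to_tsv(clusters: list[RepeatCluster], taxa: list[str], path) -> None:
    with open(path, "w") as fh:
        cols = ["cluster_id", "size"]
        cols += [f"n_{sp}" for sp in taxa] + [f"pct_{sp}" for sp in taxa]
        cols += ["annotation", "plastid_flag"]
        fh.write("\t".join(cols) + "\n")
        for cl in clusters:
            row = [cl.cluster_id, str(cl.size)]
            row += [str(cl.species_counts.get(sp, 0)) for sp in taxa]
            row += [f"{cl.proportions.get(sp, 0.0):.4f}" for sp in taxa]
            row += [cl.annotation or ".", str(int(cl.plastid_flag))]
            fh.write("\t".join(row) + "\n")


def membership_to_tsv(clusters: list[RepeatCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcluster_id\n")
        for cl in clusters:
            for rid in sorted(cl.members):
                fh.write(f"{rid}\t{cl.cluster_id}\n")
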