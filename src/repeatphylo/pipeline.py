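"""End-to-end orchestration: simulate -> prep -> cluster -> phylo -> additivity.

Each stage reads only the previous stage's files under the run directory, so
a run is reproducible from its config alone: one global seed derives a
per-stage seed by stable hashing of the stage name, and identical
config+seed yields byte-identical outputs (the run report records a sha256
checksum per output file).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import additivity as addmod
from . import cluster as clmod
from . import phylo as phmod
from . import prep as prmod
from .matrices import AbundanceMatrix, cube_root_transform
from .simulate import BACKGROUND_ID, ConfigurationError, simulate_repandae6

__all__ = ["RunConfig", "run_all", "run_stage", "report_top_clusters",
           "annotate_from_truth", "stage_seed"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prep", "cluster", "phylo", "additivity")

_DEFAULTS: dict = {
    "simulate": {"preset": "repandae6", "coverage": 0.02, "read_len": 95,
                 "divergence": 0.02, "fastq": False},
    "prep": {"quality_threshold": 20, "quality_fraction": 0.95,
             "target_read_len": 95, "coverage": 0.01, "genome_sizes": None},
    "cluster": {"min_identity": 0.90, "min_overlap_frac": 0.55, "kmer": 17,
                "refine": False, "top_n": 1000, "min_cluster_frac": 0.001,
                "plastid_ref": None},
    "phylo": {"transform": "cube_root", "outgroup": "OBTU", "reps": 200,
              "scheme": "symmetric", "p_change": 0.33},
    "additivity": {"parents": {"NUDI": ["SYLV", "OBTU"],
                               "REPA": ["SYLV", "OBTU"],
                               "NESO": ["SYLV", "OBTU"],
                               "STOC": ["SYLV", "OBTU"]},
                   "rank_by": "expected", "mode": "reads"},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: sha256 of '<seed>:<stage>' reduced mod 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:15], 16) % (2 ** 31)


@dataclass
class RunConfig:
    """All stage parameter blocks plus the global seed and output directory."""

    seed: int = 0
    out_dir: str = "runs/run"
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        stages = {}
        for stage in STAGES:
            block = dict(_DEFAULTS[stage])
            block.update(raw.get(stage) or {})
            stages[stage] = block
        return cls(seed=int(raw.get("seed", 0)),
                   out_dir=str(raw.get("out_dir", "runs/run")),
                   stages=stages)

    def validate(self) -> None:
        """Fail before any compute if referenced files are missing or the
        species bookkeeping is inconsistent."""
        for key in ("genome_sizes", "plastid_ref"):
            for stage in STAGES:
                path = self.stages[stage].get(key)
                if path is not None and not Path(path).exists():
                    raise ConfigurationError(
                        f"{stage}.{key}: file {path!r} does not exist")
        parents = self.stages["additivity"]["parents"]
        for poly, pair in parents.items():
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ConfigurationError(
                    f"additivity.parents[{poly}] must be two distinct codes")


# ---------------------------------------------------------------------------
# stages


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_dir(cfg: RunConfig, stage: str) -> Path:
    d = Path(cfg.out_dir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _run_simulate(cfg: RunConfig) -> dict:
    p = cfg.stages["simulate"]
    if p["preset"] != "repandae6":
        raise ConfigurationError(f"unknown preset {p['preset']!r}")
    out = _stage_dir(cfg, "simulate")
    run = simulate_repandae6(seed=stage_seed(cfg.seed, "simulate"),
                             coverage=p["coverage"], read_len=p["read_len"],
                             read_divergence=p["divergence"], out_dir=out,
                             fastq=p["fastq"])
    return {"n_reads": {c: len(v) for c, v in run.reads.items()},
            "genome_pg": {c: run.profiles[c].genome_size_pg
                          for c in sorted(run.profiles)}}


def _run_prep(cfg: RunConfig) -> dict:
    p = cfg.stages["prep"]
    sim = Path(cfg.out_dir) / "simulate"
    out = _stage_dir(cfg, "prep")
    sizes_path = p["genome_sizes"] or sim / "genome_sizes.tsv"
    if not Path(sizes_path).exists():
        raise ConfigurationError(f"genome-size table {sizes_path} not found")
    sizes = prmod.load_genome_sizes(sizes_path)
    params = prmod.PrepParams(quality_threshold=p["quality_threshold"],
                              quality_fraction=p["quality_fraction"],
                              target_read_len=p["target_read_len"],
                              coverage=p["coverage"],
                              seed=stage_seed(cfg.seed, "prep"))
    libraries = []
    for code in sorted(sizes):
        fasta = sim / f"{code}.fasta"
        fastq = sim / f"{code}.fastq"
        reads = prmod.read_fastx(fastq if fastq.exists() else fasta)
        reads = prmod.quality_filter(reads, params)
        reads = prmod.trim_reads(reads, params.target_read_len)
        lib = prmod.SpeciesLibrary(code, reads, sizes[code])
        libraries.append(prmod.downsample(lib, params))
    pooled = prmod.prefix_and_pool(libraries)
    from Bio import SeqIO
    SeqIO.write(pooled, out / "pooled.fasta", "fasta")
    counts = {lib.species_code: len(lib) for lib in libraries}
    with open(out / "pooled_counts.tsv", "w") as fh:
        fh.write("species_code\tn_reads\n")
        for code in sorted(counts):
            fh.write(f"{code}\t{counts[code]}\n")
    return {"n_per_species": counts, "n_pooled": len(pooled)}


def _run_cluster(cfg: RunConfig) -> dict:
    p = cfg.stages["cluster"]
    prep = Path(cfg.out_dir) / "prep"
    sim = Path(cfg.out_dir) / "simulate"
    out = _stage_dir(cfg, "cluster")
    pooled = prmod.read_fastx(prep / "pooled.fasta")
    pooled_counts = {}
    for line in (prep / "pooled_counts.tsv").read_text().splitlines()[1:]:
        code, n = line.split("\t")
        pooled_counts[code] = int(n)
    clusters = clmod.cluster_reads(pooled, pooled_counts,
                                   min_identity=p["min_identity"],
                                   min_overlap_frac=p["min_overlap_frac"],
                                   k=p["kmer"], refine=p["refine"])
    ref_path = p["plastid_ref"] or sim / "plastid_ref.fasta"
    removed = []
    if Path(ref_path).exists():
        reads = {str(r.id): str(r.seq) for r in pooled}
        ref_seq = str(prmod.read_fastx(ref_path)[0].seq)
        kept, removed = clmod.plastid_screen(
            clusters, reads, ref_seq,
            min_identity=p["min_identity"],
            min_overlap_frac=p["min_overlap_frac"],
            seed=stage_seed(cfg.seed, "cluster"))
    else:
        kept = clusters
    truth_path = sim / "truth.tsv"
    if truth_path.exists():
        annotate_from_truth(clusters, truth_path, sim / "profiles.tsv")
    taxa = sorted(pooled_counts)
    clmod.clusters_to_tsv(clusters, taxa, out / "clusters.tsv")
    clmod.membership_to_tsv(clusters, out / "membership.tsv")
    matrix = clmod.top_n_matrix(kept, taxa, n=p["top_n"],
                                min_frac=p["min_cluster_frac"])
    matrix.to_tsv(out / "matrix.tsv")
    return {"n_clusters": len(clusters), "n_removed_plastid": len(removed),
            "n_matrix_clusters": len(matrix.cluster_ids)}


def _run_phylo(cfg: RunConfig) -> dict:
    p = cfg.stages["phylo"]
    out = _stage_dir(cfg, "phylo")
    matrix = AbundanceMatrix.from_tsv(Path(cfg.out_dir) / "cluster" / "matrix.tsv")
    if p["transform"] == "cube_root":
        cm = cube_root_transform(matrix)
    elif p["transform"] == "raw":
        from .matrices import CharacterMatrix
        cm = CharacterMatrix(matrix.data, transform_tag="raw")
    else:
        raise ConfigurationError(f"unknown transform {p['transform']!r}")
    mp_trees = phmod.exhaustive_search(cm)
    best = mp_trees[0]
    supports, replicates = phmod.resample_support(
        cm, reference=best, n_reps=p["reps"], scheme=p["scheme"],
        p_change=p["p_change"], seed=stage_seed(cfg.seed, "phylo"),
        return_replicates=True)
    rooted = phmod.root_on_outgroup(best, p["outgroup"])
    phmod.write_tree(rooted, out / "mp_tree.nwk")
    with open(out / "supports.tsv", "w") as fh:
        fh.write("clade\tsupport_pct\n")
        for s, v in sorted(supports.items(), key=lambda kv: sorted(kv[0])):
            fh.write(f"{','.join(sorted(s))}\t{v:.2f}\n")
    with open(out / "bipartitions.tsv", "w") as fh:
        fh.write("replicate\tconsensus_bipartitions\n")
        for r, cons in enumerate(replicates):
            parts = sorted(",".join(sorted(s)) for s in cons)
            fh.write(f"{r}\t{';'.join(parts)}\n")
    return {"n_mp_trees": len(mp_trees),
            "total_length": best.total_length,
            "mp_tree": phmod.tree_to_newick(rooted)}


def _run_additivity(cfg: RunConfig) -> dict:
    p = cfg.stages["additivity"]
    out = _stage_dir(cfg, "additivity")
    parents = addmod.ParentMap({k: tuple(v) for k, v in p["parents"].items()})
    if p["mode"] == "reads":
        matrix = AbundanceMatrix.from_tsv(
            Path(cfg.out_dir) / "cluster" / "matrix.tsv")
    elif p["mode"] == "copies":
        prof = pd.read_csv(Path(cfg.out_dir) / "simulate" / "profiles.tsv",
                           sep="\t")
        wide = prof.pivot(index="species_code", columns="family_id",
                          values="copies").fillna(0.0)
        matrix = AbundanceMatrix(wide.astype(float))
    else:
        raise ConfigurationError(f"unknown additivity mode {p['mode']!r}")
    curves = [addmod.deviation_curve(matrix, parents, poly,
                                     rank_by=p["rank_by"])
              for poly in parents.polyploids()]
    for c in curves:
        c.to_tsv(out / f"curve_{c.polyploid}.tsv")
    dists = addmod.curve_distance(curves)
    dists.to_csv(out / "curve_distances.tsv", sep="\t")
    addmod.plot_curves(curves, out / "curves.png")
    return {"endpoints": {c.polyploid: c.endpoint for c in curves}}


_RUNNERS = {"simulate": _run_simulate, "prep": _run_prep,
            "cluster": _run_cluster, "phylo": _run_phylo,
            "additivity": _run_additivity}


def run_stage(cfg: RunConfig, stage: str) -> dict:
    t0 = time.time()
    logger.info("stage %s: starting", stage)
    try:
        summary = _RUNNERS[stage](cfg)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    summary["elapsed_s"] = round(time.time() - t0, 2)
    logger.info("stage %s: done in %.1fs", stage, summary["elapsed_s"])
    return summary


def run_all(cfg: RunConfig) -> dict:
    """Execute all stages in order and write a run report with parameters,
    per-stage summaries and output checksums."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logging.getLogger("repeatphylo").addHandler(handler)
    try:
        report = {"seed": cfg.seed, "parameters": cfg.stages, "stages": {}}
        for stage in STAGES:
            report["stages"][stage] = run_stage(cfg, stage)
        checksums = {}
        for path in sorted(out.rglob("*")):
            if path.is_file() and path.suffix in {".tsv", ".fasta", ".fastq",
                                                  ".nwk"}:
                checksums[str(path.relative_to(out))] = _sha256(path)
        report["checksums"] = checksums
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    finally:
        logging.getLogger("repeatphylo").removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# reporting


def annotate_from_truth(clusters, truth_tsv, profiles_tsv) -> None:
    """Label each cluster with the repeat class of the majority true family
    among its member reads (simulation truth as the annotation source)."""
    fam_of = {}
    for line in Path(truth_tsv).read_text().splitlines()[1:]:
        rid, _, fam = line.split("\t")
        fam_of[rid] = fam
    class_of = {BACKGROUND_ID: "single-copy"}
    df = pd.read_csv(profiles_tsv, sep="\t")
    for _, row in df.iterrows():
        class_of[row["family_id"]] = row["repeat_class"]
    for cl in clusters:
        fams = [fam_of.get(r) for r in cl.members]
        fams = [f for f in fams if f is not None]
        if not fams:
            continue
        top = max(set(fams), key=fams.count)
        cl.annotation = class_of.get(top, "other")


def report_top_clusters(clusters, taxa: list[str], n: int = 15) -> pd.DataFrame:
    """Per-species genome proportions of the n largest clusters with their
    repeat-class annotation (the classic top-clusters composition table).
    Plastid-flagged clusters are excluded, as they are removed upstream."""
    ordered = sorted((c for c in clusters if not c.plastid_flag),
                     key=lambda c: (-c.size, min(c.members)))[:n]
    rows = []
    for cl in ordered:
        row = {"cluster_id": cl.cluster_id,
               "annotation": cl.annotation or "."}
        for sp in taxa:
            row[f"pct_{sp}"] = round(cl.proportions.get(sp, 0.0), 4)
        rows.append(row)
    return pd.DataFrame(rows)
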