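"""Synthetic genome evolution and read emission against hand-derived truth."""

import numpy as np
import pytest

from repeatphylo.simulate import (BACKGROUND_ID, ConfigurationError,
                                  EvolModel, GenerationError, RepeatFamily,
                                  SpeciesHistory, emit_reads,
                                  simulate_profiles, simulate_repandae6)
from conftest import random_seq


def two_parent_history() -> SpeciesHistory:
    return SpeciesHistory(
        root="root",
        children={"root": ["MAT", "PAT"], "MAT": ["MATX"], "PAT": ["PATX"],
                  "POLY": ["AAAA", "MRCA"], "MRCA": ["BBBB", "CCCC"]},
        allopolyploid=("POLY", "MAT", "PAT"),
    )


def families(rng):
    return [
        RepeatFamily("famA", "Ty3-Gypsy-chromovirus", random_seq(rng, 500), 100),
        RepeatFamily("famB", "satellite", random_seq(rng, 180), 50),
        RepeatFamily("famC", "other", random_seq(rng, 400), 30),
    ]


def test_repeat_family_validation(rng):
    with pytest.raises(ValueError):
        RepeatFamily("x", "nonsense-class", "ACGT" * 100, 1)
    with pytest.raises(ValueError):
        RepeatFamily("x", "other", "", 1)
    with pytest.raises(ValueError):
        RepeatFamily("x", "other", "ACGN" * 100, 1)
    with pytest.raises(ValueError):
        RepeatFamily("x", "satellite", random_seq(rng, 450), 1)  # monomer cap 400
    with pytest.raises(ValueError):
        RepeatFamily("x", "other", random_seq(rng, 500), -1)


def test_zero_drift_identity_and_polyploid_doubling(rng):
    """With no drift/events every descendant equals the root profile and the
    polyploid is exactly twice it (sum of two identical parents)."""
    fams = families(rng)
    profs = simulate_profiles(two_parent_history(), fams,
                              EvolModel(seed=1), background_bp=50_000)
    root_copies = {f.family_id: f.base_copies for f in fams}
    for code in ("MATX", "PATX"):
        assert profs[code].copies == root_copies
    for code in ("AAAA", "BBBB", "CCCC"):
        assert profs[code].copies == {f: 2 * c for f, c in root_copies.items()}
        assert len(profs[code].background) == 100_000  # both complements


def test_additivity_is_exact_integer_sum(rng):
    """Polyploid copies equal maternal + paternal copies elementwise, even
    when the parental lineages have drifted apart."""
    fams = families(rng)
    history = SpeciesHistory(
        root="root",
        children={"root": ["MAT", "PAT"], "MAT": ["MATX"], "PAT": ["PATX"],
                  "POLY": ["AAAA"]},
        allopolyploid=("POLY", "MAT", "PAT"),
    )
    model = EvolModel(drift_sd={"MAT": 0.4, "PAT": 0.4},
                      bursts=[("MAT", "famA", 2.0)],
                      deletions=[("PAT", "famB", 0.5)], seed=7)
    profs = simulate_profiles(history, fams, model, background_bp=10_000)
    # recompute parental states: the tip branches MATX/PATX have no drift
    # configured, so the tips ARE the parental states at hybridisation
    for fam in ("famA", "famB", "famC"):
        assert (profs["AAAA"].copies[fam]
                == profs["MATX"].copies[fam] + profs["PATX"].copies[fam])


def test_parental_sum_example_100_plus_50(rng):
    fams = [RepeatFamily("F", "other", random_seq(rng, 400), 0)]
    history = SpeciesHistory(
        root="root",
        children={"root": ["MAT", "PAT"], "MAT": ["MATX"], "PAT": ["PATX"],
                  "POLY": ["AAAA"]},
        allopolyploid=("POLY", "MAT", "PAT"),
    )
    model = EvolModel(bursts=[("MAT", "F", 100.0), ("PAT", "F", 50.0)], seed=0)
    fams[0].base_copies = 1
    profs = simulate_profiles(history, fams, model, background_bp=10_000)
    assert profs["MATX"].copies["F"] == 100
    assert profs["PATX"].copies["F"] == 50
    assert profs["AAAA"].copies["F"] == 150


def test_burst_propagates_to_whole_clade(rng):
    """A 12x burst on the stem of a three-taxon clade multiplies all three
    descendants and leaves the sister taxon unchanged (hand-propagated)."""
    fams = families(rng)
    model = EvolModel(bursts=[("MRCA", "famB", 12.0)], seed=0)
    profs = simulate_profiles(two_parent_history(), fams, model,
                              background_bp=10_000)
    # polyploid root state: famB = 50 + 50 = 100; MRCA branch bursts to 1200
    assert profs["AAAA"].copies["famB"] == 100       # sister: unchanged
    assert profs["BBBB"].copies["famB"] == 1200
    assert profs["CCCC"].copies["famB"] == 1200
    for code in ("AAAA", "BBBB", "CCCC"):
        assert profs[code].copies["famA"] == 200     # untouched family


def test_event_validation_errors(rng):
    fams = families(rng)
    with pytest.raises(ConfigurationError):
        simulate_profiles(two_parent_history(), fams,
                          EvolModel(bursts=[("NOPE", "famA", 2.0)]))
    with pytest.raises(ConfigurationError):
        simulate_profiles(two_parent_history(), fams,
                          EvolModel(deletions=[("MAT", "ghost", 0.5)]))
    with pytest.raises(ValueError):
        EvolModel(bursts=[("MAT", "famA", -1.0)])
    with pytest.raises(ValueError):
        EvolModel(deletions=[("MAT", "famA", 1.5)])


def test_genome_size_consistency(rng):
    profs = simulate_profiles(two_parent_history(), families(rng),
                              EvolModel(drift_sd=0.2, seed=3),
                              background_bp=80_000)
    for prof in profs.values():
        prof.validate()  # pg consistent with sequence content


def test_read_count_follows_coverage_formula(rng):
    """genome 9,500,000 bp at 0.01x with 95 bp reads -> exactly 1,000 reads."""
    fams = [RepeatFamily("famA", "other", random_seq(rng, 500), 18_000)]
    history = SpeciesHistory(root="root", children={"root": ["AAAA"]})
    profs = simulate_profiles(history, fams, EvolModel(), background_bp=500_000)
    assert profs["AAAA"].genome_size_bp == 9_500_000
    reads, truth = emit_reads(profs, read_len=95, coverage=0.01, divergence=0,
                              seed=0)
    assert len(reads["AAAA"]) == 1000
    assert len(truth.reads) == 1000


def test_zero_divergence_reads_are_exact_substrings(rng):
    fams = families(rng)
    profs = simulate_profiles(two_parent_history(), fams, EvolModel(seed=2),
                              background_bp=20_000)
    reads, truth = emit_reads(profs, divergence=0.0, seed=5,
                              both_strands=False)
    comp = str.maketrans("ACGT", "TGCA")
    for code, recs in reads.items():
        prof = profs[code]
        for rid, seq in recs:
            fam = truth.reads[rid][1]
            if fam == BACKGROUND_ID:
                src = prof.background
            else:
                src = prof.family_seqs[fam]
                if prof.classes[fam] == "satellite":
                    src = src * (95 // len(src) + 2)   # circular tandem array
            assert seq in src or seq.translate(comp)[::-1] in src


def test_emission_is_byte_identical_per_seed(rng):
    run1 = simulate_repandae6(seed=11)
    run2 = simulate_repandae6(seed=11)
    assert run1.reads == run2.reads
    assert run1.truth.reads == run2.truth.reads
    run3 = simulate_repandae6(seed=12)
    assert run3.reads != run1.reads


def test_truth_table_lists_every_read_exactly_once(fixture_run):
    ids = [rid for _, recs in fixture_run.reads.items() for rid, _ in recs]
    assert len(ids) == len(set(ids))
    assert set(ids) == set(fixture_run.truth.reads)


def test_read_fractions_approach_genome_fractions(rng):
    """Realised per-family read share matches its genomic share within 3
    binomial standard deviations (high coverage to shrink the noise)."""
    fams = families(rng)
    history = SpeciesHistory(root="root", children={"root": ["AAAA"]})
    profs = simulate_profiles(history, fams, EvolModel(), background_bp=30_000)
    reads, truth = emit_reads(profs, coverage=0.5, divergence=0, seed=9)
    prof = profs["AAAA"]
    n = len(reads["AAAA"])
    for fam in ("famA", "famB", "famC"):
        p = prof.copies[fam] * len(prof.family_seqs[fam]) / prof.genome_size_bp
        got = sum(1 for rid, _ in reads["AAAA"]
                  if truth.reads[rid][1] == fam)
        assert abs(got - n * p) <= 3 * np.sqrt(n * p * (1 - p)) + 1


def test_read_len_longer_than_source_is_generation_error(rng):
    fams = [RepeatFamily("famA", "other", random_seq(rng, 400), 100)]
    history = SpeciesHistory(root="root", children={"root": ["AAAA"]})
    profs = simulate_profiles(history, fams, EvolModel(), background_bp=10_000)
    with pytest.raises(GenerationError):
        emit_reads(profs, read_len=450, coverage=0.01, seed=0)


def test_repandae6_fixture_headline_properties(fixture_run):
    """>= 10 families; the burst satellite is <0.1% of the genome in exactly
    one polyploid; pooled size is in the intended few-thousand range."""
    run = fixture_run
    fams = {f for _, f in run.truth.reads.values() if f != BACKGROUND_ID}
    assert len(fams) >= 10
    low_sat = [code for code in ("NUDI", "REPA", "NESO", "STOC")
               if (run.profiles[code].copies["satNNES"] * 180
                   / run.profiles[code].genome_size_bp) < 0.001]
    assert low_sat == ["NUDI"]
    pooled = sum(len(v) for v in run.reads.values())
    assert 3000 <= pooled <= 7000
    # downsized polyploid is the smallest polyploid genome
    sizes = {c: run.profiles[c].genome_size_bp
             for c in ("NUDI", "REPA", "NESO", "STOC")}
    assert min(sizes, key=sizes.get) == "NUDI"
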