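"""Graph clustering, ranking, proportions, plastid screening, matrices."""

import networkx as nx
import pytest
from _oracles import oracle_hit_pairs

from repeatphylo.align import SimilarityHit, find_hits
from repeatphylo.cluster import (AccountingError, build_graph, cluster_graph,
                                 genome_proportions, plastid_screen,
                                 species_of_read, top_n_matrix)
from repeatphylo.simulate import BACKGROUND_ID
from conftest import random_seq


def hit(a, b):
    return SimilarityHit(a, b, 1.0, 95, 95.0)


def test_no_hits_gives_edgeless_graph():
    g = build_graph([], ["AAAA_1", "AAAA_2"])
    assert g.number_of_nodes() == 2
    assert g.number_of_edges() == 0


def test_complete_graph_edge_count():
    ids = [f"AAAA_{i}" for i in range(6)]
    hits = [hit(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    g = build_graph(hits, ids)
    assert g.number_of_edges() == 6 * 5 // 2


def test_two_cliques_give_two_clusters_singletons_rank_last():
    ids_a = [f"AAAA_a{i}" for i in range(5)]
    ids_b = [f"BBBB_b{i}" for i in range(3)]
    lone = ["CCCC_x", "CCCC_y"]
    hits = [hit(a, b) for i, a in enumerate(ids_a) for b in ids_a[i + 1:]]
    hits += [hit(a, b) for i, a in enumerate(ids_b) for b in ids_b[i + 1:]]
    clusters = cluster_graph(build_graph(hits, ids_a + ids_b + lone))
    assert [c.cluster_id for c in clusters] == ["CL1", "CL2", "CL3", "CL4"]
    assert sorted(clusters[0].members) == sorted(ids_a)
    assert sorted(clusters[1].members) == sorted(ids_b)
    assert {c.size for c in clusters[2:]} == {1}
    # read conservation: cluster sizes sum to the pool size
    assert sum(c.size for c in clusters) == len(ids_a) + len(ids_b) + len(lone)


def test_rank_ties_break_by_smallest_member_id():
    hits = [hit("AAAA_z1", "AAAA_z2"), hit("AAAA_a1", "AAAA_a2")]
    clusters = cluster_graph(build_graph(
        hits, ["AAAA_z1", "AAAA_z2", "AAAA_a1", "AAAA_a2"]))
    assert clusters[0].members[0] == "AAAA_a1"


def test_genome_proportion_arithmetic():
    cl = cluster_graph(build_graph(
        [hit(f"SYLV_{i}", f"SYLV_{i+1}") for i in range(24)],
        [f"SYLV_{i}" for i in range(25)]))
    genome_proportions(cl, {"SYLV": 1000, "OBTU": 500})
    assert cl[0].proportions["SYLV"] == pytest.approx(2.5)   # 25 / 1000
    assert cl[0].proportions["OBTU"] == pytest.approx(0.0)   # absent -> 0%


def test_unknown_species_prefix_is_an_accounting_error():
    clusters = cluster_graph(build_graph([], ["XXXX_1"]))
    with pytest.raises(AccountingError):
        genome_proportions(clusters, {"SYLV": 10})


def test_plastid_screen_rule_and_boundary(rng):
    ref = random_seq(rng, 2000)
    plastid_reads = {f"AAAA_p{i}": ref[i * 40:i * 40 + 95] for i in range(10)}
    random_reads = {f"AAAA_r{i}": random_seq(rng, 95) for i in range(10)}
    # exactly half the sampled reads match -> removed at the 50% boundary
    mixed = dict(list(plastid_reads.items())[:5]
                 + list(random_reads.items())[:5])
    reads = {**plastid_reads, **random_reads, **mixed}

    from repeatphylo.cluster import RepeatCluster
    cl_p = RepeatCluster("CL1", sorted(plastid_reads))
    cl_r = RepeatCluster("CL2", sorted(random_reads))
    cl_m = RepeatCluster("CL3", sorted(mixed))
    kept, removed = plastid_screen([cl_p, cl_r, cl_m], reads, ref)
    assert [c.cluster_id for c in removed] == ["CL1", "CL3"]
    assert [c.cluster_id for c in kept] == ["CL2"]
    assert cl_m.plastid_flag  # >= 0.5 of sampled reads aligned


def test_top_n_matrix_shapes_and_conservation():
    from repeatphylo.cluster import RepeatCluster
    clusters = [
        RepeatCluster("CL1", [f"SYLV_{i}" for i in range(5)], {"SYLV": 5}),
        RepeatCluster("CL2", ["OBTU_0", "OBTU_1", "SYLV_9"],
                      {"OBTU": 2, "SYLV": 1}),
        RepeatCluster("CL3", ["OBTU_9"], {"OBTU": 1}),
    ]
    taxa = ["SYLV", "OBTU"]
    m = top_n_matrix(clusters, taxa, n=1000)
    assert m.data.shape == (2, 3)
    assert list(m.data.sum(axis=0)) == [5, 3, 1]      # column sums = sizes
    m1 = top_n_matrix(clusters, taxa, n=1)
    assert m1.cluster_ids == ["CL1"]
    floor = top_n_matrix(clusters, taxa, n=1000, min_frac=2 / 9)
    assert floor.cluster_ids == ["CL1", "CL2"]
    with pytest.raises(ValueError):
        top_n_matrix(clusters, taxa, n=0)


# ---------------------------------------------------------------------------
# fixture-level checks (shared session clustering)


def test_fixture_read_conservation(fixture_pooled, fixture_clusters):
    assert sum(c.size for c in fixture_clusters) == len(fixture_pooled)
    seen = [rid for c in fixture_clusters for rid in c.members]
    assert len(seen) == len(set(seen))


def test_fixture_cluster_ari_vs_truth(fixture_run, fixture_clusters):
    """Partition fidelity on the six-species fixture: ARI >= 0.9 against the
    simulation truth over repeat-family reads (background single-copy reads
    carry no recoverable pair structure at 0.01x coverage)."""
    from sklearn.metrics import adjusted_rand_score

    label = {rid: cl.cluster_id for cl in fixture_clusters
             for rid in cl.members}
    ids = [rid for rid, (_, fam) in fixture_run.truth.reads.items()
           if fam != BACKGROUND_ID]
    ari = adjusted_rand_score([fixture_run.truth.reads[r][1] for r in ids],
                              [label[r] for r in ids])
    assert ari >= 0.9


def test_fixture_component_partition_matches_oracle(fixture_run, rng):
    """On a 160-read subsample of the fixture pool, the engine's hit set and
    component partition equal the brute-force all-pairs oracle's."""
    pooled = fixture_run.pooled()
    idx = sorted(rng.choice(len(pooled), size=160, replace=False))
    sub = [pooled[i] for i in idx]
    engine_hits = find_hits(sub)
    engine_pairs = {(h.read_a, h.read_b) for h in engine_hits}
    oracle_pairs = oracle_hit_pairs(sub)
    assert engine_pairs == oracle_pairs
    ids = [rid for rid, _ in sub]
    g_e = build_graph(engine_hits, ids)
    g_o = nx.Graph()
    g_o.add_nodes_from(ids)
    g_o.add_edges_from(oracle_pairs)
    parts_e = {frozenset(c) for c in nx.connected_components(g_e)}
    parts_o = {frozenset(c) for c in nx.connected_components(g_o)}
    assert parts_e == parts_o


def test_fixture_satellite_proportions(fixture_run, fixture_clusters):
    """The burst satellite is percent-scale in the three amplified polyploids
    and <0.1% in the downsized one, matching the simulation truth."""
    sat_reads = {rid for rid, (_, fam) in fixture_run.truth.reads.items()
                 if fam == "satNNES"}
    best = max(fixture_clusters, key=lambda c: len(sat_reads & set(c.members)))
    for sp in ("REPA", "NESO", "STOC"):
        assert best.proportions[sp] > 1.0
    assert best.proportions["NUDI"] < 0.1


def test_species_prefix_extraction():
    assert species_of_read("SYLV_000123") == "SYLV"
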