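"""Continuous-character parsimony: Farris lengths, search, rooting, supports."""

import numpy as np
import pandas as pd
import pytest
from _oracles import brute_force_parsimony, brute_force_parsimony_grid
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatphylo.matrices import (AbundanceMatrix, CharacterMatrix,
                                  cube_root_transform)
from repeatphylo.phylo import (exhaustive_search, farris_length,
                               resample_support, root_on_outgroup,
                               tree_to_newick, write_tree)
from repeatphylo.trees import UnrootedTree, enumerate_topologies


def char_matrix(values: dict[str, list[float]]) -> CharacterMatrix:
    taxa = sorted(values)
    arr = np.array([values[t] for t in taxa], dtype=float)
    cols = [f"c{i}" for i in range(arr.shape[1])]
    return CharacterMatrix(pd.DataFrame(arr, index=taxa, columns=cols))


# ---------------------------------------------------------------------------
# transform


def test_cube_root_known_values():
    m = AbundanceMatrix(pd.DataFrame({"c": [0.0, 8.0, 274_625.0]},
                                     index=["A", "B", "C"]))
    cm = cube_root_transform(m)
    got = cm.data["c"].to_numpy()
    assert got[0] == 0.0
    assert got[1] == pytest.approx(2.0, abs=1e-9)
    # 65^3 = 274,625: the ceiling of the conventional 0-65 input range
    assert got[2] == pytest.approx(65.0, abs=1e-9)
    assert cm.transform_tag == "cube_root"


def test_cube_root_rejects_negative_counts():
    df = pd.DataFrame({"c": [1.0, -2.0]}, index=["A", "B"])
    with pytest.raises(ValueError):
        cube_root_transform(df)


def test_cube_root_is_order_preserving_per_character(rng):
    counts = rng.integers(0, 300_000, size=(6, 20)).astype(float)
    df = pd.DataFrame(counts, index=[f"T{i}" for i in range(6)])
    out = cube_root_transform(AbundanceMatrix(df)).data.to_numpy()
    for j in range(20):
        assert (np.argsort(counts[:, j], kind="stable")
                == np.argsort(out[:, j], kind="stable")).all()


# ---------------------------------------------------------------------------
# Farris lengths


def test_quartet_lengths_match_hand_values():
    m = char_matrix({"A": [0], "B": [1], "C": [10], "D": [11]})
    by_split = {}
    for t in enumerate_topologies("ABCD"):
        total, edges = farris_length(t, m)
        by_split[next(iter(t.splits()))] = total
        assert sum(edges.values()) == pytest.approx(total)
    assert by_split[frozenset({"C", "D"})] == pytest.approx(11.0)   # ((A,B),(C,D))
    assert by_split[frozenset({"B", "D"})] == pytest.approx(20.0)   # ((A,C),(B,D))
    assert by_split[frozenset({"B", "C"})] == pytest.approx(20.0)


def test_constant_character_contributes_zero_length():
    m = char_matrix({t: [7.5] for t in "ABCDE"})
    for t in enumerate_topologies("ABCDE"):
        assert farris_length(t, m)[0] == pytest.approx(0.0)


@pytest.mark.parametrize("n_taxa", [4, 5])
def test_farris_equals_brute_force_on_all_topologies(n_taxa, rng):
    """Exact interval-algorithm lengths vs exhaustive minimisation over
    internal states (observed tip values suffice for linear cost)."""
    taxa = [f"T{i}" for i in range(n_taxa)]
    topologies = list(enumerate_topologies(taxa))
    for _ in range(100):
        vals = {t: [float(v)] for t, v in
                zip(taxa, rng.integers(0, 50, n_taxa))}
        m = char_matrix(vals)
        flat = {t: v[0] for t, v in vals.items()}
        for tree in topologies:
            expect = brute_force_parsimony(tree, flat)
            got, edges = farris_length(tree, m)
            assert got == pytest.approx(expect, abs=1e-9)
            assert sum(edges.values()) == pytest.approx(got, abs=1e-6)


def test_farris_matches_grid_refined_oracle(rng):
    taxa = list("ABCDE")
    for tree in enumerate_topologies(taxa):
        vals = {t: float(v) for t, v in zip(taxa, rng.random(5) * 10)}
        m = char_matrix({t: [v] for t, v in vals.items()})
        assert farris_length(tree, m)[0] == pytest.approx(
            brute_force_parsimony_grid(tree, vals), abs=1e-6)


def test_length_invariances(rng):
    """Shift invariance, scale equivariance, taxon-relabelling invariance."""
    taxa = list("ABCDEF")
    X = rng.random((6, 30)) * 40
    m = char_matrix({t: list(X[i]) for i, t in enumerate(taxa)})
    tree = next(enumerate_topologies(taxa))
    base, _ = farris_length(tree, m)

    shifted = char_matrix({t: list(X[i] + 13.7) for i, t in enumerate(taxa)})
    assert farris_length(tree, shifted)[0] == pytest.approx(base)

    scaled = char_matrix({t: list(X[i] * 2.5) for i, t in enumerate(taxa)})
    assert farris_length(tree, scaled)[0] == pytest.approx(2.5 * base)

    # relabel taxa by a permutation: score of the relabelled tree on the
    # relabelled data is unchanged
    perm = {"A": "D", "B": "E", "C": "F", "D": "A", "E": "B", "F": "C"}
    relabelled_m = char_matrix({perm[t]: list(X[i]) for i, t in enumerate(taxa)})
    relab_tree = UnrootedTree.from_newick(
        _relabel_newick(tree.canonical_newick(), perm))
    assert farris_length(relab_tree, relabelled_m)[0] == pytest.approx(base)


def _relabel_newick(newick: str, mapping: dict[str, str]) -> str:
    import re
    return re.sub(r"[A-Z]+", lambda mo: mapping.get(mo.group(), mo.group()),
                  newick)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(vals=st.lists(st.floats(0, 65, allow_nan=False, allow_infinity=False),
                     min_size=4, max_size=4),
       shift=st.floats(-50, 50, allow_nan=False),
       scale=st.floats(0, 4, allow_nan=False))
def test_length_shift_scale_properties_hold_for_any_character(vals, shift,
                                                              scale):
    """For arbitrary quartet characters: adding a constant leaves the length
    unchanged and scaling by c >= 0 scales it by c, on every topology."""
    base = char_matrix({t: [v] for t, v in zip("ABCD", vals)})
    moved = char_matrix({t: [v * scale + shift]
                         for t, v in zip("ABCD", vals)})
    for tree in enumerate_topologies("ABCD"):
        b = farris_length(tree, base)[0]
        m = farris_length(tree, moved)[0]
        assert m == pytest.approx(scale * b, abs=1e-6)


def test_mp_set_invariant_to_character_order(rng):
    taxa = list("ABCDE")
    X = rng.random((5, 12)) * 20
    m1 = char_matrix({t: list(X[i]) for i, t in enumerate(taxa)})
    perm = rng.permutation(12)
    m2 = char_matrix({t: list(X[i][perm]) for i, t in enumerate(taxa)})
    mp1 = {t.tree.canonical_newick() for t in exhaustive_search(m1)}
    mp2 = {t.tree.canonical_newick() for t in exhaustive_search(m2)}
    assert mp1 == mp2


# ---------------------------------------------------------------------------
# search / rooting


def test_exhaustive_search_refuses_too_many_taxa():
    m = char_matrix({f"T{i}": [float(i)] for i in range(10)})
    with pytest.raises(ValueError, match="max_taxa"):
        exhaustive_search(m)


def test_exhaustive_search_preserves_ties():
    # two characters in perfect conflict: all 3 quartet topologies, lengths
    # 2 and 3 -> the two topologies compatible with one character tie at 3
    m = char_matrix({"A": [0, 0], "B": [1, 1], "C": [1, 0], "D": [0, 1]})
    res = exhaustive_search(m)
    lengths = {t.total_length for t in res}
    assert len(lengths) == 1
    assert len(res) >= 2


def test_root_on_outgroup_roundtrip_and_conservation():
    m = char_matrix({"A": [0.0], "B": [1.0], "C": [10.0], "D": [11.0]})
    best = exhaustive_search(m)[0]
    rooted = root_on_outgroup(best, "A")
    assert rooted.total_length == best.total_length
    assert rooted.edge_lengths == best.edge_lengths
    # rooted newick splits the outgroup pendant edge into two halves
    nwk = tree_to_newick(rooted)
    reparsed = UnrootedTree.from_newick(nwk)
    assert reparsed == best.tree
    with pytest.raises(KeyError):
        root_on_outgroup(best, "Z")


def test_write_tree_roundtrip(tmp_path):
    m = char_matrix({"A": [0.0, 2.0], "B": [1.0, 2.0],
                     "C": [10.0, 9.0], "D": [11.0, 9.0]})
    best = exhaustive_search(m)[0]
    resample_support(m, reference=best, n_reps=10, seed=3)
    rooted = root_on_outgroup(best, "A")
    path = tmp_path / "tree.nwk"
    write_tree(rooted, path)
    text = path.read_text()
    assert UnrootedTree.from_newick(text) == best.tree
    # integer percent support label appears on the internal node
    import re
    assert re.search(r"\)100:", text) or re.search(r"\)\d+:", text)


# ---------------------------------------------------------------------------
# resampling support


def test_single_replicate_supports_are_zero_or_hundred():
    m = char_matrix({"A": [0.0, 1.0], "B": [1.0, 0.5], "C": [10.0, 9.0],
                     "D": [11.0, 9.5]})
    sup = resample_support(m, n_reps=1, seed=0)
    assert set(sup.values()) <= {0.0, 100.0}


@pytest.mark.parametrize("scheme", ["symmetric", "bootstrap"])
def test_clean_clade_gets_full_support(scheme):
    # every character separates {C,D,E} from {A,B} by a huge gap
    m = char_matrix({"A": [0.0] * 8, "B": [1.0] * 8, "C": [50.0] * 8,
                     "D": [51.0] * 8, "E": [52.0] * 8})
    best = exhaustive_search(m)[0]
    sup = resample_support(m, reference=best, n_reps=300, scheme=scheme, seed=1)
    key = frozenset({"C", "D", "E"})
    assert key in sup
    assert sup[key] == pytest.approx(100.0)


def test_resample_support_rejects_bad_inputs():
    m = char_matrix({"A": [0.0], "B": [1.0], "C": [2.0], "D": [3.0]})
    with pytest.raises(ValueError):
        resample_support(m, n_reps=0)
    with pytest.raises(ValueError):
        resample_support(m, scheme="jackknife")
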