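"""Shared fixtures: one canonical synthetic run, clustered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from repeatphylo.cluster import cluster_reads, plastid_screen, top_n_matrix
from repeatphylo.simulate import simulate_repandae6

#: the canonical shipped fixture is the preset at its default seed
FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def fixture_run():
    return simulate_repandae6(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_pooled(fixture_run):
    return fixture_run.pooled()


@pytest.fixture(scope="session")
def fixture_clusters(fixture_pooled):
    return cluster_reads(fixture_pooled)


@pytest.fixture(scope="session")
def fixture_screened(fixture_run, fixture_pooled, fixture_clusters):
    kept, removed = plastid_screen(fixture_clusters, dict(fixture_pooled),
                                   fixture_run.plastid_reference)
    return kept, removed


@pytest.fixture(scope="session")
def fixture_matrix(fixture_run, fixture_screened):
    kept, _ = fixture_screened
    return top_n_matrix(kept, sorted(fixture_run.reads), n=1000,
                        min_frac=0.001)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
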