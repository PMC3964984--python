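"""Shared fixtures: small synthetic universes and random-structure builders."""

from __future__ import annotations

import numpy as np
import pytest

from phenoprio import FixtureConfig, generate, load_universe
from phenoprio.ontology import Ontology, Term


@pytest.fixture(scope="session")
def small_universe(tmp_path_factory):
    """A compact planted universe used across module tests (q = 0)."""
    outdir = tmp_path_factory.mktemp("universe")
    cfg = FixtureConfig(seed=11, n_diseases=30, genes_per_species=120)
    ledger = generate(cfg, outdir)
    uni = load_universe(outdir)
    assert uni.ledger.counts == ledger.counts
    return uni


def random_dag_terms(rng: np.random.Generator, n: int, prefix: str = "T") -> list[Term]:
    """A random rooted DAG: node i draws 1-2 parents among earlier nodes."""
    terms = [Term(f"{prefix}:0000000", name=f"{prefix.lower()} root")]
    for i in range(1, n):
        n_par = 1 if i == 1 else int(rng.integers(1, 3))
        parents = sorted({int(p) for p in rng.integers(0, i, size=n_par)})
        terms.append(
            Term(
                f"{prefix}:{i:07d}",
                name=f"{prefix.lower()} term {i}",
                parents=[f"{prefix}:{p:07d}" for p in parents],
            )
        )
    return terms


def reachability_closure(terms: list[Term]) -> dict[str, set[str]]:
    """Brute-force ancestor sets via boolean-matrix repeated squaring."""
    ids = [t.id for t in terms]
    idx = {tid: i for i, tid in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n), dtype=bool)
    for t in terms:
        for p in t.parents:
            adj[idx[t.id], idx[p]] = True
    reach = adj.copy()
    while True:
        step = reach | (reach @ adj)
        if (step == reach).all():
            break
        reach = step
    return {tid: {ids[j] for j in np.nonzero(reach[i])[0]} for i, tid in enumerate(ids)}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
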