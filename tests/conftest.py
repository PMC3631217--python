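"""Shared fixtures: small hand-built networks, random graph factories, and a
module-scoped default synthetic benchmark reused by the slower tests."""

import numpy as np
import pytest

import ppinet as pp


def make_net(edges, drugs=None, attrs=None):
    """Small-network factory.

    ``edges``: iterable of (a, b) or (a, b, severity, type_label).
    ``drugs``: optional explicit drug universe (ids); defaults to the edge
    endpoints.  ``attrs``: optional dict drug_id -> (atc_codes, substructures).
    """
    records = []
    for e in edges:
        if len(e) == 2:
            records.append((e[0], e[1], "unspecified", ""))
        else:
            records.append(tuple(e))
    ids = set(drugs or [])
    for r in records:
        ids |= {r[0], r[1]}
    attrs = attrs or {}
    universe = {
        d: pp.Drug(d, atc_codes=frozenset(attrs.get(d, ((), ()))[0]),
                   substructures=frozenset(attrs.get(d, ((), ()))[1]))
        for d in ids
    }
    return pp.build_network(records, universe)


def random_net(rng, n=None, p=0.4):
    """Random simple graph over n drugs with random severities/types."""
    n = n if n is not None else int(rng.integers(4, 13))
    ids = [f"d{k:02d}" for k in range(n)]
    sevs = ["minor", "moderate", "major", "contraindicated", "unspecified"]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((ids[i], ids[j],
                              sevs[int(rng.integers(len(sevs)))],
                              f"t{int(rng.integers(4))}"))
    return make_net(edges, drugs=ids)


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture(scope="session")
def default_benchmark():
    """One default-world synthetic benchmark shared across tests."""
    return pp.generate_benchmark(pp.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def benchmark_table(default_benchmark):
    train, later, tax, truth = default_benchmark
    split = pp.make_validation_split(train, later)
    table = pp.build_covariate_table(train, tax,
                                     set(train.edges) | split.candidate_pairs)
    return train, later, tax, split, table
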