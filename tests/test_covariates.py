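"""Pair covariates against independent brute-force oracles and invariants."""

import numpy as np
import pytest

import ppinet as pp
import bruteforce as bf
from conftest import make_net, random_net

TOY_CODES = ["A01BC01", "A01BC02", "A01BD01", "A02BC01", "B01BC01", "B02AA05"]


@pytest.fixture(scope="module")
def toy_tax():
    return pp.ATCTaxonomy(TOY_CODES)


def attributed_random_net(rng, n=None):
    """Random net whose drugs carry random codes and substructure sets."""
    n = n if n is not None else int(rng.integers(4, 13))
    ids = [f"d{k:02d}" for k in range(n)]
    feats = [f"f{k}" for k in range(8)]
    attrs = {}
    for d in ids:
        codes = set(rng.choice(TOY_CODES, size=int(rng.integers(1, 3)),
                               replace=False))
        subs = {f for f in feats if rng.random() < 0.4}
        attrs[d] = (codes, subs)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                edges.append((ids[i], ids[j], "major", "t"))
    return make_net(edges, drugs=ids, attrs=attrs)


class TestNeighborJaccard:
    def test_hand_case(self):
        # N(i)={a,b,c}, N(j)={b,c,d}: |{b,c}| / |{a,b,c,d}| = 0.5
        net = make_net([("i", "a"), ("i", "b"), ("i", "c"),
                        ("j", "b"), ("j", "c"), ("j", "d")])
        assert pp.neighbor_jaccard(net, "i", "j") == pytest.approx(0.5)

    def test_identical_neighborhoods(self):
        net = make_net([("i", "a"), ("i", "b"), ("j", "a"), ("j", "b")])
        assert pp.neighbor_jaccard(net, "i", "j") == 1.0

    def test_disjoint_neighborhoods(self):
        net = make_net([("i", "a"), ("j", "b")])
        assert pp.neighbor_jaccard(net, "i", "j") == 0.0

    def test_edge_between_endpoints_excluded(self):
        # the (i,j) edge itself must not contribute to similarity
        net = make_net([("i", "j"), ("i", "a"), ("j", "a")])
        assert pp.neighbor_jaccard(net, "i", "j") == 1.0

    def test_unknown_drug_named(self):
        net = make_net([("i", "a")])
        with pytest.raises(KeyError, match="nope"):
            pp.neighbor_jaccard(net, "i", "nope")


class TestJaccardMax2Mean:
    def test_isolated_pair(self):
        net = make_net([("a", "b")], drugs=["a", "b", "i", "j"])
        assert pp.jaccard_max2_mean(net, "i", "j") == 0.0

    def test_matches_bruteforce(self, rng):
        for _ in range(25):
            net = random_net(rng)
            ids = sorted(net.drugs)
            i, j = ids[0], ids[1]
            assert pp.jaccard_max2_mean(net, i, j) == pytest.approx(
                bf.jaccard_max2_mean(net, i, j), abs=1e-12)

    def test_bounded_by_max_pairwise_jaccard(self, rng):
        net = random_net(rng, n=9)
        ids = sorted(net.drugs)
        cap = max(bf.neighbor_jaccard(net, a, b)
                  for a in ids for b in ids if a != b)
        assert pp.jaccard_max2_mean(net, ids[0], ids[1]) <= cap + 1e-12


class TestTopology:
    def test_degree_product(self):
        net = make_net([("i", "a"), ("i", "b"), ("i", "c"),
                        ("j", "a"), ("j", "b"), ("j", "c"), ("j", "d")])
        deg_prod, _, _ = pp.topology_covariates(net, "i", "j")
        assert deg_prod == 12

    def test_path_graph_leaf_betweenness(self):
        net = make_net([("a", "b"), ("b", "c"), ("c", "d")])
        _, betw_prod, _ = pp.topology_covariates(net, "a", "d")
        assert betw_prod == 0.0

    def test_triangle_clustering(self):
        net = make_net([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        _, _, ccmax = pp.topology_covariates(net, "a", "b")
        assert ccmax == 1.0

    def test_betweenness_matches_path_enumeration(self, rng):
        for _ in range(5):
            net = random_net(rng, n=int(rng.integers(5, 9)))
            ids = sorted(net.drugs)
            i, j = ids[0], ids[-1]
            _, betw_prod, ccmax = pp.topology_covariates(net, i, j)
            assert betw_prod == pytest.approx(
                bf.betweenness(net, i) * bf.betweenness(net, j), abs=1e-9)
            assert ccmax == pytest.approx(
                max(bf.clustering(net, i), bf.clustering(net, j)), abs=1e-12)


class TestATCDistance:
    def test_identical_code(self, toy_tax):
        d = pp.Drug("x", {"A01BC01"})
        assert pp.atc_min_distance(toy_tax, d, d) == 0

    def test_sibling_leaves(self, toy_tax):
        d1 = pp.Drug("x", {"A01BC01"})
        d2 = pp.Drug("y", {"A01BC02"})
        assert pp.atc_min_distance(toy_tax, d1, d2) == 2

    def test_no_shared_prefix_is_max(self, toy_tax):
        d1 = pp.Drug("x", {"A01BC01"})
        d2 = pp.Drug("y", {"B02AA05"})
        assert pp.atc_min_distance(toy_tax, d1, d2) == toy_tax.max_distance

    def test_multicode_minimum_by_enumeration(self, toy_tax, rng):
        for _ in range(30):
            c1 = set(rng.choice(TOY_CODES, size=2, replace=False))
            c2 = set(rng.choice(TOY_CODES, size=2, replace=False))
            d1, d2 = pp.Drug("x", c1), pp.Drug("y", c2)
            assert pp.atc_min_distance(toy_tax, d1, d2) == bf.atc_min(toy_tax, d1, d2)

    def test_unresolvable_code_errors(self, toy_tax):
        with pytest.raises(ValueError, match="x"):
            pp.atc_min_distance(toy_tax, pp.Drug("x"), pp.Drug("y", {"A01BC01"}))

    def test_custom_level_prefixes(self):
        # three-level toy taxonomy via the generic prefix-length config
        tax = pp.ATCTaxonomy(["aaX", "aaY", "abZ", "baQ"], level_prefixes=(1, 2, 3))
        assert tax.distance("aaX", "aaY") == 2
        assert tax.distance("aaX", "abZ") == 4
        assert tax.distance("aaX", "baQ") == 6


class TestFirstOrderCovariates:
    def test_atc_min_prod_zero_annihilator(self, toy_tax):
        attrs = {"i": ({"A01BC01"}, ()), "j": ({"A01BC02"}, ()),
                 "u": ({"A01BC01"}, ()), "v": ({"A01BC02"}, ())}
        net = make_net([("j", "u"), ("i", "v")], drugs=["i", "j", "u", "v"],
                       attrs=attrs)
        assert pp.atc_min_prod(net, toy_tax, "i", "j") == 0.0

    def test_atc_min_prod_isolated_fallback(self, toy_tax):
        attrs = {"i": ({"A01BC01"}, ()), "j": ({"A01BC02"}, ())}
        net = make_net([], drugs=["i", "j"], attrs=attrs)
        dmax = float(toy_tax.max_distance)
        assert pp.atc_min_prod(net, toy_tax, "i", "j") == dmax * dmax

    def test_str_max_prod_attains_one(self):
        subs = {"f1", "f2"}
        attrs = {"i": ((), subs), "j": ((), subs),
                 "u": ((), subs), "v": ((), subs)}
        net = make_net([("j", "u"), ("i", "v")], drugs=["i", "j", "u", "v"],
                       attrs=attrs)
        assert pp.str_max_prod(net, "i", "j") == 1.0

    def test_str_max_prod_isolated_zero(self):
        net = make_net([("j", "u")], drugs=["i", "j", "u"],
                       attrs={"i": ((), {"f"}), "j": ((), {"f"}),
                              "u": ((), {"f"})})
        assert pp.str_max_prod(net, "i", "j") == 0.0

    def test_match_bruteforce_on_random_fixtures(self, toy_tax, rng):
        for _ in range(15):
            net = attributed_random_net(rng, n=8)
            ids = sorted(net.drugs)
            i, j = ids[0], ids[1]
            assert pp.atc_min_prod(net, toy_tax, i, j) == pytest.approx(
                bf.atc_min_prod(net, toy_tax, i, j), abs=1e-12)
            assert pp.str_max_prod(net, i, j) == pytest.approx(
                bf.str_max_prod(net, i, j), abs=1e-12)


class TestStructuralJaccard:
    def test_identical_sets(self):
        d = pp.Drug("x", substructures={"a", "b"})
        assert pp.structural_jaccard(d, d) == 1.0

    def test_partial_overlap(self):
        d1 = pp.Drug("x", substructures={"f1", "f2", "f3"})
        d2 = pp.Drug("y", substructures={"f2", "f3", "f4", "f5"})
        assert pp.structural_jaccard(d1, d2) == pytest.approx(0.4)

    def test_both_empty(self):
        assert pp.structural_jaccard(pp.Drug("x"), pp.Drug("y")) == 0.0


class TestCovariateTable:
    def test_empty_pairs(self, toy_tax, rng):
        net = attributed_random_net(rng, n=5)
        table = pp.build_covariate_table(net, toy_tax, [])
        assert len(table) == 0
        assert list(table.columns[:2]) == ["drug_a", "drug_b"]

    def test_rows_match_per_op_recomputation(self, toy_tax, rng):
        net = attributed_random_net(rng, n=9)
        pairs = set(net.edges) | pp.non_edges(net)
        table = pp.build_covariate_table(net, toy_tax, pairs)
        assert len(table) == net.n_pairs
        assert table["response"].sum() == net.n_edges
        sample = table.sample(6, random_state=3)
        for row in sample.itertuples():
            i, j = row.drug_a, row.drug_b
            deg_prod, betw_prod, ccmax = pp.topology_covariates(net, i, j)
            assert row.degree_prod == deg_prod
            assert row.betw_prod == pytest.approx(betw_prod, abs=1e-12)
            assert row.cccnw_max == pytest.approx(ccmax, abs=1e-12)
            assert row.jackard == pytest.approx(
                pp.neighbor_jaccard(net, i, j), abs=1e-12)
            assert row.jackard_max2_mean == pytest.approx(
                pp.jaccard_max2_mean(net, i, j), abs=1e-12)
            assert row.atc_min == pp.atc_min_distance(
                toy_tax, net.drugs[i], net.drugs[j])
            assert row.atc_min_prod == pytest.approx(
                pp.atc_min_prod(net, toy_tax, i, j), abs=1e-12)
            assert row.str_jackard == pytest.approx(
                pp.structural_jaccard(net.drugs[i], net.drugs[j]), abs=1e-12)
            assert row.str_max_prod == pytest.approx(
                pp.str_max_prod(net, i, j), abs=1e-12)

    def test_bounds_and_symmetry(self, toy_tax, rng):
        net = attributed_random_net(rng, n=10)
        pairs = set(net.edges) | pp.non_edges(net)
        table = pp.build_covariate_table(net, toy_tax, pairs)
        for col in ["jackard", "jackard_max2_mean", "str_jackard",
                    "str_max_prod", "cccnw_max"]:
            assert table[col].between(0, 1).all()
        for col in ["degree_prod", "betw_prod", "atc_min", "atc_min_prod"]:
            assert (table[col] >= 0).all()
        # symmetry: swapping the order a pair is requested in changes nothing
        ids = sorted(net.drugs)
        t2 = pp.build_covariate_table(net, toy_tax, [(ids[1], ids[0])])
        t1 = pp.build_covariate_table(net, toy_tax, [(ids[0], ids[1])])
        assert (t1.values == t2.values).all()


class TestLocalityInvariants:
    def test_remote_edge_removal_leaves_jaccard(self, rng):
        # removing an edge incident to neither the endpoints nor their
        # neighbors cannot change their neighborhood similarity
        for _ in range(10):
            net = random_net(rng, n=12, p=0.3)
            ids = sorted(net.drugs)
            i, j = ids[0], ids[1]
            near = {i, j} | net.neighbors(i) | net.neighbors(j)
            remote = [p for p in net.edges if not (set(p) & near)]
            if not remote:
                continue
            before = pp.neighbor_jaccard(net, i, j)
            records = [(a, b, str(e.severity), e.type_label)
                       for (a, b), e in net.edges.items() if (a, b) != remote[0]]
            smaller = pp.build_network(records, net.drugs)
            assert pp.neighbor_jaccard(smaller, i, j) == pytest.approx(before)

    def test_common_neighbor_monotonicity(self, rng):
        for _ in range(10):
            net = random_net(rng, n=10, p=0.3)
            ids = sorted(net.drugs)
            i, j = ids[0], ids[1]
            before = pp.neighbor_jaccard(net, i, j)
            if before >= 1.0:
                continue
            free = [d for d in ids if d not in (i, j)
                    and not (net.has_edge(i, d) and net.has_edge(j, d))]
            if not free:
                continue
            u = free[0]
            records = [(a, b, str(e.severity), e.type_label)
                       for (a, b), e in net.edges.items()]
            for x in (i, j):
                if not net.has_edge(x, u):
                    records.append((x, u, "unspecified", ""))
            bigger = pp.build_network(records, net.drugs)
            assert pp.neighbor_jaccard(bigger, i, j) >= before - 1e-12
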