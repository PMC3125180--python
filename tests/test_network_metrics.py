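import itertools
import math

import numpy as np
import pandas as pd
import pytest

from apmsnet.io_formats import RoleAnnotation
from apmsnet.network_metrics import (build_network, degree_summary,
                                     functional_agreement, permutation_test,
                                     profile_correlations, reciprocal_rate)


def conf_table(edges, baits=None):
    """Confidence-table stand-in from a directed edge list."""
    baits = baits if baits is not None else sorted({b for b, _ in edges})
    rows = [{"bait": b, "prey": p, "score": 0.5, "high_confidence": True,
             "dashed": False} for b, p in edges]
    for b in baits:
        if not any(r["bait"] == b for r in rows):
            rows.append({"bait": b, "prey": b, "score": 1.0,
                         "high_confidence": False, "dashed": False})
    return pd.DataFrame(rows)


class TestBuildNetwork:
    def test_counts(self):
        net = build_network(conf_table([("A", "x"), ("A", "y")]))
        assert net.graph.number_of_nodes() == 3
        assert net.n_edges() == 2

    def test_reciprocal_flags(self):
        net = build_network(conf_table([("A", "B"), ("B", "A"), ("A", "x")]))
        assert net.graph.edges["A", "B"]["reciprocal"]
        assert net.graph.edges["B", "A"]["reciprocal"]
        assert not net.graph.edges["A", "x"]["reciprocal"]

    def test_self_edges_excluded_but_bait_prominence_kept(self):
        table = pd.DataFrame([
            {"bait": "A", "prey": "A", "score": 1.0, "high_confidence": True,
             "dashed": False},
            {"bait": "A", "prey": "x", "score": 0.3, "high_confidence": True,
             "dashed": False},
        ])
        net = build_network(table)
        assert not net.graph.has_edge("A", "A")
        assert net.graph.nodes["A"]["bait_prominence"] == 1.0

    def test_counts_equal_independent_recount(self, study_dataset):
        from apmsnet.confidence_scoring import score_all
        _, _, table = score_all(study_dataset.matrix)
        net = build_network(table)
        hc = table[table["high_confidence"]]
        expected_edges = {(r.bait, r.prey) for r in hc.itertuples()
                          if r.bait != r.prey}
        assert set(net.graph.edges) == expected_edges


class TestReciprocalRate:
    def test_three_of_six(self):
        # three bait pairs confirmed in both directions, three one-way
        edges = [("A", "B"), ("B", "A"), ("C", "D"), ("D", "C"),
                 ("E", "F"), ("F", "E"), ("G", "H"), ("I", "J"), ("K", "L")]
        baits = sorted({n for e in edges for n in e})
        net = build_network(conf_table(edges, baits))
        assert reciprocal_rate(net) == (3, 6, 0.5)

    def test_no_bait_bait_edges(self):
        net = build_network(conf_table([("A", "x")], baits=["A", "B"]))
        observed, possible, rate = reciprocal_rate(net)
        assert (observed, possible) == (0, 0)
        assert math.isnan(rate)

    def test_matches_brute_force_pair_scan(self):
        rng = np.random.default_rng(5)
        baits = [f"B{i}" for i in range(6)]
        edges = [(a, b) for a in baits for b in baits
                 if a != b and rng.random() < 0.3]
        if not edges:
            edges = [(baits[0], baits[1])]
        net = build_network(conf_table(edges, baits))
        observed = possible = 0
        for a, b in itertools.combinations(baits, 2):
            ab, ba = (a, b) in edges, (b, a) in edges
            possible += ab or ba
            observed += ab and ba
        assert reciprocal_rate(net)[:2] == (observed, possible)


class TestFunctionalAgreement:
    def test_single_role(self):
        net = build_network(conf_table([("A", "x"), ("A", "y")]))
        roles = RoleAnnotation({"A": "r", "x": "r", "y": "r"})
        assert functional_agreement(net, roles) == 1.0

    def test_bipartite_roles(self):
        net = build_network(conf_table([("A", "x"), ("A", "y")]))
        roles = RoleAnnotation({"A": "r1", "x": "r2", "y": "r2"})
        assert functional_agreement(net, roles) == 0.0

    def test_hand_count_with_unannotated(self):
        edges = [("A", "x"), ("A", "y"), ("A", "z")]
        net = build_network(conf_table(edges))
        roles = RoleAnnotation({"A": "r", "x": "r"})  # y, z unannotated
        assert functional_agreement(net, roles) == pytest.approx(1 / 3)
        assert functional_agreement(net, roles, drop_unannotated=True) == 1.0


class TestPermutationTest:
    def test_all_same_role_p_is_one(self):
        net = build_network(conf_table([("A", "x")]))
        roles = RoleAnnotation({"A": "r", "x": "r"})
        res = permutation_test(net, roles, n_perm=200, rng=0)
        assert res.observed_agreement == 1.0
        assert res.p_value == 1.0

    def test_low_agreement_gives_large_p(self):
        net = build_network(conf_table([("A", "x"), ("B", "y")]))
        roles = RoleAnnotation({"A": "r1", "x": "r2", "B": "r3", "y": "r4"})
        res = permutation_test(net, roles, n_perm=200, rng=0)
        assert res.observed_agreement == 0.0
        assert res.p_value >= 0.0  # direction: permuted can only tie or beat 0
        assert res.permuted_mean >= res.observed_agreement

    def test_exact_enumeration_on_four_node_toy(self):
        # path A->B->C with labels (r1, r1, r2, r2): observed agreement 1/2,
        # and exactly 2/3 of the label permutations reach at least 1/2
        net = build_network(conf_table([("A", "B"), ("B", "C")],
                                       baits=["A", "B", "C", "D"]))
        roles = RoleAnnotation({"A": "r1", "B": "r1", "C": "r2", "D": "r2"})
        observed = functional_agreement(net, roles)
        assert observed == 0.5
        nodes = sorted(net.graph.nodes)
        exceed = total = 0
        for perm in itertools.permutations(["r1", "r1", "r2", "r2"]):
            assignment = dict(zip(nodes, perm))
            agreement = np.mean([assignment[u] == assignment[v]
                                 for u, v in net.graph.edges])
            total += 1
            exceed += agreement >= observed
        exact_p = exceed / total
        assert exact_p == pytest.approx(2 / 3)
        n_perm = 20_000
        res = permutation_test(net, roles, n_perm=n_perm, rng=2)
        se = math.sqrt(exact_p * (1 - exact_p) / n_perm)
        assert abs(res.p_value - exact_p) < 4 * se

    def test_invariant_to_node_relabeling(self):
        edges = [("A", "x"), ("A", "y"), ("B", "x")]
        roles = {"A": "r1", "B": "r1", "x": "r2", "y": "r1"}
        mapping = {"A": "n1", "B": "n2", "x": "n3", "y": "n4"}
        net1 = build_network(conf_table(edges))
        net2 = build_network(conf_table([(mapping[a], mapping[b])
                                         for a, b in edges]))
        res1 = permutation_test(net1, RoleAnnotation(roles), n_perm=2000, rng=9)
        res2 = permutation_test(
            net2, RoleAnnotation({mapping[k]: v for k, v in roles.items()}),
            n_perm=2000, rng=9)
        assert res1.observed_agreement == res2.observed_agreement
        assert abs(res1.p_value - res2.p_value) < 0.05


class TestProfileCorrelations:
    def test_diagonal_and_scale_invariance(self):
        profiles = {
            "b1": {"p": 1.0, "q": 2.0, "r": 3.0},
            "b2": {"p": 2.0, "q": 4.0, "r": 6.0},
        }
        corr = profile_correlations(profiles)
        assert corr.loc["b1", "b1"] == 1.0
        assert corr.loc["b1", "b2"] == pytest.approx(1.0)

    def test_textbook_pearson_zero_filled(self):
        profiles = {
            "b1": {"p": 1.0, "q": 2.0},
            "b2": {"q": 1.0, "r": 5.0},
        }
        corr = profile_correlations(profiles)
        x = np.array([1.0, 2.0, 0.0])
        y = np.array([0.0, 1.0, 5.0])
        assert corr.loc["b1", "b2"] == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_constant_vector_is_nan(self):
        corr = profile_correlations({
            "b1": {"p": 1.0, "q": 1.0, "r": 1.0},
            "b2": {"p": 1.0, "q": 2.0, "r": 0.5},
        })
        assert math.isnan(corr.loc["b1", "b2"])


class TestDegreeSummary:
    def test_small_network(self):
        net = build_network(conf_table([("A", "x"), ("A", "y")]))
        summary = degree_summary(net)
        assert summary == {"n_baits": 1, "n_prey": 2, "n_edges": 2,
                           "mean_prey_per_bait": 2.0, "mean_baits_per_prey": 1.0}

    def test_empty_network(self):
        net = build_network(conf_table([], baits=["A"]))
        summary = degree_summary(net)
        assert summary["n_edges"] == 0
        assert math.isnan(summary["mean_prey_per_bait"])

    def test_matches_recount(self, study_dataset):
        from apmsnet.confidence_scoring import score_all
        _, _, table = score_all(study_dataset.matrix)
        net = build_network(table)
        summary = degree_summary(net)
        edges = set(net.graph.edges)
        assert summary["n_edges"] == len(edges)
        assert summary["n_prey"] == len({p for _, p in edges})
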