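"""Partnership-network construction and edge filtering."""

import math
from itertools import combinations

import networkx as nx
import pytest

from coregnet import (NullEnsembleStats, RegulatoryNetwork, SynthNetworkSpec,
                      build_coregulation, co_regulated_targets,
                      cotarget_counts, make_bipartite_network,
                      null_cotarget_stats, partner_counts)
from conftest import exact_mean_shared


def brute_force_cotargets(net: RegulatoryNetwork):
    """Independent pairwise set-intersection implementation."""
    out = {}
    for r1, r2 in combinations(sorted(net.regulators), 2):
        shared = len(net.out_map[r1] & net.out_map[r2])
        if shared:
            out[(r1, r2)] = shared
    return out


def manual_stats(pairs: dict, mu: float, sd: float) -> NullEnsembleStats:
    return NullEnsembleStats({p: mu for p in pairs}, {p: sd for p in pairs},
                             ensemble_size=10, seed=0)


class TestCotargetCounts:
    def test_toy_example(self, toy_net):
        assert cotarget_counts(toy_net) == {("A", "B"): 1}

    def test_complete_bipartite(self, complete_bipartite):
        assert cotarget_counts(complete_bipartite) == {("R1", "R2"): 3}

    def test_matches_brute_force_on_random_networks(self):
        for seed in range(5):
            net = make_bipartite_network(
                SynthNetworkSpec(20, 50, "poisson", mean_out_degree=6,
                                 seed=seed))
            assert cotarget_counts(net) == brute_force_cotargets(net)


class TestBuildCoregulation:
    def test_cc_filter_empties_forced_network(self, complete_bipartite):
        stats = null_cotarget_stats(complete_bipartite, 50, seed=0)
        cc_net = build_coregulation(complete_bipartite, stats, "cc")
        assert cc_net.num_edges == 0
        none_net = build_coregulation(complete_bipartite, stats, "none")
        assert none_net.num_edges == 1
        (_, _, d), = none_net.edges()
        assert d["cc"] == pytest.approx(1.0)

    def test_structured_pair_survives_cc_filter(self):
        # (A,B) share all 3 targets; the exact fixed-margin expectation
        # is below 3, so CC > 1 and the edge is retained
        net = RegulatoryNetwork(
            [("A", "g1"), ("A", "g2"), ("A", "g3"),
             ("B", "g1"), ("B", "g2"), ("B", "g3"),
             ("C", "g4"), ("D", "g4")])
        exact = exact_mean_shared([3, 3, 1, 1], 4, [2, 2, 2, 2], 0, 1)
        assert exact < 3
        stats = null_cotarget_stats(net, 500, seed=3)
        assert stats.pair_mean[("A", "B")] == pytest.approx(exact, rel=0.15)
        coreg = build_coregulation(net, stats, "cc")
        assert coreg.graph.has_edge("A", "B")

    def test_z_and_cc_filters_agree_when_sigma_positive(self):
        for seed in range(3):
            net = make_bipartite_network(
                SynthNetworkSpec(15, 40, "poisson", mean_out_degree=6,
                                 seed=seed))
            stats = null_cotarget_stats(net, 100, seed=seed + 10)
            cc_edges = set(build_coregulation(net, stats, "cc", 1.0)
                           .graph.edges())
            z_edges = set(build_coregulation(net, stats, "z", 0.0)
                          .graph.edges())
            sigma_pos = {p for p, sd in stats.pair_sd.items() if sd > 0}
            assert {e for e in cc_edges if e in sigma_pos} == \
                   {e for e in z_edges if e in sigma_pos}

    def test_mu_zero_pair_gets_infinite_cc_and_is_kept(self, toy_net):
        stats = manual_stats(cotarget_counts(toy_net), mu=0.0, sd=0.0)
        coreg = build_coregulation(toy_net, stats, "cc")
        (_, _, d), = coreg.edges()
        assert math.isinf(d["cc"]) and d["z"] is None

    def test_missing_stats_error_names_pair(self, toy_net):
        empty = NullEnsembleStats({}, {}, 1, 0)
        with pytest.raises(KeyError, match="'A', 'B'"):
            build_coregulation(toy_net, empty, "cc")

    def test_negative_cc_threshold_rejected(self, toy_net):
        stats = manual_stats(cotarget_counts(toy_net), 1.0, 0.5)
        with pytest.raises(ValueError):
            build_coregulation(toy_net, stats, "cc", -1.0)

    def test_threshold_monotonicity(self):
        net = make_bipartite_network(
            SynthNetworkSpec(20, 40, "poisson", mean_out_degree=8, seed=1))
        stats = null_cotarget_stats(net, 100, seed=2)
        edges_by_thr = [
            set(build_coregulation(net, stats, "cc", thr).graph.edges())
            for thr in (0.5, 1.0, 1.5, 2.0)]
        for small, large in zip(edges_by_thr, edges_by_thr[1:]):
            assert large <= small

    def test_disjoint_regulons_give_empty_partnership(self):
        net = make_bipartite_network(
            SynthNetworkSpec(10, 200, "poisson", mean_out_degree=5,
                             allow_shared_targets=False, seed=4))
        stats = null_cotarget_stats(net, 20, seed=5)
        for filt in ("cc", "z", "none"):
            assert build_coregulation(net, stats, filt).num_edges == 0


class TestPartnerCounts:
    def test_empty_partnership_all_zero(self, toy_net):
        stats = manual_stats(cotarget_counts(toy_net), mu=5.0, sd=1.0)
        coreg = build_coregulation(toy_net, stats, "cc")  # 1/5 < 1: dropped
        assert partner_counts(coreg) == {"A": 0, "B": 0, "C": 0}

    def test_triangle_degrees(self):
        net = RegulatoryNetwork(
            [(r, t) for r in ("A", "B", "C") for t in ("g1", "g2")])
        stats = manual_stats(cotarget_counts(net), mu=1.0, sd=0.5)
        coreg = build_coregulation(net, stats, "none")
        assert partner_counts(coreg) == {"A": 2, "B": 2, "C": 2}

    def test_degree_bounded_by_other_regulators(self):
        net = make_bipartite_network(
            SynthNetworkSpec(12, 30, "poisson", mean_out_degree=8, seed=6))
        stats = null_cotarget_stats(net, 50, seed=7)
        coreg = build_coregulation(net, stats, "none")
        m = len(net.regulators)
        assert all(f <= m - 1 for f in partner_counts(coreg).values())


class TestCoRegulatedTargets:
    def test_single_regulon_clique(self):
        net = RegulatoryNetwork([("A", "g1"), ("A", "g2")])
        dual = co_regulated_targets(net)
        assert set(dual.edges()) == {("g1", "g2")}

    def test_disjoint_regulons_empty(self):
        net = RegulatoryNetwork([("A", "g1"), ("B", "g2")])
        assert co_regulated_targets(net).number_of_edges() == 0

    def test_duality_with_cotarget_counts_on_reversed_network(self):
        for seed in range(3):
            net = make_bipartite_network(
                SynthNetworkSpec(10, 25, "poisson", mean_out_degree=5,
                                 seed=seed))
            dual = co_regulated_targets(net)
            reversed_net = RegulatoryNetwork(
                [(t, r) for r, t in net.edges])
            expected = set(cotarget_counts(reversed_net))
            got = {tuple(sorted(e)) for e in dual.edges()}
            assert got == expected
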