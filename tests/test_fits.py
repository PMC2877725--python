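"""Degree distributions, power-law diagnostics, scaling-law fits,
operon recalibration and down-sampling."""

import numpy as np
import pytest

from coregnet import (FitError, OperonMap, PartnerTargetSeries,
                      RegulatoryNetwork, SynthNetworkSpec, collapse_operons,
                      compare_fits, degree_distribution, downsample,
                      fit_exp_saturation, fit_linear, fit_powerlaw,
                      make_bipartite_network, make_saturation_scatter,
                      null_cotarget_stats, build_coregulation,
                      partner_counts, partners_vs_targets)


def series(k, f):
    k = np.asarray(k, dtype=float)
    return PartnerTargetSeries(tuple(f"r{i}" for i in range(len(k))), k, f)


def triangle_coreg():
    net = RegulatoryNetwork(
        [(r, t) for r in ("A", "B", "C") for t in ("g1", "g2")])
    stats = null_cotarget_stats(net, 20, seed=0)
    return net, build_coregulation(net, stats, "none")


class TestDegreeDistribution:
    def test_triangle_all_degree_two(self):
        _, coreg = triangle_coreg()
        assert degree_distribution(coreg) == {2: 1.0}

    def test_normalization(self):
        net = make_bipartite_network(
            SynthNetworkSpec(20, 40, "poisson", mean_out_degree=6, seed=1))
        coreg = build_coregulation(
            net, null_cotarget_stats(net, 30, seed=2), "none")
        dist = degree_distribution(coreg)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_matches_histogram_oracle(self):
        net = make_bipartite_network(
            SynthNetworkSpec(25, 50, "poisson", mean_out_degree=5, seed=3))
        coreg = build_coregulation(
            net, null_cotarget_stats(net, 30, seed=4), "cc")
        dist = degree_distribution(coreg, include_zero=True)
        degs = list(partner_counts(coreg).values())
        for k, p in dist.items():
            assert p == pytest.approx(degs.count(k) / len(degs))

    def test_empty_without_zero_errors(self, toy_net):
        from coregnet import NullEnsembleStats, cotarget_counts
        pairs = cotarget_counts(toy_net)
        stats = NullEnsembleStats({p: 9.0 for p in pairs},
                                  {p: 1.0 for p in pairs}, 5, 0)
        coreg = build_coregulation(toy_net, stats, "cc")
        with pytest.raises(ValueError):
            degree_distribution(coreg, include_zero=False)


class TestFitPowerlaw:
    def test_exact_powerlaw_recovered(self):
        ks = np.arange(1, 21)
        p = ks ** -2.0
        dist = dict(zip(ks.tolist(), (p / p.sum()).tolist()))
        fit = fit_powerlaw(dist)
        assert fit.params["gamma"] == pytest.approx(2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_uniform_distribution_degenerate(self):
        dist = {k: 1 / 20 for k in range(1, 21)}
        fit = fit_powerlaw(dist)
        assert fit.params["gamma"] == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-9)

    def test_noisy_powerlaw_gamma_within_10_percent(self):
        rng = np.random.default_rng(0)
        gammas = []
        for _ in range(50):
            ks = np.arange(1, 41)
            p = ks ** -1.8 * np.exp(rng.normal(0, 0.1, size=len(ks)))
            dist = dict(zip(ks.tolist(), (p / p.sum()).tolist()))
            gammas.append(fit_powerlaw(dist).params["gamma"])
        assert abs(np.mean(gammas) / 1.8 - 1.0) < 0.10

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_powerlaw({1: 0.5, 2: 0.5})


class TestPartnersVsTargets:
    def test_single_shared_target(self):
        net = RegulatoryNetwork([("A", "g1"), ("B", "g1")])
        coreg = build_coregulation(
            net, null_cotarget_stats(net, 10, seed=0), "none")
        s = partners_vs_targets(net, coreg)
        assert dict(zip(s.regulators, zip(s.k, s.f))) == \
            {"A": (1.0, 1.0), "B": (1.0, 1.0)}

    def test_provenance_mismatch_rejected(self, toy_net):
        other = RegulatoryNetwork([("X", "g1"), ("Y", "g1")])
        coreg = build_coregulation(
            other, null_cotarget_stats(other, 10, seed=0), "none")
        with pytest.raises(ValueError, match="provenance"):
            partners_vs_targets(toy_net, coreg)

    def test_matches_independent_recomputation(self):
        net = make_bipartite_network(
            SynthNetworkSpec(15, 30, "poisson", mean_out_degree=5, seed=5))
        coreg = build_coregulation(
            net, null_cotarget_stats(net, 30, seed=6), "none")
        s = partners_vs_targets(net, coreg)
        for reg, k, f in zip(s.regulators, s.k, s.f):
            assert k == len(net.out_map[reg])
            assert f == coreg.graph.degree(reg)


class TestFitLinear:
    def test_exact_line(self):
        k = np.arange(1, 11)
        fit = fit_linear(series(k, 2 * k + 1))
        assert fit.params["slope"] == pytest.approx(2.0, abs=1e-9)
        assert fit.params["intercept"] == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_response(self):
        fit = fit_linear(series([1, 2, 3, 4], [5, 5, 5, 5]))
        assert fit.params["slope"] == 0.0
        assert fit.r_squared == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        k = rng.uniform(1, 50, size=40)
        f = np.abs(3 * k + rng.normal(0, 5, size=40))
        fit = fit_linear(series(k, f))
        # closed-form OLS via normal equations
        X = np.column_stack([k, np.ones_like(k)])
        beta = np.linalg.solve(X.T @ X, X.T @ f)
        assert fit.params["slope"] == pytest.approx(beta[0], abs=1e-9)
        assert fit.params["intercept"] == pytest.approx(beta[1], abs=1e-9)

    def test_degenerate_k_variance_rejected(self):
        with pytest.raises(FitError):
            fit_linear(series([2, 2, 2], [1, 2, 3]))


class TestFitExpSaturation:
    def test_noiseless_recovery_to_1e6(self):
        s = make_saturation_scatter(50, 0.1, np.arange(1, 101), 0.0, 0)
        fit = fit_exp_saturation(s)
        assert fit.params["a"] == pytest.approx(50.0, rel=1e-6)
        assert fit.params["b"] == pytest.approx(0.1, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_half_regulator_plateau_recovery(self):
        # plateau at half of a 157-regulator pool, slow approach
        s = make_saturation_scatter(78.5, 0.05, np.arange(1, 201), 0.0, 0)
        fit = fit_exp_saturation(s)
        assert fit.params["a"] == pytest.approx(78.5, rel=1e-6)
        assert fit.params["b"] == pytest.approx(0.05, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_response_rejected(self):
        with pytest.raises(FitError):
            fit_exp_saturation(series([1, 2, 3], [0, 0, 0]))

    def test_near_linear_data_converges_on_plateau_bound(self):
        # b*k << 1: a and b unidentifiable separately; fit must still
        # converge and reproduce the line's quality
        s = series(np.arange(1, 6), 0.001 * np.arange(1, 6) * 50)
        fit = fit_exp_saturation(s)
        assert fit.r_squared > 0.999


class TestCompareFits:
    def test_plateau_data_prefers_saturation(self):
        s = make_saturation_scatter(40, 0.08, np.linspace(1, 120, 150),
                                    1.5, 2)
        cmp_ = compare_fits(s)
        assert cmp_.preferred == "exp_saturation"

    def test_linear_regime_near_tie_reported(self):
        s = make_saturation_scatter(50, 0.001, np.linspace(1, 5, 60),
                                    0.0, 0)
        cmp_ = compare_fits(s)
        assert cmp_.linear.r_squared > 0.999
        assert cmp_.exp_saturation.r_squared > 0.999
        assert abs(cmp_.delta_r_squared) < 1e-3

    def test_constant_zero_errors(self):
        with pytest.raises(FitError):
            compare_fits(series([1, 2, 3, 4], [0, 0, 0, 0]))


class TestCollapseOperons:
    def test_merges_parallel_edges(self):
        net = RegulatoryNetwork([("A", "g1"), ("A", "g2"), ("A", "g3")])
        omap = OperonMap({"g1": "op1", "g2": "op1", "g3": "op2"})
        collapsed = collapse_operons(net, omap)
        assert collapsed.out_map["A"] == {"op1", "op2"}

    def test_identity_map_is_noop(self, toy_net):
        assert collapse_operons(toy_net, OperonMap({})) == toy_net

    def test_never_increases_out_degree(self):
        rng = np.random.default_rng(3)
        net = make_bipartite_network(
            SynthNetworkSpec(10, 50, "poisson", mean_out_degree=8, seed=7))
        targets = sorted(net.targets)
        omap = OperonMap({t: f"op{rng.integers(0, 12)}" for t in targets})
        collapsed = collapse_operons(net, omap)
        for r in net.regulators:
            expected = len({omap.operon_of(t) for t in net.out_map[r]})
            assert collapsed.out_degree(r) == expected
            assert collapsed.out_degree(r) <= net.out_degree(r)


class TestDownsample:
    def test_fraction_zero_returns_input(self, toy_net):
        for sub in downsample(toy_net, 0.0, "edges", trials=3, seed=0):
            assert sub.edges == toy_net.edges

    def test_edge_count_contract(self):
        net = make_bipartite_network(
            SynthNetworkSpec(20, 60, "fixed", mean_out_degree=5, seed=8))
        assert len(net.edges) == 100
        for sub in downsample(net, 0.2, "edges", trials=3, seed=1):
            assert len(sub.edges) == 80

    def test_node_mode_removes_incident_edges(self):
        net = make_bipartite_network(
            SynthNetworkSpec(20, 60, "poisson", mean_out_degree=5, seed=9))
        n_remove = int(round(0.2 * len(net.nodes)))
        for sub in downsample(net, 0.2, "nodes", trials=2, seed=2):
            assert len(sub.nodes) == len(net.nodes) - n_remove
            assert all(r in sub.nodes and t in sub.nodes
                       for r, t in sub.edges)

    def test_trials_remove_different_subsets(self):
        net = make_bipartite_network(
            SynthNetworkSpec(30, 200, "poisson", mean_out_degree=10, seed=10))
        subs = downsample(net, 0.4, "edges", trials=3, seed=3)
        assert len({s.edges for s in subs}) == 3

    def test_invalid_fraction_rejected(self, toy_net):
        with pytest.raises(ValueError):
            downsample(toy_net, 1.0, "edges")
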