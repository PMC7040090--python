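"""Evaluation protocol: precision-coverage, LOO AUROC, connectivity,
randomization, independence guard."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import binom, rankdata

import cofnet as cf
from cofnet.evaluation import guilt_by_association_scores


class TestPrecisionCoverage:
    def test_all_truth_edges_give_unit_precision(self):
        net = cf.WeightedNetwork({("a", "b"): 2.0, ("c", "d"): 1.0})
        curve = cf.precision_coverage_curve(net, set(net.edges), genome_size=10)
        assert all(prec == 1.0 for _cov, prec in curve)

    def test_manual_prefix_counts(self):
        # truth edges at ranks 1, 2, 4 of 5; all genes annotated
        edges = {("a", "b"): 5.0, ("c", "d"): 4.0, ("e", "f"): 3.0,
                 ("g", "h"): 2.0, ("i", "j"): 1.0}
        truth = {("a", "b"), ("c", "d"), ("g", "h")}
        annotated = {g for p in edges for g in p}
        curve = cf.precision_coverage_curve(
            cf.WeightedNetwork(edges), truth, genome_size=20, annotated_genes=annotated
        )
        precisions = [p for _c, p in curve]
        assert precisions == pytest.approx([1.0, 1.0, 2 / 3, 3 / 4, 3 / 5])

    def test_coverage_non_decreasing(self, small_build, small_world):
        curve = cf.precision_coverage_curve(
            small_build.network, small_world.truth_pairs,
            genome_size=len(small_world.genes),
        )
        cov = [c for c, _p in curve]
        assert all(b >= a for a, b in zip(cov, cov[1:]))
        assert cov[-1] <= 1.0

    def test_unannotated_edges_skip_precision_denominator(self):
        edges = {("a", "b"): 5.0, ("x", "y"): 4.0, ("c", "d"): 3.0}
        truth = {("a", "b"), ("c", "d")}
        curve = cf.precision_coverage_curve(
            cf.WeightedNetwork(edges), truth, genome_size=10,
            annotated_genes={"a", "b", "c", "d"},
        )
        # (x,y) adds coverage but not to the precision denominator
        assert [p for _c, p in curve] == pytest.approx([1.0, 1.0, 1.0])

    def test_empty_truth_is_error(self):
        with pytest.raises(ValueError):
            cf.precision_coverage_curve(cf.WeightedNetwork({}), set(), 10)


class TestLooAuroc:
    def test_disconnected_clique_is_perfect(self):
        edges = {}
        clique = [f"p{i}" for i in range(4)]
        for a, b in itertools.combinations(clique, 2):
            edges[cf.canonical_pair(a, b)] = 1.0
        edges[("n1", "n2")] = 5.0
        res = cf.loo_auroc(cf.WeightedNetwork(edges), clique)
        assert res.auroc_full == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in res.auroc_at.values())

    def test_tied_scores_give_three_quarters(self):
        # scores: p1=p2=n1=3 (ties), n2=0 -> AUROC = (2 + 2*0.5)/4 = 0.75
        net = cf.WeightedNetwork({("p1", "p2"): 3.0, ("n1", "p1"): 3.0, ("n2", "p2"): 0.0})
        res = cf.loo_auroc(net, {"p1", "p2"})
        assert res.auroc_full == pytest.approx(0.75)

    def test_matches_mann_whitney_oracle_on_random_fixtures(self):
        """Trapezoidal AUROC equals tie-corrected Mann-Whitney pair counting."""
        rng = np.random.default_rng(3)
        for trial in range(5):
            genes = [f"g{i:02d}" for i in range(30)]
            edges = {}
            for a, b in itertools.combinations(genes, 2):
                if rng.random() < 0.15:
                    edges[(a, b)] = float(rng.gamma(2, 1))
            net = cf.WeightedNetwork(edges)
            positives = set(rng.choice(sorted(net.genes()), size=6, replace=False))
            res = cf.loo_auroc(net, positives)
            _genes, scores, labels = guilt_by_association_scores(net, positives)
            # brute-force U statistic with half credit for ties
            pos = scores[labels]
            neg = scores[~labels]
            u = sum(
                1.0 if p > n else (0.5 if p == n else 0.0)
                for p in pos for n in neg
            )
            assert res.auroc_full == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(9)
        aurocs = []
        for seed in range(10):
            genes = [f"g{i:03d}" for i in range(120)]
            edges = {}
            for a, b in itertools.combinations(genes, 2):
                if rng.random() < 0.05:
                    edges[(a, b)] = float(rng.random())
            net = cf.WeightedNetwork(edges)
            positives = set(rng.choice(sorted(net.genes()), 20, replace=False))
            aurocs.append(cf.loo_auroc(net, positives).auroc_full)
        assert abs(np.mean(aurocs) - 0.5) < 3 * np.std(aurocs) / math.sqrt(len(aurocs)) + 0.05

    def test_partial_auroc_normalized_to_unit_scale(self, small_build, small_world):
        module = set(small_world.modules[small_world.heldout_modules[0]])
        res = cf.loo_auroc(small_build.network, module, fpr_cutoffs=(0.01, 0.1, 1.0))
        for v in res.auroc_at.values():
            assert 0.0 <= v <= 1.0
        assert res.auroc_at[1.0] == pytest.approx(res.auroc_full)

    def test_fewer_than_two_positives_is_error(self):
        net = cf.WeightedNetwork({("a", "b"): 1.0})
        with pytest.raises(ValueError):
            cf.loo_auroc(net, {"a"})


class TestBatchAuroc:
    def test_min_set_boundary(self, small_build, small_world):
        res = cf.batch_auroc(small_build.network, small_world.annotations, min_set=10)
        assert len(res.per_term) == len(small_world.annotations.terms)
        with pytest.raises(ValueError):
            cf.batch_auroc(small_build.network, small_world.annotations, min_set=11)

    def test_identical_networks_compare_to_p_one(self, small_build, small_world):
        res = cf.batch_auroc(small_build.network, small_world.annotations)
        p, n = cf.paired_auroc_test(res.auroc_vector(), res.auroc_vector())
        assert p == 1.0 and n == len(res.per_term)

    def test_degraded_network_scores_lower(self, small_build, small_world):
        res = cf.batch_auroc(small_build.network, small_world.annotations)
        noisy = cf.randomize_network(small_build.network, fraction=0.5, seed=2)
        res2 = cf.batch_auroc(noisy, small_world.annotations)
        assert res2.summary()["median"] <= res.summary()["median"]

    def test_summary_reports_quartiles(self, small_build, small_world):
        s = cf.batch_auroc(small_build.network, small_world.annotations).summary()
        assert s["p10"] <= s["q1"] <= s["median"] <= s["q3"] <= s["p90"]


class TestConnectivity:
    def test_clique_observed_count(self):
        genes = [f"g{i}" for i in range(8)]
        edges = {cf.canonical_pair(a, b): 1.0
                 for a, b in itertools.combinations(genes[:5], 2)}
        edges[cf.canonical_pair(genes[5], genes[6])] = 1.0
        net = cf.WeightedNetwork(edges)
        res = cf.within_group_connectivity(net, genes[:5], n_random=50, seed=0)
        assert res.observed_edges == 10  # C(5,2)

    def test_binomial_tail_oracle(self):
        """p_binomial equals the explicit binomial tail sum at the network density."""
        rng = np.random.default_rng(1)
        genes = [f"g{i:03d}" for i in range(60)]
        edges = {}
        for a, b in itertools.combinations(genes, 2):
            if rng.random() < 0.1:
                edges[(a, b)] = 1.0
        net = cf.WeightedNetwork(edges)
        members = sorted(net.genes())[:6]
        res = cf.within_group_connectivity(net, members, n_random=50, seed=2)
        n_net = len(net.genes())
        density = len(net.edges) / (n_net * (n_net - 1) / 2)
        trials = 15  # C(6,2)
        expected = sum(
            binom.pmf(j, trials, density) for j in range(res.observed_edges, trials + 1)
        )
        assert res.p_binomial == pytest.approx(expected, rel=1e-9)

    def test_planted_module_is_significant(self, small_build, small_world):
        module = small_world.modules[small_world.train_modules[0]]
        res = cf.within_group_connectivity(
            small_build.network, module, n_random=200, seed=3
        )
        assert res.p_empirical <= 1 / 100
        assert res.p_binomial < 1e-6

    def test_too_small_set_is_error(self, small_build):
        with pytest.raises(ValueError):
            cf.within_group_connectivity(small_build.network, ["only"], seed=0)

    def test_null_sets_give_moderate_p(self, small_build):
        rng = np.random.default_rng(5)
        genes = sorted(small_build.network.genes())
        ps = [
            cf.within_group_connectivity(
                small_build.network, rng.choice(genes, 15, replace=False),
                n_random=100, seed=int(s),
            ).p_empirical
            for s in range(20)
        ]
        # uniform-ish: mean near 0.5, never systematically tiny
        assert 0.2 < float(np.mean(ps)) < 0.8


class TestRandomize:
    def test_zero_fraction_is_identity(self, small_build):
        net = small_build.network
        out = cf.randomize_network(net, fraction=0.0, seed=1)
        assert out.edges == net.edges

    def test_topology_invariants_conserved(self, small_world):
        net = cf.WeightedNetwork(dict(small_world.evidence_tables[0].scores))
        out = cf.randomize_network(net, fraction=0.2, seed=4)
        assert len(out) == len(net)
        assert out.degree_map() == net.degree_map()
        assert sorted(out.edges.values()) == sorted(net.edges.values())
        assert out.genes() == net.genes()

    def test_rewires_requested_fraction(self, small_world):
        net = cf.WeightedNetwork(dict(small_world.evidence_tables[0].scores))
        out = cf.randomize_network(net, fraction=0.2, seed=5)
        assert 0.19 <= cf.rewired_fraction(net, out) <= 0.21

    def test_invalid_fraction_rejected(self, small_build):
        with pytest.raises(ValueError):
            cf.randomize_network(small_build.network, fraction=1.5, seed=0)

    def test_infeasible_request_reports_achieved_fraction(self):
        # a triangle cannot be rewired at all
        net = cf.WeightedNetwork({("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0})
        with pytest.raises(RuntimeError, match="achieved"):
            cf.randomize_network(net, fraction=0.5, seed=0, max_tries_per_edge=50)


class TestIndependenceGuard:
    def test_overlap_fraction_computed(self, small_world):
        gs = small_world.gold_standard
        frac = cf.evaluation_overlap(gs.positives, gs)
        assert frac == 1.0
        assert cf.evaluation_overlap(small_world.module_pairs(
            small_world.heldout_modules[0]), gs) == 0.0

    def test_entangled_truth_refused_without_override(self, small_world):
        gs = small_world.gold_standard
        with pytest.raises(cf.EvaluationOverlapError):
            cf.assert_evaluation_independent(gs.positives, gs, max_fraction=0.05)

    def test_override_allows_and_reports(self, small_world):
        gs = small_world.gold_standard
        frac = cf.assert_evaluation_independent(
            gs.positives, gs, max_fraction=0.05, override=True
        )
        assert frac == 1.0

    def test_heldout_truth_passes(self, small_world):
        gs = small_world.gold_standard
        truth = set().union(
            *(small_world.module_pairs(m) for m in small_world.heldout_modules)
        )
        frac = cf.assert_evaluation_independent(truth, gs, max_fraction=0.05)
        assert frac == 0.0
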