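"""Interval construction, ranking, pooled ROC, Wilcoxon, and the CV harness."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from tsppi.core import GeneCatalog, PropagationResult, ValidationError, WeightedNetwork
from tsppi.evaluation import (
    NetworkVariant,
    attenuate_unexpressed,
    auc_from_scores,
    build_interval,
    compare_rankings,
    kfold_auc_spread,
    loocv,
    pooled_roc,
    rank_of,
    rw_sweep,
    summarize,
    wilcoxon_signed_rank,
)
from tsppi.networks import ReweightConfig, edge_reweight, node_removal


class TestBuildInterval:
    def _catalog_line(self, n):
        return GeneCatalog([f"g{i}" for i in range(n)], ["chr1"] * n, list(range(n)))

    def _full_net(self, n):
        net = WeightedNetwork([(i, i + 1, 0.5) for i in range(n - 1)])
        return net

    def test_balanced_interval_around_center(self):
        cat = self._catalog_line(1000)
        net = self._full_net(1000)
        interval = build_interval(500, cat, net, size=100)
        assert len(interval) == 100
        assert 500 not in interval
        assert set(interval) == set(range(450, 551)) - {500}

    def test_chromosome_start_takes_downstream(self):
        cat = self._catalog_line(300)
        net = self._full_net(300)
        interval = build_interval(0, cat, net, size=100)
        assert set(interval) == set(range(1, 101))

    def test_non_network_genes_skipped(self):
        cat = self._catalog_line(250)
        # gene 11 is not in the network: nearest network genes take its place
        edges = [(i, i + 1, 0.5) for i in range(249) if i != 11 and i + 1 != 11]
        net = WeightedNetwork(edges)
        net._nodes.update(set(range(250)) - {11})
        interval = build_interval(10, cat, net, size=20)
        assert 11 not in interval
        assert len(interval) == 20

    def test_short_chromosome_errors(self):
        cat = self._catalog_line(50)
        net = self._full_net(50)
        with pytest.raises(ValidationError):
            build_interval(25, cat, net, size=100)

    def test_gene_absent_from_network_errors(self):
        cat = self._catalog_line(300)
        net = WeightedNetwork([(0, 1, 0.5)])
        with pytest.raises(ValidationError):
            build_interval(250, cat, net, size=10)


class TestRankOf:
    def test_strict_top(self):
        scores = np.concatenate([[5.0], np.zeros(100)])
        assert rank_of(scores, 0) == 1

    def test_pessimistic_on_zero_ties(self):
        # 60 candidates strictly above, 40 tied at zero with the causal gene
        scores = np.concatenate([np.linspace(1, 2, 60), np.zeros(41)])
        assert rank_of(scores, 100) == 101

    def test_distinct_scores(self):
        rng = np.random.default_rng(2)
        scores = rng.permutation(101).astype(float)
        pos = 37
        assert rank_of(scores, pos) == 1 + int((scores > scores[pos]).sum())

    def test_antitone_in_score(self):
        rng = np.random.default_rng(3)
        others = rng.random(100)
        ranks = [
            rank_of(np.concatenate([others, [s]]), 100) for s in (0.1, 0.5, 0.9, 2.0)
        ]
        assert ranks == sorted(ranks, reverse=True)


class TestAuc:
    def test_separable(self):
        assert auc_from_scores([2.0, 3.0], [0.1, 0.2, 0.3]) == 1.0

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(4)
        s = rng.random(4000)
        assert auc_from_scores(s[:2000], s[2000:]) == pytest.approx(0.5, abs=0.03)

    def test_all_ties_half_with_warning(self):
        with pytest.warns(UserWarning):
            assert auc_from_scores([1.0, 1.0], [1.0, 1.0, 1.0]) == 0.5

    def test_small_pooled_set_matches_pair_counting(self):
        pos = np.array([0.9, 0.5, 0.5])
        neg = np.array([0.7, 0.5, 0.1])
        concordant = sum(
            1.0 if p > n else (0.5 if p == n else 0.0)
            for p in pos
            for n in neg
        )
        assert auc_from_scores(pos, neg) == pytest.approx(concordant / 9)


class TestWilcoxon:
    def test_identical_vectors(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0 and res.n_used == 0

    def test_uniform_improvement_exact_tail(self):
        # 20 pairs all improved by 1: the one-sided tail is 2^-20; the
        # two-sided convention doubles it
        a = list(range(20))
        b = [x + 1 for x in a]
        res = wilcoxon_signed_rank(a, b)
        assert res.p_value == pytest.approx(2 * 2.0**-20, rel=1e-9)

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=18)
        y = rng.normal(size=18)
        ours = wilcoxon_signed_rank(x, y)
        ref = sstats.wilcoxon(x, y, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_eight_pairs_match_enumeration(self):
        """Exact p equals brute-force enumeration of all 2^8 sign vectors."""
        rng = np.random.default_rng(7)
        x = rng.integers(0, 5, size=8).astype(float)
        y = rng.integers(0, 5, size=8).astype(float)
        d = x - y
        d = d[d != 0]
        r = sstats.rankdata(np.abs(d))
        w_obs = r[d > 0].sum()
        ws = np.array(
            [sum(ri for ri, s in zip(r, signs) if s)
             for signs in itertools.product([0, 1], repeat=d.size)]
        )
        expect = min(1.0, 2 * min((ws >= w_obs - 1e-9).mean(),
                                  (ws <= w_obs + 1e-9).mean()))
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(expect, rel=1e-12)

    def test_normal_approximation_large_n(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=60)
        y = x + rng.normal(0.4, 1.0, size=60)
        ours = wilcoxon_signed_rank(x, y)
        ref = sstats.wilcoxon(x, y, method="approx", correction=True)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestCompareRankings:
    def test_identical_ranks(self):
        res = compare_rankings([3, 1, 4], [3, 1, 4])
        assert (res.better, res.tie, res.worse) == (0, 3, 0)
        assert res.wilcoxon.p_value == 1.0

    def test_counts_partition_cases(self):
        res = compare_rankings([1, 5, 2, 2], [3, 4, 2, 1])
        assert (res.better, res.tie, res.worse) == (1, 1, 2)
        assert res.better + res.tie + res.worse == 4


class TestLoocv:
    def test_case_shape_and_determinism(self, decoy_bundle, decoy_cases):
        b = decoy_bundle
        assert len(decoy_cases) == 200
        for c in decoy_cases[:10]:
            assert c.gene in c.candidates and c.gene not in c.interval
            assert len(c.interval) == 100
            assert 1 <= c.ranks["generic"] <= 101
        # reproducibility: re-running one case gives identical scores
        variants = [NetworkVariant(label="generic", network=b.network)]
        again = loocv(
            b.associations, variants,
            sim=b.similarity, catalog=b.catalog, interval_network=b.network,
            assign=b.assignment, profiles=b.profiles,
            mas_threshold=40.0, expressed_only=True,
        )
        np.testing.assert_array_equal(
            again[0].scores["generic"], decoy_cases[0].scores["generic"]
        )

    def test_gene_with_two_diseases_fully_excluded(self, small_bundle):
        """Holding out one association removes the gene's other ones too."""
        import pandas as pd

        from tsppi.core import GeneDiseaseAssociations
        from tsppi.propagation import PropagationConfig, build_prior

        b = small_bundle
        g = b.causal_gene[b.families[0][0]]
        extra = GeneDiseaseAssociations(
            list(b.associations.pairs) + [(g, b.families[1][0])]
        )
        cfg = PropagationConfig()
        exclude = frozenset((g, d) for d in extra.diseases_of(g))
        Y = build_prior(
            b.families[0][0], b.similarity, extra, cfg, b.catalog.n_genes,
            exclude=exclude,
        )
        assert Y[g] == 0.0

    def test_generic_variant_ignores_tissue_data(self, small_bundle):
        """With only the generic network, the MAS matrix plays no role."""
        b = small_bundle
        variants = [NetworkVariant(label="generic", network=b.network)]
        with_assign = loocv(
            b.associations, variants,
            sim=b.similarity, catalog=b.catalog, interval_network=b.network,
            assign=b.assignment, mas_threshold=40.0,
        )
        without_assign = loocv(
            b.associations, variants,
            sim=b.similarity, catalog=b.catalog, interval_network=b.network,
        )
        ranks_with = {(c.gene, c.disease): c.ranks["generic"] for c in with_assign}
        ranks_without = {
            (c.gene, c.disease): c.ranks["generic"] for c in without_assign
        }
        for key, r in ranks_with.items():
            assert ranks_without[key] == r

    def test_nr_unexpressed_candidates_score_zero(self, small_bundle):
        b = small_bundle
        nr = {
            t: node_removal(b.network, b.profiles.expressed_in(t))
            for t in b.tissues
        }
        cases = loocv(
            b.associations,
            [NetworkVariant(label="nr", by_tissue=nr)],
            sim=b.similarity, catalog=b.catalog, interval_network=b.network,
            assign=b.assignment, profiles=b.profiles, mas_threshold=40.0,
        )
        checked = 0
        for c in cases:
            net = nr[c.tissue]
            for gene, score in zip(c.candidates, c.scores["nr"]):
                if gene not in net.nodes:
                    assert score == 0.0
                    checked += 1
        assert checked > 0


class TestSummaryAndVariants:
    def test_erw_rw1_scores_bitwise_equal_generic(self, small_bundle):
        b = small_bundle
        erw1 = {
            t: edge_reweight(b.network, b.profiles.expressed_in(t), ReweightConfig(1.0))
            for t in b.tissues
        }
        variants = [
            NetworkVariant(label="generic", network=b.network),
            NetworkVariant(label="erw1", by_tissue=erw1),
        ]
        cases = loocv(
            b.associations, variants,
            sim=b.similarity, catalog=b.catalog, interval_network=b.network,
            assign=b.assignment, mas_threshold=40.0, profiles=b.profiles,
        )
        assert cases
        for c in cases:
            np.testing.assert_array_equal(c.scores["erw1"], c.scores["generic"])

    def test_summarize_counts_cover_cases(self, decoy_cases):
        res = summarize(decoy_cases, baseline="generic")
        comp = res.comparisons["ts-erw"]
        assert comp.better + comp.tie + comp.worse == len(decoy_cases)
        assert 0.0 <= res.auc["generic"] <= 1.0


class TestKFold:
    def _run(self, bundle, seed, k=8, n_partitions=3):
        variant = NetworkVariant(label="generic", network=bundle.network)
        return kfold_auc_spread(
            bundle.associations, variant,
            sim=bundle.similarity, catalog=bundle.catalog,
            interval_network=bundle.network, assign=bundle.assignment,
            mas_threshold=40.0, k=k, n_partitions=n_partitions, seed=seed,
        )

    def test_same_seed_reproducible(self, small_bundle):
        a = self._run(small_bundle, seed=21)
        b = self._run(small_bundle, seed=21)
        assert a.std_auc == b.std_auc
        np.testing.assert_array_equal(a.aucs, b.aucs)

    def test_single_partition_zero_std(self, small_bundle):
        with pytest.warns(UserWarning):
            res = self._run(small_bundle, seed=5, n_partitions=1)
        assert res.std_auc == 0.0

    def test_k_larger_than_cases_rejected(self, small_bundle):
        with pytest.raises(ValidationError):
            self._run(small_bundle, seed=5, k=10**6)


class TestRwSweep:
    def test_endpoints_match_identities(self, small_bundle):
        """rw=1 reproduces the generic AUC; the sweep table covers the grid."""
        b = small_bundle
        expressed = {t: b.profiles.expressed_in(t) for t in b.tissues}
        sweep = rw_sweep(
            b.associations, b.network, expressed,
            sim=b.similarity, catalog=b.catalog, assign=b.assignment,
            profiles=b.profiles, mas_threshold=40.0,
            grid_step=0.5, max_refinements=2,
        )
        generic_cases = loocv(
            b.associations,
            [NetworkVariant(label="generic", network=b.network)],
            sim=b.similarity, catalog=b.catalog, interval_network=b.network,
            assign=b.assignment, mas_threshold=40.0, profiles=b.profiles,
        )
        generic_auc = pooled_roc(generic_cases, "generic").auc
        assert sweep.table[1.0] == pytest.approx(generic_auc, abs=1e-12)
        assert {0.0, 0.5, 1.0} <= set(sweep.table)
        assert sweep.best_rw in sweep.table


class TestAttenuation:
    def test_identity_when_all_expressed(self):
        res = PropagationResult("d", "generic", np.array([0.1, 0.2]))
        out = attenuate_unexpressed(res, {0, 1})
        np.testing.assert_array_equal(out.scores, res.scores)

    def test_all_zero_when_none_expressed(self):
        res = PropagationResult("d", "generic", np.array([0.1, 0.2]))
        assert attenuate_unexpressed(res, set()).scores.sum() == 0.0

    def test_mixed_zeroes_exact_complement(self):
        res = PropagationResult("d", "generic", np.array([0.1, 0.2, 0.3, 0.4]))
        out = attenuate_unexpressed(res, {1, 3})
        np.testing.assert_array_equal(out.scores, [0.0, 0.2, 0.0, 0.4])
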