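"""Enrichment statistics against brute-force oracles: BH step-up, exhaustive
hypergeometric draws, pairwise-comparison AUROC, bootstrap and consensus."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from conftest import gene, make_record
from dtrikit.aggregate import aggregate_dtris
from dtrikit.benchmark import (
    DEResult,
    Ranking,
    TargetBenchmark,
    auroc,
    bootstrap_auroc_ci,
    consensus_ranking,
    hit_list,
    hypergeom_overrep,
    subset_targets,
)
from dtrikit.records import ContextType, ExperimentType


def de_from_pvalues(pvalues, genes=None, label="screen", tf=None) -> DEResult:
    pvalues = np.asarray(pvalues, dtype=float)
    genes = (
        np.arange(1, len(pvalues) + 1, dtype=np.int64)
        if genes is None
        else np.asarray(genes, dtype=np.int64)
    )
    return DEResult.from_frame(
        pd.DataFrame(
            {"gene_entrez": genes, "log2fc": np.zeros_like(pvalues), "pvalue": pvalues}
        ),
        label=label,
        tf=tf,
    )


# ---------------------------------------------------------------------------
# oracles

def brute_force_bh_hits(pvalues, fdr):
    """Step-up procedure computed from the definition."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if pvalues[i] <= rank * fdr / n:
            k_star = rank
    return {order[i] for i in range(k_star)}


def brute_force_hypergeom_upper(k, N, K, n):
    """P(X >= k) by exhaustive enumeration of draws."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


def brute_force_auroc(scores, is_target):
    """Fraction of (target, non-target) pairs with the target ranked better
    (smaller score); ties count one half."""
    t = [s for s, m in zip(scores, is_target) if m]
    b = [s for s, m in zip(scores, is_target) if not m]
    wins = sum(1.0 if x < y else 0.5 if x == y else 0.0 for x in t for y in b)
    return wins / (len(t) * len(b))


class TestHitList:
    def test_all_p_one_gives_empty(self):
        assert hit_list(de_from_pvalues([1.0] * 5), 0.1) == frozenset()

    def test_hand_computed_bh_example(self):
        # p = (0.001, 0.01, 0.02, 0.8) -> adjusted (0.004, 0.02, 0.0267, 0.8)
        de = de_from_pvalues([0.001, 0.01, 0.02, 0.8])
        assert hit_list(de, 0.1) == frozenset({1, 2, 3})

    def test_fdr_one_keeps_everything(self):
        de = de_from_pvalues([0.2, 0.9, 0.5])
        assert hit_list(de, 1.0) == frozenset({1, 2, 3})

    def test_matches_step_up_oracle_up_to_length_20(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            n = int(rng.integers(1, 21))
            p = rng.uniform(0, 1, size=n).round(3)
            de = de_from_pvalues(p)
            for fdr in (0.05, 0.1, 0.25):
                expected = {i + 1 for i in brute_force_bh_hits(p, fdr)}
                assert hit_list(de, fdr) == frozenset(expected)


class TestHypergeom:
    def test_everything_overlaps(self):
        u = frozenset(range(1, 11))
        res = hypergeom_overrep(u, u, u)
        assert res.p_value == pytest.approx(1.0)
        assert res.k == res.K == res.n == res.N == 10

    def test_perfect_draw_probability(self):
        universe = frozenset(range(1, 11))
        targets = frozenset(range(1, 6))
        res = hypergeom_overrep(targets, targets, universe)
        assert res.p_value == pytest.approx(1 / math.comb(10, 5))

    def test_zero_overlap_is_upper_bound(self):
        universe = frozenset(range(1, 11))
        res = hypergeom_overrep(frozenset({1, 2}), frozenset({9, 10}), universe)
        assert res.k == 0 and res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_for_small_universes(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            N = int(rng.integers(2, 13))
            universe = frozenset(range(1, N + 1))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            targets = frozenset(rng.choice(N, size=K, replace=False) + 1)
            hits = frozenset(rng.choice(N, size=n, replace=False) + 1)
            res = hypergeom_overrep(hits, targets, universe)
            assert res.p_value == pytest.approx(
                brute_force_hypergeom_upper(res.k, N, K, n), abs=1e-12
            )

    def test_genes_outside_universe_dropped(self):
        universe = frozenset(range(1, 6))
        res = hypergeom_overrep(frozenset({1, 99}), frozenset({1, 2, 77}), universe)
        assert res.n == 1 and res.K == 2 and res.k == 1

    def test_empty_universe_error(self):
        with pytest.raises(ValueError):
            hypergeom_overrep(frozenset(), frozenset(), frozenset())


class TestAuroc:
    def test_targets_at_the_top(self):
        ranking = Ranking.from_de(de_from_pvalues(np.linspace(0.01, 1, 10)))
        res = auroc(ranking, {1, 2})
        assert res.statistic == pytest.approx(1.0)

    def test_targets_split_top_and_bottom(self):
        ranking = Ranking.from_de(de_from_pvalues(np.linspace(0.01, 1, 10)))
        res = auroc(ranking, {1, 10})
        assert res.statistic == pytest.approx(0.5)  # (8 + 0)/16

    def test_matches_pairwise_oracle_on_small_universes(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(5, 51))
            m = int(rng.integers(1, n))
            scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.8], size=n)  # many ties
            targets = set(rng.choice(n, size=m, replace=False) + 1)
            ranking = Ranking(
                genes=np.arange(1, n + 1, dtype=np.int64),
                scores=np.asarray(scores, float),
            )
            expected = brute_force_auroc(scores, [g in targets for g in range(1, n + 1)])
            assert auroc(ranking, targets).statistic == pytest.approx(expected)

    def test_null_auroc_centers_on_half(self):
        rng = np.random.default_rng(3)
        n, m = 2000, 50
        vals = []
        for _ in range(100):
            ranking = Ranking(
                genes=np.arange(1, n + 1, dtype=np.int64),
                scores=rng.uniform(size=n),
            )
            targets = set(rng.choice(n, size=m, replace=False) + 1)
            vals.append(auroc(ranking, targets).statistic)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)

    def test_pvalue_significant_for_clear_enrichment(self):
        p = np.concatenate([np.full(20, 1e-5), np.linspace(0.05, 1, 480)])
        ranking = Ranking.from_de(de_from_pvalues(p))
        res = auroc(ranking, set(range(1, 21)))
        assert res.p_value < 1e-6

    def test_no_targets_in_universe_error(self):
        ranking = Ranking.from_de(de_from_pvalues([0.1, 0.2]))
        with pytest.raises(ValueError, match="no targets"):
            auroc(ranking, {99})


class TestBootstrapCI:
    def test_targets_at_top_gives_degenerate_interval(self):
        ranking = Ranking.from_de(de_from_pvalues(np.linspace(0.01, 1, 20)))
        low, high = bootstrap_auroc_ci(ranking, {1, 2, 3}, n_boot=200, seed=0)
        assert low == pytest.approx(1.0) and high == pytest.approx(1.0)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(1)
        ranking = Ranking.from_de(de_from_pvalues(rng.uniform(size=100)))
        a = bootstrap_auroc_ci(ranking, set(range(1, 11)), n_boot=300, seed=7)
        b = bootstrap_auroc_ci(ranking, set(range(1, 11)), n_boot=300, seed=7)
        assert a == b

    def test_interval_covers_point_estimate_for_planted_signal(self):
        rng = np.random.default_rng(4)
        covered = 0
        for rep in range(50):
            p = rng.uniform(size=2000)
            targets = set(rng.choice(2000, size=30, replace=False) + 1)
            for t in targets:
                if rng.random() < 0.6:
                    p[t - 1] = rng.beta(0.1, 1.0)
            ranking = Ranking.from_de(de_from_pvalues(p))
            stat = auroc(ranking, targets).statistic
            low, high = bootstrap_auroc_ci(ranking, targets, n_boot=300, seed=rep)
            covered += low <= stat <= high
        assert covered >= 45  # central percentile interval covers the estimate

    def test_needs_two_targets(self):
        ranking = Ranking.from_de(de_from_pvalues([0.1, 0.5, 0.9]))
        with pytest.raises(ValueError):
            bootstrap_auroc_ci(ranking, {1}, n_boot=10, seed=0)


class TestConsensusRanking:
    def test_single_ranking_is_identity(self):
        de = de_from_pvalues([0.3, 0.1, 0.9, 0.5])
        cons = consensus_ranking([Ranking.from_de(de)])
        assert list(cons.genes) == [2, 1, 4, 3]

    def test_reversed_rankings_tie_everywhere(self):
        a = Ranking(genes=np.array([1, 2, 3, 4]), scores=np.array([1.0, 2, 3, 4]))
        b = Ranking(genes=np.array([1, 2, 3, 4]), scores=np.array([4.0, 3, 2, 1]))
        cons = consensus_ranking([a, b])
        assert np.allclose(cons.mean_ranks, 2.5)
        assert list(cons.genes) == [1, 2, 3, 4]  # ties broken by Entrez id

    def test_nonoverlapping_genes_dropped_and_ranks_recomputed(self):
        a = Ranking(genes=np.array([1, 2, 3]), scores=np.array([0.1, 0.2, 0.3]))
        b = Ranking(genes=np.array([2, 3, 9]), scores=np.array([0.9, 0.1, 0.5]))
        cons = consensus_ranking([a, b])
        assert set(cons.genes) == {2, 3}
        # within {2,3}: a ranks (1,2), b ranks (2,1) -> means (1.5, 1.5)
        assert np.allclose(cons.mean_ranks, 1.5)

    def test_consensus_beats_median_individual_on_shared_signal(self):
        rng = np.random.default_rng(9)
        n = 3000
        targets = set(rng.choice(n, size=40, replace=False) + 1)
        wins = 0
        for rep in range(20):
            screens = []
            for s in range(3):
                p = rng.uniform(size=n)
                for t in targets:
                    if rng.random() < 0.5:
                        p[t - 1] = rng.beta(0.15, 1.0)
                screens.append(Ranking.from_de(de_from_pvalues(p, label=f"s{s}")))
            individual = [auroc(r, targets).statistic for r in screens]
            cons = consensus_ranking(screens).to_ranking()
            wins += auroc(cons, targets).statistic >= np.median(individual)
        assert wins >= 15  # rank averaging denoises the shared signal

    def test_empty_intersection_error(self):
        a = Ranking(genes=np.array([1]), scores=np.array([0.1]))
        b = Ranking(genes=np.array([2]), scores=np.array([0.1]))
        with pytest.raises(ValueError):
            consensus_ranking([a, b])


class TestSubsetTargets:
    def _dtris(self, dag):
        records = [
            make_record("E1", tf=gene(1), target=gene(10),
                        context_type=ContextType.PRIMARY,
                        context_term="UBERON:0000955"),
            make_record("E2", tf=gene(1), target=gene(10),
                        experiment_type=ExperimentType.BINDING),
            make_record("E3", tf=gene(1), target=gene(11),
                        context_type=ContextType.PRIMARY,
                        context_term="UBERON:0000966"),
            make_record("E4", tf=gene(1), target=gene(12)),
        ]
        return aggregate_dtris(records, dag)

    def test_context_partition(self, dag):
        sets = {ts.category: ts.genes for ts in subset_targets(self._dtris(dag), 1)}
        assert sets == {"CNS": {10}, "eye": {11}, "other": {12}}

    def test_cns_and_eye_evidence_goes_to_cns_only(self, dag):
        records = [
            make_record("E1", tf=gene(1), target=gene(10),
                        context_type=ContextType.PRIMARY,
                        context_term="UBERON:0000955"),
            make_record("E2", tf=gene(1), target=gene(10),
                        context_type=ContextType.PRIMARY,
                        context_term="UBERON:0000966"),
        ]
        sets = {ts.category: ts.genes
                for ts in subset_targets(aggregate_dtris(records, dag), 1)}
        assert sets == {"CNS": {10}}

    def test_evidence_depth_partition(self, dag):
        sets = {ts.category: ts.genes
                for ts in subset_targets(self._dtris(dag), 1, "evidence_depth")}
        assert sets == {"multi_evidence": {10}, "single_evidence": {11, 12}}

    def test_all_single_type_means_no_multi_set(self, dag):
        records = [make_record("E1", tf=gene(1), target=gene(10))]
        sets = subset_targets(aggregate_dtris(records, dag), 1, "evidence_depth")
        assert [ts.category for ts in sets] == ["single_evidence"]

    def test_absent_tf_error(self, dag):
        with pytest.raises(ValueError):
            subset_targets(self._dtris(dag), 999)


class TestTargetBenchmark:
    def test_small_sets_are_skipped(self, dag):
        records = [
            make_record(f"E{i}", tf=gene(1), target=gene(10 + i)) for i in range(9)
        ]
        dtris = aggregate_dtris(records, dag)
        screen = de_from_pvalues(np.linspace(0.001, 1, 50), tf=1)
        res = TargetBenchmark(dtris, [screen], 1).fit(min_targets=10, n_boot=50, seed=0)
        assert res.entries["all"]["skipped"] is True
        assert res.entries["all"]["n_in_universe"] == 9

    def test_single_screen_report_structure(self, dag):
        records = [
            make_record(f"E{i}", tf=gene(1), target=gene(10 + i)) for i in range(15)
        ]
        dtris = aggregate_dtris(records, dag)
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        for t in range(10, 25):
            p[t - 1] = rng.beta(0.1, 1.0)
        screen = de_from_pvalues(p, label="forebrain_ko", tf=1)
        res = TargetBenchmark(dtris, [screen], 1).fit(min_targets=10, n_boot=100, seed=1)
        entry = res.entries["all"]
        assert not entry["skipped"]
        assert 0.5 < entry["auroc"] <= 1.0
        assert entry["ci"][0] <= entry["auroc"] <= entry["ci"][1]
        assert entry["hypergeom"]["forebrain_ko"]["N"] == 200
        table = res.summary()
        assert "all" in table.index
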