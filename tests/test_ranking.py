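import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sagedriver.decoder import ScoreMatrix
from sagedriver.ranking import (
    SampleRanking,
    build_sample_rankings,
    condorcet_rank,
    epv_scores,
    rank_weight,
)

from oracles import epv_bruteforce


def _random_rankings(rng, n_genes=8, n_samples=4):
    genes = [f"g{i}" for i in range(n_genes)]
    rankings = []
    for s in range(n_samples):
        m = int(rng.integers(0, n_genes + 1))
        chosen = list(rng.choice(genes, size=m, replace=False))
        rankings.append(
            SampleRanking(sample=f"s{s}", genes=chosen, scores=[0.0] * m)
        )
    return genes, rankings


class TestBuildSampleRankings:
    def _scores(self):
        genes = ["a", "b", "c", "d", "e"]
        vals = np.array(
            [
                [0.9, 0.1],
                [0.8, 0.2],
                [0.7, 0.3],
                [0.6, 0.4],
                [0.5, 0.5],
            ]
        )
        return ScoreMatrix(values=vals, genes=genes, samples=["s1", "s2"])

    def test_even_count_keeps_half(self):
        mut = np.array([[1, 0], [1, 0], [1, 0], [1, 0], [0, 0]])
        (r1, r2) = build_sample_rankings(self._scores(), mut)
        assert r1.genes == ["a", "b"]  # 4 mutated -> keep 2
        assert r2.genes == []

    def test_odd_count_uses_ceiling(self):
        mut = np.ones((5, 2), dtype=int)
        r1, _ = build_sample_rankings(self._scores(), mut)
        assert len(r1.genes) == 3  # ceil(0.5 * 5)

    def test_single_mutated_gene_still_contributes(self):
        mut = np.zeros((5, 2), dtype=int)
        mut[2, 0] = 1
        r1, _ = build_sample_rankings(self._scores(), mut)
        assert r1.genes == ["c"]

    def test_only_mutated_genes_eligible_and_sorted_by_score(self):
        mut = np.array([[0, 0], [1, 0], [0, 0], [1, 0], [1, 0]])
        r1, _ = build_sample_rankings(self._scores(), mut)
        assert r1.genes == ["b", "d"]

    def test_score_ties_break_by_symbol(self):
        vals = np.full((4, 1), 0.5)
        scores = ScoreMatrix(values=vals, genes=["d", "b", "c", "a"], samples=["s"])
        (r,) = build_sample_rankings(scores, np.ones((4, 1), dtype=int))
        assert r.genes == ["a", "b"]


class TestRankWeight:
    def test_rank_one_is_unity(self):
        assert rank_weight(1, 0.7) == 1.0

    def test_alpha_zero_is_unweighted(self):
        assert rank_weight(9, 0.0) == 1.0

    def test_decay_value(self):
        assert rank_weight(2, 0.5) == pytest.approx(math.exp(-0.5))

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            rank_weight(0, 0.5)


class TestEPV:
    def test_worked_three_gene_example(self):
        """One sample ranks [g1, g2] over universe {g1, g2, g3}, alpha 0.5."""
        rankings = [SampleRanking("s1", ["g1", "g2"], [0.9, 0.8])]
        res = epv_scores(rankings, alpha=0.5, universe={"g1", "g2", "g3"})
        w2 = math.exp(-0.5)
        assert res.score_of("g1") == pytest.approx(1.0)
        assert res.score_of("g2") == pytest.approx(w2 / (1 + w2))  # ~0.3775
        assert res.score_of("g3") == 0.0
        assert res.genes == ["g1", "g2", "g3"]

    def test_unlisted_gene_never_wins(self):
        rankings = [SampleRanking("s", ["a", "b"], [1, 1])]
        res = epv_scores(rankings, alpha=0.3, universe={"a", "b", "z"})
        row = res.table.set_index("gene").loc["z"]
        assert row["win"] == 0 and row["p"] == 0

    def test_duplicate_samples_double_tallies_keep_p(self):
        one = [SampleRanking("s1", ["a", "c", "b"], [3, 2, 1])]
        two = one + [SampleRanking("s2", ["a", "c", "b"], [3, 2, 1])]
        r1 = epv_scores(one, alpha=0.4)
        r2 = epv_scores(two, alpha=0.4)
        t1 = r1.table.set_index("gene")
        t2 = r2.table.set_index("gene")
        for g in "abc":
            assert t2.loc[g, "win"] == pytest.approx(2 * t1.loc[g, "win"])
            assert t2.loc[g, "loss"] == pytest.approx(2 * t1.loc[g, "loss"])
            assert t2.loc[g, "p"] == pytest.approx(t1.loc[g, "p"])

    def test_total_win_equals_total_loss(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            genes, rankings = _random_rankings(rng)
            if all(not r.genes for r in rankings):
                continue
            res = epv_scores(rankings, alpha=float(rng.random()), universe=genes)
            assert res.table["win"].sum() == pytest.approx(res.table["loss"].sum())

    def test_agrees_with_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            genes, rankings = _random_rankings(
                rng, n_genes=int(rng.integers(2, 12)), n_samples=int(rng.integers(1, 6))
            )
            if all(not r.genes for r in rankings):
                continue
            alpha = float(rng.random())
            res = epv_scores(rankings, alpha=alpha, universe=genes)
            win, loss, p = epv_bruteforce(rankings, alpha, genes)
            t = res.table.set_index("gene")
            for g in genes:
                assert t.loc[g, "win"] == pytest.approx(win[g], abs=1e-12)
                assert t.loc[g, "loss"] == pytest.approx(loss[g], abs=1e-12)
                assert t.loc[g, "p"] == pytest.approx(p[g], abs=1e-12)

    def test_consistent_front_runner_attains_one(self):
        rankings = [
            SampleRanking("s1", ["top", "x"], [2, 1]),
            SampleRanking("s2", ["top", "y"], [2, 1]),
        ]
        res = epv_scores(rankings, alpha=0.8, universe={"top", "x", "y"})
        assert res.score_of("top") == pytest.approx(1.0)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_promoting_a_gene_never_lowers_its_score(self, seed):
        rng = np.random.default_rng(seed)
        genes, rankings = _random_rankings(rng, n_genes=6, n_samples=3)
        target = next((r for r in rankings if len(r.genes) >= 2), None)
        if target is None:
            return
        g = target.genes[-1]
        before = epv_scores(rankings, alpha=0.5, universe=genes).score_of(g)
        k = len(target.genes)
        target.genes[k - 2], target.genes[k - 1] = (
            target.genes[k - 1],
            target.genes[k - 2],
        )
        after = epv_scores(rankings, alpha=0.5, universe=genes).score_of(g)
        assert after >= before - 1e-12

    def test_empty_rankings_rejected(self):
        with pytest.raises(ValueError):
            epv_scores([SampleRanking("s", [], [])], alpha=0.5)


class TestCondorcet:
    def test_single_voter_order(self):
        rankings = [SampleRanking("s", ["a", "b", "c"], [3, 2, 1])]
        assert condorcet_rank(rankings, universe={"a", "b", "c"}) == ["a", "b", "c"]

    def test_matches_epv_at_alpha_zero(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            genes, rankings = _random_rankings(
                rng, n_genes=int(rng.integers(2, 10)), n_samples=int(rng.integers(1, 5))
            )
            if all(not r.genes for r in rankings):
                continue
            assert condorcet_rank(rankings, universe=genes) == epv_scores(
                rankings, alpha=0.0, universe=genes
            ).genes

    def test_cyclic_preferences_break_ties_deterministically(self):
        cyc = [
            SampleRanking("s1", ["a", "b", "c"], [3, 2, 1]),
            SampleRanking("s2", ["b", "c", "a"], [3, 2, 1]),
            SampleRanking("s3", ["c", "a", "b"], [3, 2, 1]),
        ]
        order1 = condorcet_rank(cyc, universe={"a", "b", "c"})
        order2 = condorcet_rank(list(cyc), universe={"a", "b", "c"})
        assert order1 == order2 == sorted(order1)  # symmetric cycle -> symbol order
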