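"""Rank metric and evaluation protocol tests."""

import numpy as np
import pytest

from lbdkit import discovery as disc
from lbdkit.discovery import BaselineClosedApproach, BaselineOpenApproach, ScoredRanking
from lbdkit.evaluation import (
    MetricReport,
    QueryResult,
    mean_average_precision,
    mean_rank,
    median_rank,
    mrr,
    r_precision,
    run_case_protocol,
    run_timeslice_protocol,
    summarize,
    tie_adjusted_rank,
)
from lbdkit.graph import DiscoveryCase
from tests.conftest import make_graph


def ranking_with_tie_block(gold_position, block_size, n_total):
    """Scored list with one tied block starting at ``gold_position``."""
    scores = {}
    for i in range(1, n_total + 1):
        if gold_position <= i < gold_position + block_size:
            score = float(n_total - gold_position)
        else:
            score = float(n_total - i)
        scores[f"e{i:03d}" if i != gold_position else "gold"] = score
    return ScoredRanking.from_scores("a", None, scores)


class TestTieAdjustedRank:
    def test_paper_worked_example_rank_15(self):
        # gold tied with 10 others, block occupying ranks 10..20
        r = ranking_with_tie_block(10, 11, 30)
        assert tie_adjusted_rank(r, "gold") == 15.0

    def test_unique_best_is_rank_one(self):
        r = ScoredRanking.from_scores("a", None, {"gold": 9.0, "x": 1.0, "y": 0.5})
        assert tie_adjusted_rank(r, "gold") == 1.0

    def test_two_way_tie_is_half_integral(self):
        r = ScoredRanking.from_scores("a", None, {"w": 5.0, "x": 4.0, "gold": 2.0, "y": 2.0})
        assert tie_adjusted_rank(r, "gold") == 3.5

    def test_absent_gold_is_none(self):
        r = ScoredRanking.from_scores("a", None, {"x": 1.0})
        assert tie_adjusted_rank(r, "gold") is None

    def test_permutation_invariant_under_ties(self):
        scores = {f"n{i}": 1.0 for i in range(6)}
        r = ScoredRanking.from_scores("a", None, scores)
        assert set(r.ranks) == {3.5}

    def test_fully_tied_list_averages_to_midpoint(self):
        n = 9
        r = ScoredRanking.from_scores("a", None, {f"n{i}": 2.0 for i in range(n)})
        assert np.mean(r.ranks) == pytest.approx((n + 1) / 2)


class TestSummaryMetrics:
    def test_mrr_single_gold_rank_4(self):
        res = [QueryResult(gold_ranks=(4.0,), n_candidates=10)]
        assert mrr(res) == pytest.approx(25.0)

    def test_map_worked_example(self):
        res = [QueryResult(gold_ranks=(1.0, 3.0), n_candidates=10)]
        assert mean_average_precision(res) == pytest.approx(100 * (1 + 2 / 3) / 2)

    def test_r_precision_half(self):
        res = [QueryResult(gold_ranks=(1.0, 5.0), n_candidates=10)]
        assert r_precision(res) == pytest.approx(50.0)

    def test_mean_median(self):
        res = [
            QueryResult(gold_ranks=(2.0,), n_candidates=10),
            QueryResult(gold_ranks=(6.0,), n_candidates=10),
            QueryResult(gold_ranks=(10.0,), n_candidates=10),
        ]
        assert mean_rank(res) == pytest.approx(6.0)
        assert median_rank(res) == pytest.approx(6.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mrr([])

    def test_antitone_in_gold_rank(self):
        for metric in (mrr, mean_average_precision, r_precision):
            values = [
                metric([QueryResult(gold_ranks=(r,), n_candidates=50)])
                for r in (1.0, 2.0, 10.0, 49.0)
            ]
            assert values == sorted(values, reverse=True)

    def test_scale_bounds(self):
        res = [QueryResult(gold_ranks=(1.0,), n_candidates=3)]
        rep = summarize(res)
        for v in (rep.mrr, rep.map, rep.r_precision):
            assert 0.0 <= v <= 100.0


def protocol_graph():
    """Pre-cutoff wedges plus post-cutoff closure links for protocol tests."""
    pre = [
        ("A", "B1", 2000, 9, 5), ("B1", "C1", 2000, 9, 5),
        ("A", "B2", 2000, 1, 1), ("B2", "C2", 2000, 1, 1),
        ("A2", "B3", 2000, 8, 4), ("B3", "C3", 2000, 8, 4),
        ("A2", "B4", 2000, 1, 1), ("B4", "C1", 2000, 1, 1),
    ]
    post = [("A", "C1", 2012, 2, 1), ("A2", "C3", 2013, 2, 1)]
    return make_graph(pre + post)


class TestCaseProtocol:
    def test_single_deterministic_case(self):
        graph = protocol_graph()
        cases = [DiscoveryCase(a="A", gold="C1", cutoff_year=2005)]
        approach = BaselineOpenApproach("count", "min", "sum")
        report = run_case_protocol(graph, cases, approach, seeds=[0])
        # C1 leg counts (9,9) beat C2 (1,1): gold rank 1
        assert report.mean_rank == 1.0
        assert report.median_rank == 1.0
        assert report.n_queries == 1

    def test_two_case_hand_computation(self):
        graph = protocol_graph()
        cases = [
            DiscoveryCase(a="A", gold="C1", cutoff_year=2005),
            DiscoveryCase(a="A", gold="C2", cutoff_year=2005),
        ]
        approach = BaselineOpenApproach("count", "min", "sum")
        report = run_case_protocol(graph, cases, approach, seeds=[0])
        # ranks 1 and 2 -> mean 1.5, median 1.5
        assert report.mean_rank == pytest.approx(1.5)
        assert report.median_rank == pytest.approx(1.5)

    def test_missing_endpoint_skipped(self):
        graph = protocol_graph()
        cases = [
            DiscoveryCase(a="A", gold="C1", cutoff_year=2005),
            DiscoveryCase(a="ZZZ", gold="C1", cutoff_year=2005),
        ]
        report = run_case_protocol(graph, cases, BaselineOpenApproach("count", "min", "sum"), [0])
        assert report.n_queries == 1
        assert report.n_unranked == 1

    def test_closed_case(self):
        graph = protocol_graph()
        cases = [DiscoveryCase(a="A", c="C1", gold="B1", cutoff_year=2005)]
        report = run_case_protocol(graph, cases, BaselineClosedApproach("count", "min"), [0])
        assert report.mean_rank == 1.0

    def test_best_checkpoint_rank_kept(self):
        graph = protocol_graph()
        cases = [DiscoveryCase(a="A", gold="C2", cutoff_year=2005)]

        class TwoCheckpointApproach:
            def fit(self, slice_, seed):
                return ["bad", "good"]

            def rank(self, checkpoint, slice_, a):
                if checkpoint == "good":
                    return ScoredRanking.from_scores(a, None, {"C2": 2.0, "C1": 1.0})
                return ScoredRanking.from_scores(a, None, {"C1": 2.0, "C2": 1.0})

        report = run_case_protocol(graph, cases, TwoCheckpointApproach(), [0])
        assert report.mean_rank == 1.0  # best over checkpoints, not last


class TestTimesliceProtocol:
    def make_temporal_graph(self):
        rng = np.random.default_rng(12)
        rows = []
        names = [f"N{i:02d}" for i in range(40)]
        for i in range(40):
            for j in range(i + 1, 40):
                if rng.random() < 0.12:
                    rows.append((names[i], names[j], 2010, int(rng.integers(1, 9)), 1))
        graph = make_graph(rows, extra_nodes=names)
        # post-cutoff: close wedges
        s = graph.slice(2016)
        post = []
        for i in range(40):
            for j in range(i + 1, 40):
                u, v = names[i], names[j]
                if s.has_edge(u, v):
                    continue
                shared = len(s.neighbors(u) & s.neighbors(v))
                if shared >= 2 and rng.random() < 0.5:
                    post.append((u, v, 2017, 1, 1))
        return make_graph(rows + post, extra_nodes=names)

    def test_baseline_protocol_runs(self):
        graph = self.make_temporal_graph()
        approach = BaselineOpenApproach("jaccard", "min", "sum")
        report = run_timeslice_protocol(
            graph, 2016, dev_fraction=0.5, n_queries=10, approach=approach, seed=0
        )
        assert report.n_queries >= 1
        assert 0 <= report.mrr <= 100

    def test_argmax_checkpoint_selected(self):
        graph = self.make_temporal_graph()
        train = graph.slice(2016)

        calls = []

        class RecordingApproach(BaselineOpenApproach):
            def fit(self, slice_, seed):
                return [disc._Checkpoint(epoch=e, scorer=None, emb=None) for e in (25, 50)]

            def rank(self, checkpoint, slice_, a):
                calls.append(checkpoint.epoch)
                base = super().rank(None, slice_, a)
                if checkpoint.epoch == 25:
                    # invert: worst dev MRR
                    inverted = {e: -s for e, s in zip(base.candidates, base.scores)}
                    return ScoredRanking.from_scores(a, None, inverted)
                return base

        approach = RecordingApproach("jaccard", "min", "sum")
        report = run_timeslice_protocol(
            graph, 2016, dev_fraction=0.5, n_queries=8, approach=approach, seed=1
        )
        good = run_timeslice_protocol(
            graph, 2016, dev_fraction=0.5, n_queries=8,
            approach=BaselineOpenApproach("jaccard", "min", "sum"), seed=1
        )
        # epoch-50 checkpoint (the non-inverted one) must have been chosen
        assert report.mrr == pytest.approx(good.mrr)

    def test_more_queries_than_nodes_uses_all(self):
        graph = self.make_temporal_graph()
        approach = BaselineOpenApproach("count", "min", "sum")
        r1 = run_timeslice_protocol(graph, 2016, 0.5, 10_000, approach, seed=2)
        assert r1.n_queries >= 1

    def test_full_pipeline_matches_bruteforce_report(self):
        """Deterministic baseline on a small graph vs a hand-built report."""
        graph = self.make_temporal_graph()
        approach = BaselineOpenApproach("count", "min", "sum")
        report = run_timeslice_protocol(graph, 2016, 0.4, 10_000, approach, seed=3)

        # independent recomputation
        from lbdkit.graph import c_candidates, timeslice_split
        train, dev, test = timeslice_split(graph, 2016, 0.4, seed=3)
        partners = {}
        for u, v in test:
            partners.setdefault(u, set()).add(v)
            partners.setdefault(v, set()).add(u)
        results = []
        for a in sorted(partners):
            cands = c_candidates(train, a)
            golds = sorted(partners[a] & cands)
            if not golds:
                continue
            ranking = disc.baseline_open(train, "count", "min", "sum", a)
            ranks = [ranking.rank_of(g) for g in golds if ranking.rank_of(g) is not None]
            if ranks:
                results.append(QueryResult(gold_ranks=tuple(ranks), n_candidates=len(ranking)))
        expected = summarize(results)
        assert report.mean_rank == pytest.approx(expected.mean_rank)
        assert report.mrr == pytest.approx(expected.mrr)
        assert report.map == pytest.approx(expected.map)
        assert report.r_precision == pytest.approx(expected.r_precision)


class TestNeuralApproachProtocols:
    def test_timeslice_with_od1(self):
        from lbdkit.discovery import OD1Approach
        from lbdkit.embeddings import EmbeddingConfig
        from lbdkit.scorers import TrainConfig

        graph = TestTimesliceProtocol().make_temporal_graph()
        approach = OD1Approach(
            combiner="hadamard",
            emb_config=EmbeddingConfig(dim_per_order=4, total_samples=2000, seed=0),
            train_config=TrainConfig(batch_size=20, train_set_size=100, epochs=4,
                                     eval_interval_epochs=2, seed=0),
            hidden_units=8,
        )
        report = run_timeslice_protocol(
            graph, 2016, dev_fraction=0.5, n_queries=5, approach=approach, seed=4
        )
        assert report.n_queries >= 1
        assert 0 <= report.mrr <= 100

    def test_case_protocol_with_cd1_multi_seed(self):
        from lbdkit.discovery import CD1Approach
        from lbdkit.embeddings import EmbeddingConfig
        from lbdkit.scorers import TrainConfig

        graph = protocol_graph()
        cases = [DiscoveryCase(a="A", c="C1", gold="B1", cutoff_year=2005)]
        approach = CD1Approach(
            aggregator="min",
            combiner="hadamard",
            emb_config=EmbeddingConfig(dim_per_order=4, total_samples=1000, seed=0),
            train_config=TrainConfig(batch_size=10, train_set_size=40, epochs=4,
                                     eval_interval_epochs=2, seed=0),
            hidden_units=8,
        )
        report = run_case_protocol(graph, cases, approach, seeds=[0, 1])
        assert report.n_queries == 2  # one case x two seeds
        assert report.mean_rank_std is not None


def test_metric_report_text_roundtrip():
    rep = MetricReport(mean_rank=3.0, median_rank=2.0, mrr=50.0, map=40.0,
                       r_precision=30.0, n_queries=4, n_unranked=1, mean_rank_std=0.5)
    text = rep.to_text()
    assert "mean_rank: 3.0000" in text
    assert "mean_rank_std: 0.5000" in text
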