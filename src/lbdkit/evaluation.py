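"""Tie-aware rank metrics and the two evaluation protocols.

Rank metrics follow standard information-retrieval definitions computed over
tie-adjusted (median-of-tied-range) ranks.  MRR, MAP and R-precision are
reported on a 0-100 scale; mean and median rank are unscaled.

Two harnesses are provided: the case-replication protocol (train per case
slice, checkpoint every few epochs, keep the best checkpoint rank per case,
average across seeds) and the time-sliced protocol (one temporal split,
checkpoint selection by development-set MRR, final scoring on held-out test
queries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from lbdkit.graph import DiscoveryCase, GraphSlice, TemporalGraph, c_candidates, timeslice_split
from lbdkit.discovery import ScoredRanking

logger = logging.getLogger(__name__)

__all__ = [
    "QueryResult",
    "MetricReport",
    "tie_adjusted_rank",
    "mean_rank",
    "median_rank",
    "mrr",
    "mean_average_precision",
    "r_precision",
    "summarize",
    "run_case_protocol",
    "run_timeslice_protocol",
]


@dataclass(frozen=True)
class QueryResult:
    """Tie-adjusted ranks of a query's gold items within its candidate list."""

    gold_ranks: tuple[float, ...]
    n_candidates: int

    def __post_init__(self) -> None:
        for r in self.gold_ranks:
            if not 1.0 <= r <= self.n_candidates:
                raise ValueError(f"rank {r} outside [1, {self.n_candidates}]")

    @property
    def best_rank(self) -> float:
        return min(self.gold_ranks)


@dataclass
class MetricReport:
    mean_rank: float
    median_rank: float
    mrr: float
    map: float
    r_precision: float
    n_queries: int
    n_unranked: int = 0
    mean_rank_std: float | None = None  # across seeds, where applicable

    def to_text(self) -> str:
        lines = [
            f"mean_rank: {self.mean_rank:.4f}",
            f"median_rank: {self.median_rank:.4f}",
            f"mrr: {self.mrr:.4f}",
            f"map: {self.map:.4f}",
            f"r_precision: {self.r_precision:.4f}",
            f"n_queries: {self.n_queries}",
            f"n_unranked: {self.n_unranked}",
        ]
        if self.mean_rank_std is not None:
            lines.append(f"mean_rank_std: {self.mean_rank_std:.4f}")
        return "\n".join(lines)


def tie_adjusted_rank(ranking: ScoredRanking, gold: str) -> float | None:
    """Gold's rank under the median-of-tied-range rule; None if absent."""
    return ranking.rank_of(gold)


def mean_rank(results) -> float:
    _require(results)
    return float(np.mean([r.best_rank for r in results]))


def median_rank(results) -> float:
    _require(results)
    return float(np.median([r.best_rank for r in results]))


def mrr(results) -> float:
    """Mean reciprocal best-gold rank, scaled to 0-100."""
    _require(results)
    return 100.0 * float(np.mean([1.0 / r.best_rank for r in results]))


def mean_average_precision(results) -> float:
    """Mean average precision over tie-adjusted gold ranks, scaled to 0-100."""
    _require(results)
    aps = []
    for r in results:
        ranks = sorted(r.gold_ranks)
        ap = np.mean([(i + 1) / rank for i, rank in enumerate(ranks)])
        aps.append(ap)
    return 100.0 * float(np.mean(aps))


def r_precision(results) -> float:
    """Mean fraction of golds ranked within the top R (R = gold count), 0-100."""
    _require(results)
    fracs = []
    for r in results:
        big_r = len(r.gold_ranks)
        fracs.append(sum(1 for g in r.gold_ranks if g <= big_r) / big_r)
    return 100.0 * float(np.mean(fracs))


def summarize(results, n_unranked: int = 0, mean_rank_std: float | None = None) -> MetricReport:
    return MetricReport(
        mean_rank=mean_rank(results),
        median_rank=median_rank(results),
        mrr=mrr(results),
        map=mean_average_precision(results),
        r_precision=r_precision(results),
        n_queries=len(results),
        n_unranked=n_unranked,
        mean_rank_std=mean_rank_std,
    )


def _require(results) -> None:
    if len(results) == 0:
        raise ValueError("metrics require at least one query result")


def _result_for(ranking: ScoredRanking, golds) -> QueryResult | None:
    ranks = [ranking.rank_of(g) for g in golds]
    ranks = [r for r in ranks if r is not None]
    if not ranks:
        return None
    return QueryResult(gold_ranks=tuple(ranks), n_candidates=len(ranking))


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def run_case_protocol(
    graph: TemporalGraph,
    cases: list[DiscoveryCase],
    approach,
    seeds,
) -> MetricReport:
    """Case replication: per case, train on its cutoff slice and keep the
    best checkpoint rank; report means/medians averaged across seeds.

    The approach object supplies ``fit(slice, seed) -> checkpoints`` and
    ``rank(checkpoint, slice, a[, c]) -> ScoredRanking``.
    """
    if not cases:
        raise ValueError("case protocol requires at least one case")
    seeds = list(seeds)
    per_seed_ranks: list[list[float]] = []
    n_skipped = 0
    slices: dict[int, GraphSlice] = {}
    for seed in seeds:
        case_ranks: list[float] = []
        for case in cases:
            if case.cutoff_year not in slices:
                slices[case.cutoff_year] = graph.slice(case.cutoff_year)
            slice_ = slices[case.cutoff_year]
            if case.a not in slice_.adjacency or (
                case.is_closed and case.c not in slice_.adjacency
            ):
                logger.warning("case %s skipped: endpoint absent from slice", case)
                n_skipped += 1
                continue
            checkpoints = approach.fit(slice_, seed)
            best: float | None = None
            for cp in checkpoints:
                if case.is_closed:
                    ranking = approach.rank(cp, slice_, case.a, case.c)
                else:
                    ranking = approach.rank(cp, slice_, case.a)
                r = ranking.rank_of(case.gold)
                if r is not None and (best is None or r < best):
                    best = r
            if best is None:
                logger.warning("case %s: gold never ranked; excluded", case)
                n_skipped += 1
                continue
            case_ranks.append(best)
        if case_ranks:
            per_seed_ranks.append(case_ranks)
    if not per_seed_ranks:
        raise ValueError("no case produced a ranked gold")
    seed_means = [float(np.mean(r)) for r in per_seed_ranks]
    seed_medians = [float(np.median(r)) for r in per_seed_ranks]
    all_results = [
        QueryResult(gold_ranks=(r,), n_candidates=max(int(np.ceil(r)), 1))
        for ranks in per_seed_ranks
        for r in ranks
    ]
    return MetricReport(
        mean_rank=float(np.mean(seed_means)),
        median_rank=float(np.mean(seed_medians)),
        mrr=mrr(all_results),
        map=mean_average_precision(all_results),
        r_precision=r_precision(all_results),
        n_queries=sum(len(r) for r in per_seed_ranks),
        n_unranked=n_skipped,
        mean_rank_std=float(np.std(seed_means)) if len(seed_means) > 1 else None,
    )


def _score_queries(approach, checkpoint, slice_, queries) -> tuple[list[QueryResult], int]:
    results: list[QueryResult] = []
    unranked = 0
    for a, golds in queries:
        ranking = approach.rank(checkpoint, slice_, a)
        res = _result_for(ranking, golds)
        if res is None:
            unranked += 1
            continue
        results.append(res)
    return results, unranked


def run_timeslice_protocol(
    graph: TemporalGraph,
    cutoff_year: int,
    dev_fraction: float,
    n_queries: int,
    approach,
    seed: int,
    n_dev_queries: int | None = None,
) -> MetricReport:
    """Time-sliced open discovery with dev-MRR checkpoint selection.

    Post-cutoff new links are split into dev/test pair sets; checkpoints are
    scored on dev queries by MRR and the argmax checkpoint is scored once on
    the sampled test queries.  A query's gold set is the A node's post-cutoff
    new partners that fall inside its two-hop candidate set; queries whose
    gold set is empty are excluded and counted.
    """
    train, dev_pairs, test_pairs = timeslice_split(graph, cutoff_year, dev_fraction, seed)
    rng = np.random.default_rng(seed)

    def build_queries(pairs, limit):
        partners: dict[str, set[str]] = {}
        for u, v in pairs:
            partners.setdefault(u, set()).add(v)
            partners.setdefault(v, set()).add(u)
        a_nodes = sorted(a for a in partners if a in train.adjacency)
        if limit is not None and limit < len(a_nodes):
            idx = rng.choice(len(a_nodes), size=limit, replace=False)
            a_nodes = [a_nodes[i] for i in sorted(idx)]
        elif limit is not None and limit > len(a_nodes):
            logger.warning(
                "requested %d queries but only %d A nodes available; using all",
                limit, len(a_nodes),
            )
        queries = []
        for a in a_nodes:
            cands = c_candidates(train, a)
            golds = sorted(partners[a] & cands)
            if golds:
                queries.append((a, golds))
        return queries

    dev_queries = build_queries(dev_pairs, n_dev_queries)
    test_queries = build_queries(test_pairs, n_queries)
    if not dev_queries or not test_queries:
        raise ValueError("timeslice protocol produced no usable queries")

    checkpoints = approach.fit(train, seed)
    best_cp, best_mrr = None, -1.0
    for cp in checkpoints:
        dev_results, _ = _score_queries(approach, cp, train, dev_queries)
        cp_mrr = mrr(dev_results) if dev_results else 0.0
        logger.info("checkpoint epoch %d: dev MRR %.4f", cp.epoch, cp_mrr)
        if cp_mrr > best_mrr:
            best_cp, best_mrr = cp, cp_mrr
    results, unranked = _score_queries(approach, best_cp, train, test_queries)
    if not results:
        raise ValueError("no test query produced a ranked gold")
    return summarize(results, n_unranked=unranked)
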