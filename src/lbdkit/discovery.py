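"""Open and closed discovery rankings: co-occurrence baselines and the four
neural approaches.

Closed discovery ranks linking-term candidates B for a given (A, C); open
discovery ranks two-hop target candidates C for a given A.  Each operation
returns a :class:`ScoredRanking` whose tie-adjusted ranks follow the
median-of-tied-range rule.

CD-1 and OD-1 replace the baseline edge metric with a neural link scorer but
keep the aggregator (and, for open discovery, accumulator) machinery; the
link scorer is an arbitrary ``(u, v) -> score`` callable, so substituting a
metric-backed scorer reproduces the baselines exactly.  CD-2 scores the
combined A-B-C vector in one shot; OD-2 scores the packed window over all
A-B-C paths per candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from lbdkit import scorers as sc
from lbdkit.embeddings import (
    EmbeddingConfig,
    EmbeddingTable,
    edge_weights_jaccard,
    train_both_orders,
)
from lbdkit.graph import GraphSlice, b_candidates, c_candidates
from lbdkit.metrics import UndefinedScoreError, get_metric
from lbdkit.paths import aggregate, accumulate, combine, combined_dim

logger = logging.getLogger(__name__)

__all__ = [
    "ScoredRanking",
    "tie_adjusted_ranks",
    "metric_link_scorer",
    "embedding_link_scorer",
    "baseline_closed",
    "baseline_open",
    "closed_cd1",
    "closed_cd2",
    "open_od1",
    "open_od2",
    "BaselineClosedApproach",
    "BaselineOpenApproach",
    "CD1Approach",
    "CD2Approach",
    "OD1Approach",
    "OD2Approach",
]


def tie_adjusted_ranks(scores: np.ndarray) -> np.ndarray:
    """Median-of-tied-range ranks for scores already sorted descending."""
    n = len(scores)
    ranks = np.empty(n, dtype=np.float64)
    start = 0
    while start < n:
        end = start
        while end + 1 < n and scores[end + 1] == scores[start]:
            end += 1
        ranks[start:end + 1] = (start + 1 + end + 1) / 2.0
        start = end + 1
    return ranks


@dataclass(frozen=True)
class ScoredRanking:
    """Candidates for one discovery query, sorted by descending score."""

    a: str
    c: str | None
    candidates: tuple[str, ...]
    scores: tuple[float, ...]
    ranks: tuple[float, ...]  # tie-adjusted

    @classmethod
    def from_scores(cls, a: str, c: str | None, score_map: dict[str, float]) -> "ScoredRanking":
        for ent, s in score_map.items():
            if not np.isfinite(s):
                raise ValueError(f"non-finite score for candidate {ent!r}")
        ordered = sorted(score_map.items(), key=lambda kv: (-kv[1], kv[0]))
        cands = tuple(ent for ent, _ in ordered)
        scores = tuple(float(s) for _, s in ordered)
        ranks = tuple(float(r) for r in tie_adjusted_ranks(np.array(scores)))
        return cls(a=a, c=c, candidates=cands, scores=scores, ranks=ranks)

    def __len__(self) -> int:
        return len(self.candidates)

    def rank_of(self, entity: str) -> float | None:
        try:
            return self.ranks[self.candidates.index(entity)]
        except ValueError:
            return None

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tentity\tscore\ttie_adjusted_rank\n")
            for i, (ent, s, r) in enumerate(
                zip(self.candidates, self.scores, self.ranks), start=1
            ):
                fh.write(f"{i}\t{ent}\t{s:.10g}\t{r:g}\n")


# ---------------------------------------------------------------------------
# link scorers
# ---------------------------------------------------------------------------


def metric_link_scorer(slice_: GraphSlice, metric):
    """Adapt a co-occurrence metric into a ``(u, v) -> score`` callable."""
    fn = get_metric(metric) if isinstance(metric, str) else metric

    def link_score(u: str, v: str) -> float:
        try:
            return float(fn(slice_.contingency(u, v)))
        except UndefinedScoreError:
            return 0.0

    return link_score


def embedding_link_scorer(emb: EmbeddingTable, scorer, combiner: str):
    """Adapt a trained link scorer over combined embedding pairs."""

    def link_score(u: str, v: str) -> float:
        return float(scorer.score(combine([emb[u], emb[v]], combiner)))

    return link_score


# ---------------------------------------------------------------------------
# ranking operations
# ---------------------------------------------------------------------------


def _closed_by_link_scores(slice_, link_score, aggregator, a, c) -> ScoredRanking:
    bs = b_candidates(slice_, a, c)
    if not bs:
        logger.warning("no B candidates for (%s, %s)", a, c)
    score_map = {
        b: aggregate([link_score(a, b), link_score(b, c)], aggregator) for b in bs
    }
    return ScoredRanking.from_scores(a, c, score_map)


def _open_by_link_scores(slice_, link_score, aggregator, accumulator, a) -> ScoredRanking:
    cands = c_candidates(slice_, a)
    if not cands:
        logger.warning("no C candidates for %s", a)
    ab_cache = {b: link_score(a, b) for b in slice_.neighbors(a)}
    score_map: dict[str, float] = {}
    for cand in cands:
        path_scores = [
            aggregate([ab_cache[b], link_score(b, cand)], aggregator)
            for b in (slice_.neighbors(a) & slice_.neighbors(cand))
        ]
        score_map[cand] = accumulate(path_scores, accumulator)
    return ScoredRanking.from_scores(a, None, score_map)


def baseline_closed(slice_, metric, aggregator, a, c) -> ScoredRanking:
    """Rank Bs by aggregating the metric over the A-B and B-C edges."""
    return _closed_by_link_scores(slice_, metric_link_scorer(slice_, metric), aggregator, a, c)


def baseline_open(slice_, metric, aggregator, accumulator, a) -> ScoredRanking:
    """Rank Cs by accumulating aggregated metric scores over all A-B-C paths."""
    return _open_by_link_scores(
        slice_, metric_link_scorer(slice_, metric), aggregator, accumulator, a
    )


def closed_cd1(slice_, link_scorer, aggregator, a, c) -> ScoredRanking:
    """CD-1: baseline closed discovery with neural per-link scores."""
    return _closed_by_link_scores(slice_, link_scorer, aggregator, a, c)


def open_od1(slice_, link_scorer, aggregator, accumulator, a) -> ScoredRanking:
    """OD-1: baseline open discovery with neural per-link scores."""
    return _open_by_link_scores(slice_, link_scorer, aggregator, accumulator, a)


def closed_cd2(slice_, emb, scorer, combiner, a, c) -> ScoredRanking:
    """CD-2: score the combined A-B-C vector in one shot (no aggregator)."""
    bs = sorted(b_candidates(slice_, a, c))
    kept, feats = [], []
    for b in bs:
        if b not in emb or a not in emb or c not in emb:
            logger.warning("candidate %s lacks an embedding; skipped", b)
            continue
        kept.append(b)
        feats.append(combine([emb[a], emb[b], emb[c]], combiner))
    if not kept:
        return ScoredRanking.from_scores(a, c, {})
    scores = np.atleast_1d(scorer.score(np.stack(feats)))
    return ScoredRanking.from_scores(a, c, dict(zip(kept, map(float, scores))))


def open_od2(slice_, emb, cnn_scorer, combiner, window_height, a) -> ScoredRanking:
    """OD-2: pack all A-B-C path vectors per candidate and score once."""
    cands = sorted(c_candidates(slice_, a))
    kept, windows = [], []
    for cand in cands:
        window = sc.path_window(slice_, emb, combiner, window_height, a, cand)
        if window is None:
            logger.warning("candidate %s has no scorable path; skipped", cand)
            continue
        kept.append(cand)
        windows.append(window)
    if not kept:
        return ScoredRanking.from_scores(a, None, {})
    scores = np.atleast_1d(cnn_scorer.score(np.stack(windows)))
    return ScoredRanking.from_scores(a, None, dict(zip(kept, map(float, scores))))


# ---------------------------------------------------------------------------
# approach orchestration (training + ranking, for the evaluation protocols)
# ---------------------------------------------------------------------------


@dataclass
class _Checkpoint:
    epoch: int
    scorer: object | None
    emb: EmbeddingTable | None


class _ApproachBase:
    """Shared training plumbing for the neural approaches."""

    def __init__(
        self,
        combiner: str = "hadamard",
        emb_config: EmbeddingConfig | None = None,
        train_config: sc.TrainConfig | None = None,
        hidden_units: int = 100,
    ):
        self.combiner = combiner
        self.emb_config = emb_config or EmbeddingConfig()
        self.train_config = train_config or sc.TrainConfig()
        self.hidden_units = hidden_units

    def _embed(self, slice_: GraphSlice, seed: int) -> EmbeddingTable:
        edges = edge_weights_jaccard(slice_)
        cfg = replace(self.emb_config, seed=self.emb_config.seed + seed)
        return train_both_orders(edges, cfg, nodes=slice_.nodes)

    def _collect(self, train_fn) -> list[_Checkpoint]:
        checkpoints: list[_Checkpoint] = []

        def hook(epoch, snapshot):
            checkpoints.append(_Checkpoint(epoch=epoch, scorer=snapshot, emb=None))

        final = train_fn(hook)
        if not checkpoints or checkpoints[-1].epoch != self.train_config.epochs:
            checkpoints.append(
                _Checkpoint(epoch=self.train_config.epochs, scorer=final.copy(), emb=None)
            )
        return checkpoints


class BaselineClosedApproach:
    def __init__(self, metric: str, aggregator: str):
        self.metric = metric
        self.aggregator = aggregator

    def fit(self, slice_: GraphSlice, seed: int) -> list[_Checkpoint]:
        return [_Checkpoint(epoch=0, scorer=None, emb=None)]

    def rank(self, checkpoint, slice_, a, c) -> ScoredRanking:
        return baseline_closed(slice_, self.metric, self.aggregator, a, c)


class BaselineOpenApproach:
    def __init__(self, metric: str, aggregator: str, accumulator: str):
        self.metric = metric
        self.aggregator = aggregator
        self.accumulator = accumulator

    def fit(self, slice_: GraphSlice, seed: int) -> list[_Checkpoint]:
        return [_Checkpoint(epoch=0, scorer=None, emb=None)]

    def rank(self, checkpoint, slice_, a) -> ScoredRanking:
        return baseline_open(slice_, self.metric, self.aggregator, self.accumulator, a)


class _LinkModelApproach(_ApproachBase):
    """Trains the shared A-B / B-C link MLP used by CD-1 and OD-1."""

    def _fit_link_model(self, slice_: GraphSlice, seed: int) -> list[_Checkpoint]:
        emb = self._embed(slice_, seed)
        tc = replace(self.train_config, seed=self.train_config.seed + seed)
        examples = sc.build_link_examples(
            slice_, emb, self.combiner, tc.train_set_size, seed=tc.seed
        )
        cfg = sc.MLPScorerConfig(
            input_dim=combined_dim(emb.dim, self.combiner, 2),
            hidden_units=self.hidden_units,
            seed=tc.seed,
        )
        checkpoints = self._collect(
            lambda hook: sc.train_mlp(examples, cfg, tc, checkpoint_hook=hook)
        )
        for cp in checkpoints:
            cp.emb = emb
        return checkpoints


class CD1Approach(_LinkModelApproach):
    def __init__(self, aggregator: str = "min", **kwargs):
        super().__init__(**kwargs)
        self.aggregator = aggregator

    fit = _LinkModelApproach._fit_link_model

    def rank(self, checkpoint, slice_, a, c) -> ScoredRanking:
        link = embedding_link_scorer(checkpoint.emb, checkpoint.scorer, self.combiner)
        return closed_cd1(slice_, link, self.aggregator, a, c)


class OD1Approach(_LinkModelApproach):
    def __init__(self, aggregator: str = "min", accumulator: str = "sum", **kwargs):
        super().__init__(**kwargs)
        self.aggregator = aggregator
        self.accumulator = accumulator

    fit = _LinkModelApproach._fit_link_model

    def rank(self, checkpoint, slice_, a) -> ScoredRanking:
        link = embedding_link_scorer(checkpoint.emb, checkpoint.scorer, self.combiner)
        return open_od1(slice_, link, self.aggregator, self.accumulator, a)


class CD2Approach(_ApproachBase):
    def fit(self, slice_: GraphSlice, seed: int) -> list[_Checkpoint]:
        emb = self._embed(slice_, seed)
        tc = replace(self.train_config, seed=self.train_config.seed + seed)
        examples = sc.build_path_examples(
            slice_, emb, self.combiner, tc.train_set_size, seed=tc.seed
        )
        cfg = sc.MLPScorerConfig(
            input_dim=combined_dim(emb.dim, self.combiner, 3),
            hidden_units=self.hidden_units,
            seed=tc.seed,
        )
        checkpoints = self._collect(
            lambda hook: sc.train_mlp(examples, cfg, tc, checkpoint_hook=hook)
        )
        for cp in checkpoints:
            cp.emb = emb
        return checkpoints

    def rank(self, checkpoint, slice_, a, c) -> ScoredRanking:
        return closed_cd2(slice_, checkpoint.emb, checkpoint.scorer, self.combiner, a, c)


class OD2Approach(_ApproachBase):
    def __init__(
        self,
        window_height: int = 50,
        conv_height: int = 7,
        conv_filters: int = 128,
        fc_units: int = 128,
        **kwargs,
    ):
        super().__init__(**kwargs)
        self.window_height = window_height
        self.conv_height = conv_height
        self.conv_filters = conv_filters
        self.fc_units = fc_units

    def fit(self, slice_: GraphSlice, seed: int) -> list[_Checkpoint]:
        emb = self._embed(slice_, seed)
        tc = replace(self.train_config, seed=self.train_config.seed + seed)
        examples = sc.build_stack_examples(
            slice_, emb, self.combiner, self.window_height, tc.train_set_size, seed=tc.seed
        )
        cfg = sc.CNNScorerConfig(
            input_width=combined_dim(emb.dim, self.combiner, 3),
            window_height=self.window_height,
            conv_height=self.conv_height,
            conv_filters=self.conv_filters,
            fc_units=self.fc_units,
            seed=tc.seed,
        )
        checkpoints = self._collect(
            lambda hook: sc.train_cnn(examples, cfg, tc, checkpoint_hook=hook)
        )
        for cp in checkpoints:
            cp.emb = emb
        return checkpoints

    def rank(self, checkpoint, slice_, a) -> ScoredRanking:
        return open_od2(
            slice_, checkpoint.emb, checkpoint.scorer, self.combiner, self.window_height, a
        )
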