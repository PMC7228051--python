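"""Synthetic temporal co-occurrence graphs with planted triadic closure.

Pre-cutoff edges come from a stochastic-block-style community model: dense,
count-heavy links inside communities and sparse, count-light links between
them, each stamped with a uniform pre-cutoff birth year.  Post-cutoff edges
are drawn for previously unlinked pairs with log-odds increasing in their
Jaccard-weighted wedge mass (the sum over shared neighbours of the smaller
leg Jaccard) scaled by ``closure_strength``, so future links preferentially
close wedges with high-Jaccard legs and every pipeline stage has a
recoverable signal.

Sentence counts are shifted Poisson (>= 1); document counts are a binomial
thinning of sentence counts (>= 1), which respects doc <= sent.  Node and
corpus totals are accumulated from incident edges plus background mentions,
which guarantees the contingency invariants on every slice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from lbdkit.graph import (
    DiscoveryCase,
    Entity,
    TemporalGraph,
    b_candidates,
    c_candidates,
)

__all__ = ["SyntheticConfig", "generate_graph", "derive_cases", "PRESETS"]

_ENTITY_TYPES = ("chemical", "gene", "disease")

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    n_nodes: int = 60
    n_communities: int = 4
    start_year: int = 2000
    end_year: int = 2015
    cutoff_year: int = 2010
    p_intra: float = 0.6
    p_inter: float = 0.2
    mean_sent_count: float = 1.0
    intra_count_boost: float = 20.0  # extra mean sentence count inside communities
    doc_thinning: float = 0.7
    closure_strength: float = 50.0  # scales the Jaccard-weighted wedge mass
    base_closure_logit: float = -12.0
    background_mentions: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if self.n_communities < 1 or self.n_communities > self.n_nodes:
            raise ValueError("n_communities must lie in [1, n_nodes]")
        if not self.start_year <= self.cutoff_year < self.end_year:
            raise ValueError("need start_year <= cutoff_year < end_year")
        for p in (self.p_intra, self.p_inter, self.doc_thinning):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.closure_strength < 0:
            raise ValueError("closure_strength must be >= 0")


def generate_graph(config: SyntheticConfig) -> TemporalGraph:
    """Generate a reproducible temporal graph per the module docstring."""
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    width = max(3, len(str(n - 1)))
    names = [f"E{str(i).zfill(width)}" for i in range(n)]
    community = np.array([i % config.n_communities for i in range(n)])

    graph = TemporalGraph()
    for i, name in enumerate(names):
        graph.entities[name] = Entity(name, _ENTITY_TYPES[i % len(_ENTITY_TYPES)])

    pre_years = list(range(config.start_year, config.cutoff_year + 1))
    post_years = list(range(config.cutoff_year + 1, config.end_year + 1))

    # Pre-cutoff: community model.
    adjacency: dict[int, set[int]] = {i: set() for i in range(n)}
    edge_rows = []  # (i, j, year, sent, doc)
    for i in range(n):
        for j in range(i + 1, n):
            intra = community[i] == community[j]
            p = config.p_intra if intra else config.p_inter
            if rng.random() >= p:
                continue
            year = int(rng.choice(pre_years))
            mean = config.mean_sent_count + (config.intra_count_boost if intra else 0.0)
            sent = int(1 + rng.poisson(max(mean - 1.0, 0.0)))
            doc = int(1 + rng.binomial(sent - 1, config.doc_thinning))
            edge_rows.append((i, j, year, sent, doc))
            adjacency[i].add(j)
            adjacency[j].add(i)

    # Pre-cutoff leg Jaccard (edge-incident totals as the node marginals).
    node_sent = np.zeros(n)
    pair_sent: dict[tuple[int, int], int] = {}
    for i, j, _, sent, _ in edge_rows:
        node_sent[i] += sent
        node_sent[j] += sent
        key = (i, j)
        pair_sent[key] = pair_sent.get(key, 0) + sent

    def leg_jaccard(i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        c = pair_sent[key]
        return c / (node_sent[i] + node_sent[j] - c)

    # Post-cutoff: triadic closure weighted by leg Jaccard.
    for i in range(n):
        for j in range(i + 1, n):
            if j in adjacency[i]:
                continue
            mass = sum(
                min(leg_jaccard(i, b), leg_jaccard(b, j))
                for b in adjacency[i] & adjacency[j]
            )
            logit = config.base_closure_logit + config.closure_strength * mass
            if rng.random() >= 1.0 / (1.0 + math.exp(-logit)):
                continue
            year = int(rng.choice(post_years))
            sent = int(1 + rng.poisson(max(config.mean_sent_count - 1.0, 0.0)))
            doc = int(1 + rng.binomial(sent - 1, config.doc_thinning))
            edge_rows.append((i, j, year, sent, doc))

    # Node/corpus totals: incident edge counts plus background mentions.
    node_year_sent: dict[tuple[int, int], int] = {}
    node_year_doc: dict[tuple[int, int], int] = {}
    for i, j, year, sent, doc in edge_rows:
        for node in (i, j):
            key = (node, year)
            node_year_sent[key] = node_year_sent.get(key, 0) + sent
            node_year_doc[key] = node_year_doc.get(key, 0) + doc
    all_years = pre_years + post_years
    for i in range(n):
        for year in all_years:
            extra = int(rng.poisson(config.background_mentions))
            if extra:
                key = (i, year)
                node_year_sent[key] = node_year_sent.get(key, 0) + extra
                node_year_doc[key] = node_year_doc.get(key, 0) + extra

    for i, j, year, sent, doc in edge_rows:
        u, v = sorted((names[i], names[j]))
        counts = graph.edge_years.setdefault((u, v), {})
        cur = counts.setdefault(year, [0, 0])
        cur[0] += sent
        cur[1] += doc
    for (i, year), sent in node_year_sent.items():
        graph.node_year_counts[(names[i], year)] = sent
    for year in all_years:
        total_s = sum(s for (_, y), s in node_year_sent.items() if y == year)
        total_d = sum(d for (_, y), d in node_year_doc.items() if y == year)
        graph.corpus_totals[year] = (max(total_s, 1), max(total_d, 1))

    graph.validate()
    return graph


def derive_cases(
    graph: TemporalGraph,
    cutoff: int,
    mode: str,
    k: int,
    seed: int,
) -> list[DiscoveryCase]:
    """Derive discovery cases from post-cutoff new links with pre-cutoff paths.

    Open cases: (a, gold C) where C is a new post-cutoff partner of ``a``
    lying in ``c_candidates`` of the cutoff slice.  Closed cases: (a, c,
    gold B) where B is the highest-weight common neighbour (weight = min of
    the two leg sentence counts, ties broken lexicographically).
    """
    if mode not in ("open", "closed"):
        raise ValueError("mode must be 'open' or 'closed'")
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    slice_ = graph.slice(cutoff)
    new_links = sorted(
        (u, v)
        for (u, v), yc in graph.edge_years.items()
        if (u, v) not in slice_.edge_counts and any(y > cutoff for y in yc)
    )
    eligible: list[DiscoveryCase] = []
    for u, v in new_links:
        bs = b_candidates(slice_, u, v)
        if not bs:
            continue
        if mode == "open":
            for a, c in ((u, v), (v, u)):
                if c in c_candidates(slice_, a):
                    eligible.append(DiscoveryCase(a=a, gold=c, cutoff_year=cutoff))
        else:
            def leg_weight(b: str) -> int:
                s1 = slice_.edge_counts[tuple(sorted((u, b)))][0]
                s2 = slice_.edge_counts[tuple(sorted((v, b)))][0]
                return min(s1, s2)

            gold = max(sorted(bs), key=leg_weight)
            eligible.append(DiscoveryCase(a=u, c=v, gold=gold, cutoff_year=cutoff))
    if k == 0:
        return []
    if len(eligible) <= k:
        if len(eligible) < k:
            logger.warning("only %d eligible cases (requested %d)", len(eligible), k)
        return eligible
    idx = rng.choice(len(eligible), size=k, replace=False)
    return [eligible[i] for i in sorted(idx)]


PRESETS: dict[str, SyntheticConfig] = {
    "tiny": SyntheticConfig(
        n_nodes=40, n_communities=4, p_inter=0.15, base_closure_logit=-6.0,
        closure_strength=30.0, seed=0,
    ),
    "small": SyntheticConfig(
        n_nodes=120, n_communities=8, p_inter=0.25, base_closure_logit=-10.0,
        closure_strength=40.0, seed=0,
    ),
    "medium": SyntheticConfig(
        n_nodes=300, n_communities=15, p_inter=0.4, base_closure_logit=-13.0,
        closure_strength=50.0, seed=0,
    ),
}
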