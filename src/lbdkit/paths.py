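"""Node-vector combination and path score aggregation/accumulation.

Five node combination methods merge the vectors along an A-B-C path into one
model input: ``avg`` (elementwise mean), ``concat`` (ordered concatenation),
``hadamard`` (elementwise product), ``w1`` / ``w2`` (weighted-L1 |a-b| and
weighted-L2 (a-b)^2).  For paths of more than two nodes, w1/w2 are applied as
a left fold ``comb(comb(a, b), c)`` so that the output length stays ``d``.

Aggregators (min/avg/max) collapse the edge scores of one path into a path
score; accumulators (sum/max) collapse multiple path scores reaching the
same candidate into one candidate score.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

__all__ = [
    "COMBINERS",
    "AGGREGATORS",
    "ACCUMULATORS",
    "combine",
    "combined_dim",
    "aggregate",
    "accumulate",
]

COMBINERS = ("avg", "concat", "hadamard", "w1", "w2")
AGGREGATORS = ("min", "avg", "max")
ACCUMULATORS = ("sum", "max")


def combine(vectors: Sequence[np.ndarray], method: str) -> np.ndarray:
    """Merge >= 2 equal-length node vectors into one input vector."""
    if len(vectors) < 2:
        raise ValueError("combine requires at least two vectors")
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    d = arrs[0].shape[0]
    if any(a.ndim != 1 or a.shape[0] != d for a in arrs):
        raise ValueError("combine requires equal-length 1-d vectors")
    if method == "avg":
        return np.mean(arrs, axis=0)
    if method == "concat":
        return np.concatenate(arrs)
    if method == "hadamard":
        out = arrs[0].copy()
        for a in arrs[1:]:
            out *= a
        return out
    if method == "w1":
        out = arrs[0]
        for a in arrs[1:]:
            out = np.abs(out - a)
        return out
    if method == "w2":
        out = arrs[0]
        for a in arrs[1:]:
            out = (out - a) ** 2
        return out
    raise ValueError(f"unknown combiner {method!r}; choose from {COMBINERS}")


def combined_dim(embedding_dim: int, method: str, path_length: int) -> int:
    """Model input dimension for a given combiner and node count."""
    if method == "concat":
        return embedding_dim * path_length
    if method in COMBINERS:
        return embedding_dim
    raise ValueError(f"unknown combiner {method!r}")


def aggregate(edge_scores: Sequence[float], f: str) -> float:
    """Collapse the edge scores of one path into a single path score."""
    if len(edge_scores) == 0:
        raise ValueError("aggregate requires a non-empty score list")
    if f == "min":
        return float(min(edge_scores))
    if f == "avg":
        return float(sum(edge_scores) / len(edge_scores))
    if f == "max":
        return float(max(edge_scores))
    raise ValueError(f"unknown aggregator {f!r}; choose from {AGGREGATORS}")


def accumulate(path_scores: Sequence[float], f: str) -> float:
    """Collapse the scores of all paths reaching one candidate."""
    if len(path_scores) == 0:
        raise ValueError("accumulate requires a non-empty score list")
    if f == "sum":
        return float(sum(path_scores))
    if f == "max":
        return float(max(path_scores))
    raise ValueError(f"unknown accumulator {f!r}; choose from {ACCUMULATORS}")
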