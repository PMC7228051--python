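"""First/second-order proximity node embeddings trained by edge sampling.

Embeddings are optimised with negative sampling over weighted edges drawn
proportionally to their weight (alias method).  First order maximises
``log s(u_i . u_j)`` for sampled edges; second order uses separate context
vectors and maximises ``log s(c_j . u_i)``.  Training both orders and
concatenating the halves yields the full node representation.  Edge weights
for the training slice are Jaccard scores of the aggregated counts.

Updates are applied in chunks with stale-within-chunk gradients (the
reference implementation is asynchronous SGD, so this matches its semantics
while staying deterministic for a fixed seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from lbdkit.graph import GraphSlice
from lbdkit.metrics import UndefinedScoreError, jaccard

__all__ = [
    "EmbeddingConfig",
    "EmbeddingTable",
    "AliasSampler",
    "edge_weights_jaccard",
    "train_line",
    "train_both_orders",
    "concat_orders",
    "save_embeddings",
    "load_embeddings",
    "first_order_loss_grad",
    "second_order_loss_grad",
]

_LR_FLOOR_FACTOR = 1e-4


@dataclass(frozen=True)
class EmbeddingConfig:
    dim_per_order: int = 64
    negative_samples: int = 5
    learning_rate: float = 0.025
    total_samples: int = 100_000
    seed: int = 0
    chunk_size: int = 1024
    grad_clip: float = 5.0  # per-row gradient norm cap; curbs oscillation on tiny graphs

    def __post_init__(self) -> None:
        if min(self.dim_per_order, self.negative_samples, self.total_samples) < 1:
            raise ValueError("embedding config fields must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class EmbeddingTable:
    """Mapping entity id -> real vector, backed by a dense matrix."""

    def __init__(self, ids, matrix: np.ndarray):
        self.ids = list(ids)
        self.matrix = np.asarray(matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match id count")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding table contains non-finite entries")
        self._index = {e: i for i, e in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate entity ids in embedding table")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, entity: str) -> bool:
        return entity in self._index

    def __getitem__(self, entity: str) -> np.ndarray:
        return self.matrix[self._index[entity]]

    def get(self, entity: str, default=None):
        i = self._index.get(entity)
        return default if i is None else self.matrix[i]


class AliasSampler:
    """O(1) sampling from a discrete distribution (Vose's alias method)."""

    def __init__(self, weights) -> None:
        w = np.asarray(weights, dtype=np.float64)
        if w.ndim != 1 or len(w) == 0:
            raise ValueError("weights must be a non-empty 1-d array")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        n = len(w)
        prob = np.zeros(n)
        alias = np.zeros(n, dtype=np.int64)
        scaled = w * (n / w.sum())
        small = [i for i in range(n) if scaled[i] < 1.0]
        large = [i for i in range(n) if scaled[i] >= 1.0]
        while small and large:
            s, l = small.pop(), large.pop()
            prob[s] = scaled[s]
            alias[s] = l
            scaled[l] -= 1.0 - scaled[s]
            (small if scaled[l] < 1.0 else large).append(l)
        for i in large + small:
            prob[i] = 1.0
        self._prob, self._alias, self._n = prob, alias, n

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        idx = rng.integers(0, self._n, size=size)
        accept = rng.random(size=np.shape(idx)) < self._prob[idx]
        return np.where(accept, idx, self._alias[idx])


def edge_weights_jaccard(slice_: GraphSlice) -> list[tuple[str, str, float]]:
    """Jaccard-weighted edge list of a training slice."""
    out = []
    for u, v in slice_.edges():
        try:
            w = jaccard(slice_.contingency(u, v))
        except UndefinedScoreError:
            w = 0.0
        out.append((u, v, w))
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def first_order_loss_grad(u_i, u_j, negs):
    """Per-sample first-order negative-sampling loss and analytic gradients.

    loss = -log s(u_i.u_j) - sum_k log s(-u_i.u_k)
    Returns (loss, grad_u_i, grad_u_j, grad_negs).
    """
    u_i = np.asarray(u_i, dtype=np.float64)
    u_j = np.asarray(u_j, dtype=np.float64)
    negs = np.asarray(negs, dtype=np.float64)
    pos_dot = u_i @ u_j
    neg_dots = negs @ u_i
    loss = -_log_sigmoid(np.array(pos_dot)) - _log_sigmoid(-neg_dots).sum()
    s_pos = _sigmoid(np.array(pos_dot))
    s_negs = _sigmoid(neg_dots)
    grad_i = -(1.0 - s_pos) * u_j + s_negs @ negs
    grad_j = -(1.0 - s_pos) * u_i
    grad_negs = s_negs[:, None] * u_i[None, :]
    return float(loss), grad_i, grad_j, grad_negs


def second_order_loss_grad(u_i, c_j, c_negs):
    """Second-order loss: identical form with context vectors as targets."""
    return first_order_loss_grad(u_i, c_j, c_negs)


def train_line(
    edges: list[tuple[str, str, float]],
    order: str,
    config: EmbeddingConfig,
    nodes=None,
) -> EmbeddingTable:
    """Train one proximity order and return the half-size table.

    ``nodes`` may supply extra ids (e.g. isolated nodes); they keep their
    random initial vectors.  Undirected edges are oriented uniformly at
    random per sample.
    """
    if order not in ("first", "second"):
        raise ValueError("order must be 'first' or 'second'")
    if not edges:
        raise ValueError("cannot train embeddings on an empty edge list")
    weights = np.array([w for _, _, w in edges], dtype=np.float64)
    if weights.sum() <= 0:
        raise ValueError("degenerate input: all edge weights are zero")

    ids: list[str] = sorted(
        set(nodes or []) | {u for u, _, _ in edges} | {v for _, v, _ in edges}
    )
    index = {e: i for i, e in enumerate(ids)}
    n, d = len(ids), config.dim_per_order

    rng = np.random.default_rng(config.seed)
    # Roughly unit-norm init so dot products carry signal at desk-scale
    # sample budgets (the reference implementation relies on billions of
    # samples to grow vectors from a near-zero init).
    emb = rng.normal(0.0, 1.0 / np.sqrt(d), size=(n, d))
    ctx = rng.normal(0.0, 1.0 / np.sqrt(d), size=(n, d)) if order == "second" else emb

    src = np.array([index[u] for u, _, _ in edges], dtype=np.int64)
    dst = np.array([index[v] for _, v, _ in edges], dtype=np.int64)
    edge_sampler = AliasSampler(weights)

    # Negative nodes drawn proportional to (weighted degree)^0.75.
    degree = np.zeros(n)
    np.add.at(degree, src, weights)
    np.add.at(degree, dst, weights)
    node_weights = np.zeros_like(degree)
    np.power(degree, 0.75, out=node_weights, where=degree > 0)
    node_sampler = AliasSampler(node_weights)

    lr0 = config.learning_rate
    k = config.negative_samples
    total = config.total_samples
    # Stale-within-chunk gradients are only harmless if an edge repeats a
    # handful of times per chunk, so cap the chunk near the edge count.
    chunk = max(32, min(config.chunk_size, len(edges)))
    done = 0
    while done < total:
        m = min(chunk, total - done)
        lr = max(lr0 * (1.0 - done / total), lr0 * _LR_FLOOR_FACTOR)
        eidx = edge_sampler.draw(rng, m)
        i, j = src[eidx].copy(), dst[eidx].copy()
        flip = rng.random(m) < 0.5
        i[flip], j[flip] = j[flip], i[flip]
        negs = node_sampler.draw(rng, (m, k))

        u_i = emb[i]
        tgt = ctx
        t_j = tgt[j]
        t_n = tgt[negs]

        s_pos = _sigmoid(np.einsum("md,md->m", u_i, t_j))
        s_neg = _sigmoid(np.einsum("md,mkd->mk", u_i, t_n))

        grad_i = (1.0 - s_pos)[:, None] * t_j - np.einsum("mk,mkd->md", s_neg, t_n)
        grad_j = (1.0 - s_pos)[:, None] * u_i
        grad_n = (-s_neg[..., None] * u_i[:, None, :]).reshape(-1, d)

        clip = config.grad_clip
        for g in (grad_i, grad_j, grad_n):
            norms = np.linalg.norm(g, axis=1)
            over = norms > clip
            if np.any(over):
                g[over] *= (clip / norms[over])[:, None]

        np.add.at(emb, i, lr * grad_i)
        np.add.at(tgt, j, lr * grad_j)
        np.add.at(tgt, negs.reshape(-1), lr * grad_n)
        done += m

    if not np.all(np.isfinite(emb)):
        raise FloatingPointError("embedding training diverged to non-finite values")
    return EmbeddingTable(ids, emb.copy())


def train_both_orders(
    edges, config: EmbeddingConfig, nodes=None
) -> EmbeddingTable:
    """Train first and second order halves and concatenate them."""
    first = train_line(edges, "first", config, nodes=nodes)
    second = train_line(edges, "second", replace(config, seed=config.seed + 1), nodes=nodes)
    return concat_orders(first, second)


def concat_orders(first: EmbeddingTable, second: EmbeddingTable) -> EmbeddingTable:
    """Concatenate the first-order and second-order halves, node by node."""
    if set(first.ids) != set(second.ids):
        raise ValueError("first/second order tables cover different node sets")
    ids = list(first.ids)
    sec = np.stack([second[e] for e in ids])
    return EmbeddingTable(ids, np.concatenate([first.matrix, sec], axis=1))


def save_embeddings(table: EmbeddingTable, path) -> None:
    """Write the plain-text vector format: header ``count dim`` then rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dim}\n")
        for e in table.ids:
            vec = " ".join(format(x, ".8g") for x in table[e])
            fh.write(f"{e} {vec}\n" if vec else f"{e}\n")


def load_embeddings(path) -> EmbeddingTable:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed embedding header")
        n, d = int(header[0]), int(header[1])
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {d + 1} fields, found {len(parts)}"
                )
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(ids) != n:
        raise ValueError(f"{path}: header announced {n} rows, found {len(ids)}")
    matrix = np.array(rows, dtype=np.float64).reshape(len(ids), d)
    return EmbeddingTable(ids, matrix)
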