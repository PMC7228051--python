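"""Neural link/path scorers: an MLP classifier and a CNN path-stack regressor.

The MLP (used by the CD-1, CD-2 and OD-1 approaches) has a single hidden
ReLU layer feeding a two-unit softplus output.  The softplus activations are
normalised to a probability simplex for the cross-entropy loss; the ranking
score of an input is the positive-unit softplus activation itself, which
keeps scores positive and unbounded.

The CNN (OD-2) consumes a fixed-height stack of combined path vectors:
batch-normalised convolution sliding only along the stack axis (the kernel
always spans the full vector width), ReLU, global max pooling over the stack
axis, a fully connected ReLU layer, and a single softplus output trained
pointwise with mean squared error against Jaccard ratings of the A-C link.

Both models are implemented directly on NumPy with an Adam optimiser, with
analytic gradients (verified against central differences in the test suite).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np

from lbdkit.embeddings import EmbeddingTable
from lbdkit.graph import GraphSlice
from lbdkit.metrics import UndefinedScoreError, jaccard
from lbdkit.paths import combine, combined_dim

logger = logging.getLogger(__name__)

__all__ = [
    "MLPScorerConfig",
    "CNNScorerConfig",
    "TrainConfig",
    "TrainingExample",
    "MLPScorer",
    "CNNScorer",
    "AdamOptimizer",
    "pack_windows",
    "build_link_examples",
    "build_path_examples",
    "build_stack_examples",
    "train_mlp",
    "train_cnn",
    "score",
]


@dataclass(frozen=True)
class MLPScorerConfig:
    input_dim: int
    hidden_units: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.hidden_units < 1:
            raise ValueError("MLP dims must be positive")


@dataclass(frozen=True)
class CNNScorerConfig:
    input_width: int
    window_height: int = 50
    conv_height: int = 7
    conv_filters: int = 128
    fc_units: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.input_width,
            self.window_height,
            self.conv_height,
            self.conv_filters,
            self.fc_units,
        ) < 1:
            raise ValueError("CNN dims must be positive")
        if self.conv_height > self.window_height:
            raise ValueError(
                f"conv_height {self.conv_height} exceeds window_height "
                f"{self.window_height}"
            )


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 100
    train_set_size: int = 200_000
    epochs: int = 150
    learning_rate: float | None = None  # default 1e-4 for MLP, 1e-5 for CNN
    eval_interval_epochs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.train_set_size, self.epochs) < 1:
            raise ValueError("train config fields must be positive")
        if self.eval_interval_epochs < 1:
            raise ValueError("eval_interval_epochs must be positive")


@dataclass
class TrainingExample:
    """One supervised example: a classification label or a regression rating."""

    features: np.ndarray
    label: int | None = None
    rating: float | None = None

    def __post_init__(self) -> None:
        if (self.label is None) == (self.rating is None):
            raise ValueError("exactly one of label/rating must be set")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.rating is not None and not 0.0 <= self.rating <= 1.0:
            raise ValueError("rating must lie in [0, 1]")


# ---------------------------------------------------------------------------
# numerics
# ---------------------------------------------------------------------------


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class AdamOptimizer:
    """Adaptive-moment SGD over a list of parameter arrays (updated in place)."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------


class MLPScorer:
    """input -> hidden(ReLU) -> two softplus units; score = positive unit."""

    def __init__(self, config: MLPScorerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, h = config.input_dim, config.hidden_units
        self.W1 = rng.normal(0.0, math.sqrt(2.0 / d), size=(d, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.normal(0.0, math.sqrt(2.0 / h), size=(h, 2))
        self.b2 = np.zeros(2)

    @property
    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def _forward(self, x: np.ndarray):
        pre_h = x @ self.W1 + self.b1
        h = np.maximum(pre_h, 0.0)
        logits = h @ self.W2 + self.b2
        z = _softplus(logits)
        return pre_h, h, logits, z

    def score(self, features: np.ndarray) -> np.ndarray | float:
        """Positive-class softplus activation; >= 0, deterministic."""
        x = np.asarray(features, dtype=np.float64)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"feature dim {x.shape[1]} != input_dim {self.config.input_dim}"
            )
        _, _, _, z = self._forward(x)
        scores = z[:, 1]
        return float(scores[0]) if single else scores

    def loss_and_grads(self, x: np.ndarray, labels: np.ndarray):
        """Mean cross-entropy of the normalised softplus outputs + gradients."""
        x = np.asarray(x, dtype=np.float64)
        labels = np.asarray(labels, dtype=np.int64)
        b = x.shape[0]
        pre_h, h, logits, z = self._forward(x)
        total = z.sum(axis=1)
        p_true = z[np.arange(b), labels] / total
        loss = float(-np.mean(np.log(p_true)))

        # dL/dz_c = (1/S - 1{c=y}/z_y) / b ; dz/dlogit = sigmoid(logit)
        dz = np.full_like(z, 1.0)
        dz /= total[:, None]
        dz[np.arange(b), labels] -= 1.0 / z[np.arange(b), labels]
        dz /= b
        dlogits = dz * _sigmoid(logits)

        gW2 = h.T @ dlogits
        gb2 = dlogits.sum(axis=0)
        dh = dlogits @ self.W2.T
        dh[pre_h <= 0.0] = 0.0
        gW1 = x.T @ dh
        gb1 = dh.sum(axis=0)
        return loss, [gW1, gb1, gW2, gb2]

    def copy(self) -> "MLPScorer":
        clone = MLPScorer.__new__(MLPScorer)
        clone.config = self.config
        clone.W1, clone.b1 = self.W1.copy(), self.b1.copy()
        clone.W2, clone.b2 = self.W2.copy(), self.b2.copy()
        return clone

    def state_dict(self) -> dict:
        return {
            "kind": "mlp",
            "config": {
                "input_dim": self.config.input_dim,
                "hidden_units": self.config.hidden_units,
                "seed": self.config.seed,
            },
            "params": [p.tolist() for p in self.params],
        }

    @classmethod
    def from_state(cls, state: dict) -> "MLPScorer":
        scorer = cls(MLPScorerConfig(**state["config"]))
        for p, saved in zip(scorer.params, state["params"]):
            p[...] = np.asarray(saved, dtype=np.float64)
        return scorer


# ---------------------------------------------------------------------------
# CNN
# ---------------------------------------------------------------------------


class CNNScorer:
    """Path-stack CNN regressor; see module docstring for the layer stack."""

    BN_MOMENTUM = 0.9
    BN_EPS = 1e-5

    def __init__(self, config: CNNScorerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        kh, w, f = config.conv_height, config.input_width, config.conv_filters
        fc = config.fc_units
        self.Wc = rng.normal(0.0, math.sqrt(2.0 / (kh * w)), size=(kh * w, f))
        self.bc = np.zeros(f)
        self.gamma = np.ones(f)
        self.beta = np.zeros(f)
        self.Wf = rng.normal(0.0, math.sqrt(2.0 / f), size=(f, fc))
        self.bf = np.zeros(fc)
        self.Wo = rng.normal(0.0, math.sqrt(2.0 / fc), size=(fc, 1))
        self.bo = np.zeros(1)
        self.running_mean = np.zeros(f)
        self.running_var = np.ones(f)

    @property
    def params(self):
        return [
            self.Wc, self.bc, self.gamma, self.beta,
            self.Wf, self.bf, self.Wo, self.bo,
        ]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # x: (B, H, W) -> (B, P, kh*W) with P = H - kh + 1
        kh = self.config.conv_height
        cols = np.lib.stride_tricks.sliding_window_view(x, kh, axis=1)
        # cols: (B, P, W, kh) -> (B, P, kh, W)
        cols = cols.transpose(0, 1, 3, 2)
        b, p = cols.shape[0], cols.shape[1]
        return cols.reshape(b, p, kh * self.config.input_width)

    def _forward(self, x: np.ndarray, training: bool):
        cols = self._im2col(x)                       # (B, P, khW)
        conv = cols @ self.Wc + self.bc              # (B, P, F)
        if training:
            mean = conv.mean(axis=(0, 1))
            var = conv.var(axis=(0, 1))
            mom = self.BN_MOMENTUM
            self.running_mean = mom * self.running_mean + (1 - mom) * mean
            self.running_var = mom * self.running_var + (1 - mom) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.BN_EPS)
        xhat = (conv - mean) * inv_std
        bn = self.gamma * xhat + self.beta
        act = np.maximum(bn, 0.0)                    # ReLU
        pool_idx = act.argmax(axis=1)                # (B, F) over stack axis
        b_idx = np.arange(act.shape[0])[:, None]
        pooled = act[b_idx, pool_idx, np.arange(act.shape[2])]  # (B, F)
        pre_fc = pooled @ self.Wf + self.bf
        fc = np.maximum(pre_fc, 0.0)
        out = _softplus(fc @ self.Wo + self.bo)[:, 0]
        cache = (cols, conv, mean, var, inv_std, xhat, bn, act, pool_idx,
                 pooled, pre_fc, fc)
        return out, cache

    def score(self, window: np.ndarray) -> np.ndarray | float:
        """Softplus output for a (H, W) window or a (B, H, W) batch."""
        x = np.asarray(window, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[None, :, :]
        h, w = self.config.window_height, self.config.input_width
        if x.shape[1:] != (h, w):
            raise ValueError(f"window shape {x.shape[1:]} != ({h}, {w})")
        out, _ = self._forward(x, training=False)
        return float(out[0]) if single else out

    def loss_and_grads(self, x: np.ndarray, ratings: np.ndarray):
        """Mean squared error against ratings plus analytic gradients."""
        x = np.asarray(x, dtype=np.float64)
        ratings = np.asarray(ratings, dtype=np.float64)
        b = x.shape[0]
        out, cache = self._forward(x, training=True)
        (cols, conv, mean, var, inv_std, xhat, bn, act, pool_idx, pooled,
         pre_fc, fc) = cache
        diff = out - ratings
        loss = float(np.mean(diff**2))

        dout = (2.0 / b) * diff                                   # (B,)
        final_logits = fc @ self.Wo + self.bo
        dlogit = dout * _sigmoid(final_logits[:, 0])              # softplus'
        gWo = fc.T @ dlogit[:, None]
        gbo = np.array([dlogit.sum()])
        dfc = dlogit[:, None] @ self.Wo.T                          # (B, fc)
        dfc[pre_fc <= 0.0] = 0.0
        gWf = pooled.T @ dfc
        gbf = dfc.sum(axis=0)
        dpooled = dfc @ self.Wf.T                                  # (B, F)

        dact = np.zeros_like(act)
        b_idx = np.arange(b)[:, None]
        f_idx = np.arange(act.shape[2])
        dact[b_idx, pool_idx, f_idx] = dpooled
        dbn = dact * (bn > 0.0)

        ggamma = (dbn * xhat).sum(axis=(0, 1))
        gbeta = dbn.sum(axis=(0, 1))
        dxhat = dbn * self.gamma
        # batchnorm backward over the (B, P) reduction axes
        n = float(dbn.shape[0] * dbn.shape[1])
        dconv = (inv_std / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 1))
            - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )
        gWc = np.einsum("bpk,bpf->kf", cols, dconv)
        gbc = dconv.sum(axis=(0, 1))
        return loss, [gWc, gbc, ggamma, gbeta, gWf, gbf, gWo, gbo]

    def copy(self) -> "CNNScorer":
        clone = CNNScorer.__new__(CNNScorer)
        clone.config = self.config
        for name in ("Wc", "bc", "gamma", "beta", "Wf", "bf", "Wo", "bo",
                     "running_mean", "running_var"):
            setattr(clone, name, getattr(self, name).copy())
        return clone

    def state_dict(self) -> dict:
        return {
            "kind": "cnn",
            "config": {
                "input_width": self.config.input_width,
                "window_height": self.config.window_height,
                "conv_height": self.config.conv_height,
                "conv_filters": self.config.conv_filters,
                "fc_units": self.config.fc_units,
                "seed": self.config.seed,
            },
            "params": [p.tolist() for p in self.params],
            "running_mean": self.running_mean.tolist(),
            "running_var": self.running_var.tolist(),
        }

    @classmethod
    def from_state(cls, state: dict) -> "CNNScorer":
        scorer = cls(CNNScorerConfig(**state["config"]))
        for p, saved in zip(scorer.params, state["params"]):
            p[...] = np.asarray(saved, dtype=np.float64)
        scorer.running_mean = np.asarray(state["running_mean"], dtype=np.float64)
        scorer.running_var = np.asarray(state["running_var"], dtype=np.float64)
        return scorer


def save_scorer(scorer, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(scorer.state_dict(), fh)


def load_scorer(path):
    with open(path, "r", encoding="utf-8") as fh:
        state = json.load(fh)
    cls = {"mlp": MLPScorer, "cnn": CNNScorer}[state["kind"]]
    return cls.from_state(state)


def score(scorer, features):
    """Apply a trained scorer to features; nonnegative and deterministic."""
    return scorer.score(features)


# ---------------------------------------------------------------------------
# training-set construction
# ---------------------------------------------------------------------------


def _require_embedding(emb: EmbeddingTable, node: str) -> np.ndarray:
    vec = emb.get(node)
    if vec is None:
        raise KeyError(f"no embedding for node {node!r}")
    return vec


def pack_windows(path_vectors, height: int) -> np.ndarray:
    """Chunk path vectors into height-row windows, zero-pad the last, and sum.

    Returns one (height, d) array: the elementwise sum, row by row, of all
    consecutive windows.  E.g. 175 vectors at height 50 sum 3 full windows
    plus a final window holding 25 vectors and 25 zero rows.
    """
    if len(path_vectors) == 0:
        raise ValueError("pack_windows requires at least one path vector")
    if height < 1:
        raise ValueError("window height must be positive")
    stack = np.asarray(path_vectors, dtype=np.float64)
    if stack.ndim != 2:
        raise ValueError("path vectors must be equal-length 1-d vectors")
    p, d = stack.shape
    n_windows = -(-p // height)
    padded = np.zeros((n_windows * height, d))
    padded[:p] = stack
    return padded.reshape(n_windows, height, d).sum(axis=0)


def build_link_examples(
    slice_: GraphSlice,
    emb: EmbeddingTable,
    combiner: str,
    size: int,
    seed: int,
) -> list[TrainingExample]:
    """Balanced link classification set: existing edges vs sampled non-edges."""
    rng = np.random.default_rng(seed)
    nodes = [n for n in slice_.nodes if n in emb]
    edges = [e for e in slice_.edges() if e[0] in emb and e[1] in emb]
    if not edges or len(nodes) < 3:
        raise ValueError("graph too small to build link examples")
    n_pos = size // 2
    n_neg = size - n_pos

    examples: list[TrainingExample] = []
    pos_idx = rng.integers(0, len(edges), size=n_pos)
    for i in pos_idx:
        u, v = edges[i]
        feats = combine([_require_embedding(emb, u), _require_embedding(emb, v)], combiner)
        examples.append(TrainingExample(features=feats, label=1))

    negatives: list[tuple[str, str]] = []
    attempts = 0
    max_attempts = 200 * n_neg + 1000
    while len(negatives) < n_neg:
        if attempts > max_attempts:
            raise ValueError("graph too dense to sample non-edge negatives")
        attempts += 1
        u, v = (nodes[k] for k in rng.integers(0, len(nodes), size=2))
        if u == v or slice_.has_edge(u, v):
            continue
        negatives.append((u, v))
    for u, v in negatives:
        feats = combine([_require_embedding(emb, u), _require_embedding(emb, v)], combiner)
        examples.append(TrainingExample(features=feats, label=0))
    return examples


def _wedges(slice_: GraphSlice):
    """All (a, b, c) with a < c, b adjacent to both; split by a-c edge."""
    closed, open_ = [], []
    for b in slice_.nodes:
        nbrs = sorted(slice_.neighbors(b))
        for i, a in enumerate(nbrs):
            for c in nbrs[i + 1:]:
                (closed if slice_.has_edge(a, c) else open_).append((a, b, c))
    return closed, open_


def build_path_examples(
    slice_: GraphSlice,
    emb: EmbeddingTable,
    combiner: str,
    size: int,
    seed: int,
) -> list[TrainingExample]:
    """Balanced whole-path classification set: triangles vs open wedges."""
    rng = np.random.default_rng(seed)
    closed, open_ = _wedges(slice_)
    closed = [t for t in closed if all(n in emb for n in t)]
    open_ = [t for t in open_ if all(n in emb for n in t)]
    if not closed or not open_:
        raise ValueError("insufficient triangles/open wedges for path examples")
    n_pos = size // 2
    n_neg = size - n_pos
    examples: list[TrainingExample] = []
    for pool, n, label in ((closed, n_pos, 1), (open_, n_neg, 0)):
        idx = rng.integers(0, len(pool), size=n)
        for i in idx:
            a, b, c = pool[i]
            feats = combine([emb[a], emb[b], emb[c]], combiner)
            examples.append(TrainingExample(features=feats, label=label))
    return examples


def path_window(
    slice_: GraphSlice,
    emb: EmbeddingTable,
    combiner: str,
    window_height: int,
    a: str,
    c: str,
) -> np.ndarray | None:
    """Packed window over all a-B-c paths (B in deterministic sorted order)."""
    bs = sorted((slice_.neighbors(a) & slice_.neighbors(c)) - {a, c})
    bs = [b for b in bs if b in emb]
    if not bs or a not in emb or c not in emb:
        return None
    vecs = [combine([emb[a], emb[b], emb[c]], combiner) for b in bs]
    return pack_windows(vecs, window_height)


def build_stack_examples(
    slice_: GraphSlice,
    emb: EmbeddingTable,
    combiner: str,
    window_height: int,
    size: int,
    seed: int,
    normalize_ratings: bool = True,
) -> list[TrainingExample]:
    """Regression set for the CNN: packed path windows rated by A-C Jaccard.

    Sampled pairs always have at least one connecting path.  Pairs whose A-C
    edge exists are rated with its Jaccard score; pairs without the edge are
    rated 0.  With ``normalize_ratings`` the ratings are divided by their
    maximum so the top rating is 1.0: raw Jaccard values on small corpora sit
    near the softplus floor and stall the squared-error gradient, and the
    rescaling is monotone so the learned ranking is unaffected.
    """
    rng = np.random.default_rng(seed)
    closed, open_ = _wedges(slice_)
    linked = sorted({(a, c) for a, _, c in closed})
    unlinked = sorted({(a, c) for a, _, c in open_})
    linked = [p for p in linked if p[0] in emb and p[1] in emb]
    unlinked = [p for p in unlinked if p[0] in emb and p[1] in emb]
    if not linked or not unlinked:
        raise ValueError("insufficient linked/unlinked wedge pairs for stack examples")
    n_pos = size // 2
    n_neg = size - n_pos
    examples: list[TrainingExample] = []
    for pool, n, has_edge in ((linked, n_pos, True), (unlinked, n_neg, False)):
        idx = rng.integers(0, len(pool), size=n)
        for i in idx:
            a, c = pool[i]
            window = path_window(slice_, emb, combiner, window_height, a, c)
            if window is None:
                logger.warning("pair (%s, %s) has no scorable path; skipped", a, c)
                continue
            if has_edge:
                try:
                    rating = jaccard(slice_.contingency(a, c))
                except UndefinedScoreError:
                    rating = 0.0
            else:
                rating = 0.0
            examples.append(TrainingExample(features=window, rating=rating))
    if normalize_ratings:
        top = max(ex.rating for ex in examples)
        if top > 0:
            examples = [
                TrainingExample(features=ex.features, rating=ex.rating / top)
                for ex in examples
            ]
    return examples


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------


def _run_training(model, xs, ys, loss_fn, train_config, default_lr, checkpoint_hook):
    lr = train_config.learning_rate if train_config.learning_rate is not None else default_lr
    opt = AdamOptimizer(model.params, lr=lr)
    rng = np.random.default_rng(train_config.seed)
    n = xs.shape[0]
    bs = min(train_config.batch_size, n)
    for epoch in range(1, train_config.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            sel = order[start:start + bs]
            _, grads = loss_fn(xs[sel], ys[sel])
            opt.step(grads)
        if checkpoint_hook is not None and epoch % train_config.eval_interval_epochs == 0:
            checkpoint_hook(epoch, model.copy())
    return model


def train_mlp(
    examples: list[TrainingExample],
    mlp_config: MLPScorerConfig,
    train_config: TrainConfig,
    checkpoint_hook=None,
) -> MLPScorer:
    """Train the MLP classifier; emits a copy at every eval interval."""
    if any(ex.label is None for ex in examples):
        raise ValueError("train_mlp requires classification examples")
    xs = np.stack([np.asarray(ex.features, dtype=np.float64) for ex in examples])
    if xs.shape[1] != mlp_config.input_dim:
        raise ValueError(
            f"example dim {xs.shape[1]} != configured input_dim {mlp_config.input_dim}"
        )
    ys = np.array([ex.label for ex in examples], dtype=np.int64)
    model = MLPScorer(mlp_config)
    return _run_training(
        model, xs, ys, model.loss_and_grads, train_config, 1e-4, checkpoint_hook
    )


def train_cnn(
    examples: list[TrainingExample],
    cnn_config: CNNScorerConfig,
    train_config: TrainConfig,
    checkpoint_hook=None,
) -> CNNScorer:
    """Train the CNN regressor; emits a copy at every eval interval."""
    if any(ex.rating is None for ex in examples):
        raise ValueError("train_cnn requires regression (rating) examples")
    xs = np.stack([np.asarray(ex.features, dtype=np.float64) for ex in examples])
    expected = (cnn_config.window_height, cnn_config.input_width)
    if xs.shape[1:] != expected:
        raise ValueError(f"example window shape {xs.shape[1:]} != {expected}")
    ys = np.array([ex.rating for ex in examples], dtype=np.float64)
    model = CNNScorer(cnn_config)
    return _run_training(
        model, xs, ys, model.loss_and_grads, train_config, 1e-5, checkpoint_hook
    )
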