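"""Attention fusion of the two routes and the pair-scoring decoder.

For each node the topology view z_topo and similarity view z_sim are stacked
into Z in R^{2 x d}; an additive-attention gate

    w = Softmax( W2 tanh(W1 Z) )

yields per-view weights (w1, w2) summing to 1, and the fused embedding is
z = Dropout(w1 z_topo + w2 z_sim). A drug-disease pair (i, j) is scored by a
three-layer MLP on the ordered concatenation [z_i ; z_j] followed by a
sigmoid; training minimizes mean binary cross-entropy in logit space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "AttentionParams",
    "PairScorerParams",
    "attention_weights",
    "fuse_views",
    "score_pair",
    "pair_logits",
    "bce_loss",
]


@dataclass
class AttentionParams:
    """Additive attention: W1 maps a view vector to the attention hidden
    space, W2 reduces it to one logit per view."""

    W1: object   # (d, attn_hidden)
    W2: object   # (attn_hidden, 1)
    attn_dropout_rate: float = 0.1

    @classmethod
    def init(cls, d: int, attn_hidden: int, rng: np.random.Generator,
             attn_dropout_rate: float = 0.1) -> "AttentionParams":
        return cls(
            nn.parameter((d, attn_hidden), rng=rng),
            nn.parameter((attn_hidden, 1), rng=rng),
            attn_dropout_rate,
        )

    def parameters(self) -> list:
        return [self.W1, self.W2]


@dataclass
class PairScorerParams:
    """Three-layer MLP decoder over concatenated pair embeddings."""

    weights: list    # affine weights, last maps to 1 logit
    biases: list

    @classmethod
    def init(cls, d: int, hidden: tuple[int, ...], rng: np.random.Generator) -> "PairScorerParams":
        dims = [2 * d, *hidden, 1]
        ws = [nn.parameter((a, b), rng=rng) for a, b in zip(dims[:-1], dims[1:])]
        bs = [nn.parameter(np.zeros(b)) for b in dims[1:]]
        return cls(ws, bs)

    def parameters(self) -> list:
        return [*self.weights, *self.biases]

    def state_hash(self) -> int:
        """Hash of all parameter values; used to assert frozen-decoder contracts."""
        import hashlib

        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.data).tobytes())
        return int.from_bytes(h.digest()[:8], "big")


def attention_weights(
    z_topo,
    z_sim,
    params: AttentionParams,
    rng: np.random.Generator | None = None,
    training: bool = False,
):
    """Per-node view weights (columns sum to 1); accepts (n, d) matrices.

    Attention dropout, when active, perturbs the per-view logits before the
    softmax, so evaluation-mode weights are deterministic.
    """
    z_topo, z_sim = _atleast2d(z_topo), _atleast2d(z_sim)
    if z_topo.shape != z_sim.shape:
        raise ValueError(f"view shapes differ: {z_topo.shape} vs {z_sim.shape}")
    logits = nn.concat(
        [
            nn.matmul(nn.tanh(nn.matmul(z_topo, params.W1)), params.W2),
            nn.matmul(nn.tanh(nn.matmul(z_sim, params.W1)), params.W2),
        ],
        axis=1,
    )  # (n, 2)
    logits = nn.dropout(logits, params.attn_dropout_rate, rng, training)
    return nn.softmax(logits, axis=1)


def fuse_views(
    z_topo,
    z_sim,
    w,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    training: bool = False,
):
    """z = Dropout(w1 * z_topo + w2 * z_sim); ``w`` is (n, 2) or length-2."""
    z_topo, z_sim = _atleast2d(z_topo), _atleast2d(z_sim)
    w1 = w[:, 0:1] if getattr(w, "ndim", 1) == 2 else w[0]
    w2 = w[:, 1:2] if getattr(w, "ndim", 1) == 2 else w[1]
    z = z_topo * w1 + z_sim * w2
    return nn.dropout(z, dropout_rate, rng, training)


def pair_logits(z_drugs, z_diseases, pairs: np.ndarray, params: PairScorerParams):
    """MLP logits for (drug index, disease index) pairs, pre-sigmoid."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    h = nn.concat(
        [nn.take_rows(z_drugs, pairs[:, 0]), nn.take_rows(z_diseases, pairs[:, 1])],
        axis=1,
    )
    n_layers = len(params.weights)
    for li, (w, b) in enumerate(zip(params.weights, params.biases)):
        h = nn.matmul(h, w) + b
        if li < n_layers - 1:
            h = nn.relu(h)
    return h.reshape(-1)


def score_pair(z_i, z_j, params: PairScorerParams):
    """Probability score in (0, 1) for one ordered (drug, disease) pair."""
    z_i = np.asarray(z_i.data if isinstance(z_i, nn.Tensor) else z_i, dtype=np.float64)
    z_j = np.asarray(z_j.data if isinstance(z_j, nn.Tensor) else z_j, dtype=np.float64)
    logit = pair_logits(z_i[None, :], z_j[None, :], np.array([[0, 0]]), _detached(params))
    return float(nn.sigmoid(logit if isinstance(logit, np.ndarray) else logit.data)[0])


def _detached(params: PairScorerParams) -> PairScorerParams:
    return PairScorerParams(
        [w.data if isinstance(w, nn.Tensor) else w for w in params.weights],
        [b.data if isinstance(b, nn.Tensor) else b for b in params.biases],
    )


def bce_loss(scores, labels):
    """Mean binary cross-entropy on probability scores (reporting form).

    Training uses :func:`dreamgnn.nn.bce_with_logits` on raw logits; this
    probability-space form exists for reporting and closed-form checks and
    clamps scores away from {0, 1}.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("bce_loss requires a non-empty batch")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    eps = 1e-12
    s = np.clip(scores, eps, 1 - eps)
    return float(-np.mean(labels * np.log(s) + (1 - labels) * np.log(1 - s)))


def _atleast2d(x):
    if isinstance(x, nn.Tensor):
        return x if x.ndim == 2 else x.reshape(1, -1)
    return np.atleast_2d(np.asarray(x, dtype=np.float64))
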