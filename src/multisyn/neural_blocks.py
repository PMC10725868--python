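"""Reusable network mechanisms: multi-head attention with residual
concatenation, the two-layer cross-stitch subnetwork, and the generic
rectified fully connected stack.

Attention operates on flat feature vectors by reshaping a length-d vector
into ``d / token_dim`` tokens of ``token_dim`` features (the softmax is
degenerate on a single token, so a token layout is required). Each head
projects tokens to width ``token_dim / h`` with rectified dense layers for
query, key and value; attention weights are ``softmax(I_q @ I_k^T)`` over key
tokens (no 1/sqrt(d) temperature by default, a flag enables it); head
outputs are concatenated so the attended vector matches the input size, and
the final output concatenates the attended vector with the raw query input —
output length is exactly twice the query length.

The cross-stitch unit mixes two task vectors with a learned 2x2 matrix
applied at every feature position; the subnetwork stacks
unit → per-task rectified dense → unit and concatenates each task's mixed
output with its original input.
"""

from __future__ import annotations

import numpy as np

from .autograd import Linear, Tensor, concat, dropout, relu, softmax

__all__ = [
    "FCSubnetwork",
    "AttentionBlock",
    "cross_stitch_unit",
    "CrossStitchSubnetwork",
]


class FCSubnetwork:
    """Stack of rectified dense layers with inter-layer dropout.

    Dropout (rate ``dropout_rate``) follows every layer except the last;
    it is a no-op outside training. L2 penalties on the weights
    (``reg_weight``) and on the layer activations (``reg_activity``) are
    collected during the forward pass and exposed via :meth:`penalty`.
    """

    def __init__(self, n_in: int, widths: list[int], rng: np.random.Generator,
                 dropout_rate: float = 0.2, reg_weight: float = 1e-4,
                 reg_activity: float = 1e-5):
        if any(w <= 0 for w in widths):
            raise ValueError("layer widths must be positive")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.layers: list[Linear] = []
        prev = n_in
        for w in widths:
            self.layers.append(Linear(prev, w, rng))
            prev = w
        self.n_out = prev
        self.dropout_rate = dropout_rate
        self.reg_weight = reg_weight
        self.reg_activity = reg_activity
        self._activity_penalty: Tensor | None = None

    def __call__(self, x: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        penalty = Tensor(0.0)
        for k, layer in enumerate(self.layers):
            x = relu(layer(x))
            if training and self.reg_activity > 0:
                penalty = penalty + self.reg_activity * x.square().mean()
            if training and k < len(self.layers) - 1 and self.dropout_rate > 0:
                if rng is None:
                    raise ValueError("training forward needs an rng for dropout")
                x = dropout(x, self.dropout_rate, rng)
        self._activity_penalty = penalty
        return x

    def penalty(self) -> Tensor:
        """Regularization terms from the most recent training forward."""
        p = self._activity_penalty if self._activity_penalty is not None else Tensor(0.0)
        if self.reg_weight > 0:
            for layer in self.layers:
                p = p + self.reg_weight * layer.W.square().sum()
        return p

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


class AttentionBlock:
    """Multi-head dot-product attention over token-reshaped feature vectors."""

    def __init__(self, d_query: int, d_kv: int, heads: int, rng: np.random.Generator,
                 token_dim: int = 16, share_qkv: bool = False, scaled: bool = False):
        if heads < 1:
            raise ValueError("head count must be >= 1")
        for name, d in (("query", d_query), ("key/value", d_kv)):
            if d % token_dim:
                raise ValueError(f"{name} width {d} not divisible by token_dim {token_dim}")
        if token_dim % heads:
            raise ValueError(f"token_dim {token_dim} not divisible by {heads} heads")
        self.heads = heads
        self.token_dim = token_dim
        self.d_query = d_query
        self.d_kv = d_kv
        self.n_q_tokens = d_query // token_dim
        self.n_kv_tokens = d_kv // token_dim
        self.head_dim = token_dim // heads
        self.scaled = scaled
        self.share_qkv = share_qkv
        self.proj: list[dict[str, Linear]] = []
        for _ in range(heads):
            q = Linear(token_dim, self.head_dim, rng)
            if share_qkv:
                self.proj.append({"q": q, "k": q, "v": q})
            else:
                self.proj.append({
                    "q": q,
                    "k": Linear(token_dim, self.head_dim, rng),
                    "v": Linear(token_dim, self.head_dim, rng),
                })
        self._last_weights: np.ndarray | None = None

    def __call__(self, query: Tensor, key: Tensor, value: Tensor) -> Tensor:
        """Attend and concatenate with the query input (output = 2x query)."""
        if key.shape != value.shape:
            raise ValueError("key and value must share shape (token count)")
        b = query.shape[0]
        q_tok = query.reshape(b, self.n_q_tokens, self.token_dim)
        k_tok = key.reshape(b, self.n_kv_tokens, self.token_dim)
        v_tok = value.reshape(b, self.n_kv_tokens, self.token_dim)
        outs = []
        weights = []
        for p in self.proj:
            iq = relu(p["q"](q_tok))
            ik = relu(p["k"](k_tok))
            iv = relu(p["v"](v_tok))
            logits = iq @ ik.swap_last2()
            if self.scaled:
                logits = (1.0 / np.sqrt(self.head_dim)) * logits
            s = softmax(logits, axis=-1)  # over key tokens, per query token
            weights.append(s.data)
            outs.append(s @ iv)
        self._last_weights = np.stack(weights, axis=1)  # (B, heads, n_q, n_kv)
        attended = concat(outs, axis=-1).reshape(b, self.d_query)
        return concat([attended, query], axis=-1)

    @property
    def last_weights(self) -> np.ndarray:
        """Attention weights of the most recent call, (B, heads, n_q, n_kv)."""
        if self._last_weights is None:
            raise RuntimeError("attention block has not been called yet")
        return self._last_weights

    def parameters(self) -> list[Tensor]:
        seen: list[Tensor] = []
        for p in self.proj:
            for key in ("q", "k", "v"):
                for t in p[key].parameters():
                    if all(t is not s for s in seen):
                        seen.append(t)
        return seen


def cross_stitch_unit(t1: Tensor, t2: Tensor, r: list[list[Tensor]]) -> tuple[Tensor, Tensor]:
    """Learned 2x2 linear mix of two task vectors, elementwise.

    ``r`` holds scalar tensors [[r11, r12], [r21, r22]]; every feature
    position is mixed with the same matrix.
    """
    if t1.shape != t2.shape:
        raise ValueError(f"task vector shapes differ: {t1.shape} vs {t2.shape}")
    out1 = r[0][0] * t1 + r[0][1] * t2
    out2 = r[1][0] * t1 + r[1][1] * t2
    return out1, out2


class CrossStitchSubnetwork:
    """unit → per-task rectified dense → unit, with residual concatenation.

    Both 2x2 mixing matrices start near identity (diagonal 0.9, off-diagonal
    0.1). Each task's final output concatenates its second-unit mix with the
    task's original input, so the output width is ``dense_width + n_in``.
    """

    def __init__(self, n_in: int, rng: np.random.Generator, dense_width: int | None = None):
        self.n_in = n_in
        self.dense_width = dense_width or n_in
        self.r1 = [[Tensor(0.9, requires_grad=True), Tensor(0.1, requires_grad=True)],
                   [Tensor(0.1, requires_grad=True), Tensor(0.9, requires_grad=True)]]
        self.r2 = [[Tensor(0.9, requires_grad=True), Tensor(0.1, requires_grad=True)],
                   [Tensor(0.1, requires_grad=True), Tensor(0.9, requires_grad=True)]]
        self.dense1 = Linear(n_in, self.dense_width, rng)
        self.dense2 = Linear(n_in, self.dense_width, rng)
        self.n_out = self.dense_width + n_in

    def __call__(self, t1: Tensor, t2: Tensor) -> tuple[Tensor, Tensor]:
        m1, m2 = cross_stitch_unit(t1, t2, self.r1)
        t11 = relu(self.dense1(m1))
        t22 = relu(self.dense2(m2))
        f1, f2 = cross_stitch_unit(t11, t22, self.r2)
        return concat([f1, t1], axis=-1), concat([f2, t2], axis=-1)

    def parameters(self) -> list[Tensor]:
        mix = [t for mat in (self.r1, self.r2) for row in mat for t in row]
        return mix + self.dense1.parameters() + self.dense2.parameters()
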