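"""NumPy primitives for the convolutional translation network.

Implements the forward and backward passes of the few layer types the
translator needs — 1-D convolutions (same / causal padding), dot-product
attention with encoder masking, and masked softmax cross-entropy — plus an
Adam optimizer.  Everything operates on float32 arrays shaped
(batch, time, channels); convolutions are evaluated as a sum of K shifted
batched matmuls so the heavy lifting stays inside BLAS.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1]))
    fan_out = int(shape[-1])
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


def one_hot(indices: np.ndarray, depth: int) -> np.ndarray:
    return np.eye(depth, dtype=F32)[indices]


# ---------------------------------------------------------------------------
# 1-D convolution


def conv1d_forward(
    x: np.ndarray, W: np.ndarray, b: np.ndarray, causal: bool,
    dilation: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """y[t] = b + sum_k x[t + (k - offset) * dilation] @ W[k].

    Causal convolutions only see positions <= t (left padding (K-1)*d);
    "same" convolutions are centred.  Returns (y, padded input) — the
    padded input is needed by the backward pass.
    """
    B, T, _ = x.shape
    K = W.shape[0]
    span = (K - 1) * dilation
    pad_left = span if causal else span // 2
    pad_right = span - pad_left
    xp = np.pad(x, ((0, 0), (pad_left, pad_right), (0, 0)))
    y = np.broadcast_to(b, (B, T, W.shape[2])).copy()
    for k in range(K):
        off = k * dilation
        y += xp[:, off : off + T] @ W[k]
    return y, xp


def conv1d_backward(
    dy: np.ndarray, xp: np.ndarray, W: np.ndarray, causal: bool,
    dilation: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dW, db) of conv1d_forward."""
    B, T, Cout = dy.shape
    K, Cin, _ = W.shape
    db = dy.sum(axis=(0, 1))
    dW = np.empty_like(W)
    dy_flat = dy.reshape(-1, Cout)
    dxp = np.zeros_like(xp)
    for k in range(K):
        off = k * dilation
        dW[k] = xp[:, off : off + T].reshape(-1, Cin).T @ dy_flat
        dxp[:, off : off + T] += dy @ W[k].T
    span = (K - 1) * dilation
    pad_left = span if causal else span // 2
    dx = dxp[:, pad_left : pad_left + T]
    return dx, dW, db


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0, dtype=F32)


# ---------------------------------------------------------------------------
# Attention


def diagonal_prior(T: int, width: float = 4.0) -> np.ndarray:
    """Additive location prior favouring near-monotonic alignments.

    Reactant and product SMILES of a single-site transformation are mostly
    copies of each other, so the true alignment hugs the diagonal; a soft
    Gaussian penalty on |i - j| lets attention start near the right answer
    while remaining free to move off-diagonal where the edit happens.
    """
    d = np.arange(T, dtype=F32)
    return -((d[:, None] - d[None, :]) / F32(width)) ** 2


def attention_forward(
    dec: np.ndarray,
    enc: np.ndarray,
    Wa: np.ndarray,
    enc_mask: np.ndarray,
    pos_bias: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Scaled general (Luong) attention of decoder states over encoder states.

    dec: (B, T, Dd); enc: (B, T, De); Wa: (Dd, De); enc_mask: (B, T) bool,
    True at real (non-pad) encoder positions; pos_bias: optional constant
    (T, T) additive score bias.  Returns the context (B, T, De) and a
    cache for the backward pass.
    """
    scale = F32(1.0 / np.sqrt(enc.shape[-1]))
    q = dec @ Wa
    scores = (q @ enc.transpose(0, 2, 1)) * scale
    if pos_bias is not None:
        scores = scores + pos_bias
    scores = np.where(enc_mask[:, None, :], scores, F32(-1e9))
    scores -= scores.max(axis=-1, keepdims=True)
    attn = np.exp(scores)
    attn /= attn.sum(axis=-1, keepdims=True)
    context = attn @ enc
    return context, {"q": q, "attn": attn, "dec": dec, "enc": enc,
                     "Wa": Wa, "scale": scale}


def attention_backward(
    dcontext: np.ndarray, cache: dict, dattn_extra: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (d_dec, d_enc, d_Wa) of attention_forward.

    ``dattn_extra`` carries gradient reaching the attention weights through
    side uses of the weight matrix (e.g. a copy readout over the raw
    encoder input).
    """
    attn, enc, q = cache["attn"], cache["enc"], cache["q"]
    dec, Wa, scale = cache["dec"], cache["Wa"], cache["scale"]
    dattn = dcontext @ enc.transpose(0, 2, 1)
    if dattn_extra is not None:
        dattn = dattn + dattn_extra
    denc = attn.transpose(0, 2, 1) @ dcontext
    dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
    dq = (dscores @ enc) * scale
    denc += (dscores.transpose(0, 2, 1) @ q) * scale
    Dd, De = Wa.shape
    dWa = dec.reshape(-1, Dd).T @ dq.reshape(-1, De)
    ddec = dq @ Wa.T
    return ddec, denc, dWa


# ---------------------------------------------------------------------------
# Loss


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def masked_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean per-position categorical cross-entropy over unmasked positions.

    logits: (B, T, V); targets: (B, T) int; mask: (B, T) bool.  Returns
    (loss, dlogits).
    """
    probs = softmax(logits)
    B, T, V = logits.shape
    idx = (np.arange(B)[:, None], np.arange(T)[None, :], targets)
    n = max(int(mask.sum()), 1)
    loss = float(-(np.log(probs[idx] + 1e-12) * mask).sum() / n)
    dlogits = probs
    dlogits[idx] -= 1.0
    dlogits *= (mask[..., None] / n).astype(F32)
    return loss, dlogits


# ---------------------------------------------------------------------------
# Optimizer


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    """Rescale all gradients in place so their global L2 norm <= max_norm."""
    total = np.sqrt(sum(float(np.sum(np.square(g))) for g in grads.values()))
    if total > max_norm:
        factor = F32(max_norm / (total + 1e-12))
        for g in grads.values():
            g *= factor


class Adam:
    """Standard Adam with bias correction (defaults as commonly published)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float | None = None, weight_decay: float = 0.0):
        if lr is not None:
            self.lr = lr
        self.t += 1
        if weight_decay > 0.0:
            # decoupled weight decay on matrices (biases exempt)
            for k, p in params.items():
                if p.ndim > 1:
                    p *= F32(1.0 - self.lr * weight_decay)
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            params[k] -= (
                self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            ).astype(F32)
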