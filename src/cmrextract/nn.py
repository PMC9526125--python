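"""A compact trainable transformer encoder in NumPy.

Implements the standard pre-LayerNorm BERT-style encoder used for token
classification: token + learned position embeddings, ``n_layers`` blocks of
multi-head self-attention and a GELU feed-forward network with residual
connections, a final LayerNorm, and a linear classification head producing
per-token logits over the label space.  Forward, backward (hand-written
reverse-mode gradients, verified against finite differences in the test
suite) and an Adam optimizer are provided; everything is float64 NumPy, so
training is exactly reproducible for a fixed seed on any platform.

The classification head is zero-initialized: an untrained model therefore
outputs the uniform distribution over labels, and early training is stable.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["TinyTransformer", "Adam", "softmax"]

_NEG_INF = -1e9


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


def _layernorm_forward(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return gamma * xhat + beta, (xhat, inv, gamma)


def _layernorm_backward(dy, cache):
    xhat, inv, gamma = cache
    dgamma = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    dbeta = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * gamma
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dgamma, dbeta


def _linear_forward(x, W, b):
    return x @ W + b, x


def _linear_backward(dy, x, W):
    dx = dy @ W.T
    flat_x = x.reshape(-1, x.shape[-1])
    flat_dy = dy.reshape(-1, dy.shape[-1])
    return dx, flat_x.T @ flat_dy, flat_dy.sum(axis=0)


class TinyTransformer:
    """Pre-LN transformer token classifier with hand-written backprop.

    Parameters follow the usual BERT hyperparameter names at miniature
    scale; the default (2 layers, 64 hidden, 4 heads) trains from random
    initialization on a few hundred reports in minutes on one CPU core.
    """

    def __init__(
        self,
        vocab_size: int,
        n_labels: int,
        d_model: int = 64,
        n_heads: int = 4,
        n_layers: int = 2,
        d_ff: int = 128,
        max_len: int = 128,
        rel_window: int = 16,
        seed: int = 0,
    ):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.vocab_size = vocab_size
        self.n_labels = n_labels
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff
        self.max_len = max_len
        self.rel_window = rel_window
        self.d_head = d_model // n_heads
        rng = np.random.default_rng(seed)

        def init(*shape):
            return rng.normal(0.0, 0.02, size=shape)

        p: dict[str, np.ndarray] = {
            "emb": init(vocab_size, d_model),
            "pos": init(max_len, d_model),
            "lnf_g": np.ones(d_model),
            "lnf_b": np.zeros(d_model),
            # zero head => uniform label distribution at initialization
            "head_W": np.zeros((d_model, n_labels)),
            "head_b": np.zeros(n_labels),
        }
        for l in range(n_layers):
            # learned relative-position attention bias, clipped at +-rel_window;
            # lets heads express "attend k tokens left/right" without having to
            # assemble it from absolute position embeddings
            p[f"l{l}_rel"] = np.zeros((n_heads, 2 * rel_window + 1))
            p[f"l{l}_ln1_g"] = np.ones(d_model)
            p[f"l{l}_ln1_b"] = np.zeros(d_model)
            p[f"l{l}_Wq"] = init(d_model, d_model)
            p[f"l{l}_bq"] = np.zeros(d_model)
            p[f"l{l}_Wk"] = init(d_model, d_model)
            p[f"l{l}_bk"] = np.zeros(d_model)
            p[f"l{l}_Wv"] = init(d_model, d_model)
            p[f"l{l}_bv"] = np.zeros(d_model)
            p[f"l{l}_Wo"] = init(d_model, d_model)
            p[f"l{l}_bo"] = np.zeros(d_model)
            p[f"l{l}_ln2_g"] = np.ones(d_model)
            p[f"l{l}_ln2_b"] = np.zeros(d_model)
            p[f"l{l}_W1"] = init(d_model, d_ff)
            p[f"l{l}_b1"] = np.zeros(d_ff)
            p[f"l{l}_W2"] = init(d_ff, d_model)
            p[f"l{l}_b2"] = np.zeros(d_model)
        self.params = p

    # -- forward ------------------------------------------------------------

    def _split_heads(self, x):
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge_heads(self, x):
        B, H, T, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)

    def forward(self, ids: np.ndarray, mask: np.ndarray):
        """Compute per-token logits.

        Parameters: ``ids`` int array (B, T); ``mask`` float array (B, T)
        with 1 for real tokens and 0 for padding.  Returns (logits, cache);
        the cache feeds :meth:`backward` and holds per-layer attention maps
        under key ``attn`` (list of (B, H, T, T) arrays).
        """
        p = self.params
        B, T = ids.shape
        if T > self.max_len:
            raise ValueError(f"sequence length {T} exceeds model capacity {self.max_len}")
        x = p["emb"][ids] + p["pos"][:T]
        key_bias = (1.0 - mask)[:, None, None, :] * _NEG_INF
        pos = np.arange(T)
        rel_idx = np.clip(pos[None, :] - pos[:, None], -self.rel_window, self.rel_window)
        rel_idx = rel_idx + self.rel_window  # (T, T) bucket indices
        cache: dict = {"ids": ids, "mask": mask, "layers": [], "attn": [], "rel_idx": rel_idx}
        for l in range(self.n_layers):
            y, ln1c = _layernorm_forward(x, p[f"l{l}_ln1_g"], p[f"l{l}_ln1_b"])
            q, _ = _linear_forward(y, p[f"l{l}_Wq"], p[f"l{l}_bq"])
            k, _ = _linear_forward(y, p[f"l{l}_Wk"], p[f"l{l}_bk"])
            v, _ = _linear_forward(y, p[f"l{l}_Wv"], p[f"l{l}_bv"])
            qh, kh, vh = map(self._split_heads, (q, k, v))
            scores = (
                qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(self.d_head)
                + p[f"l{l}_rel"][:, rel_idx][None]
                + key_bias
            )
            probs = softmax(scores)
            ctx = probs @ vh
            merged = self._merge_heads(ctx)
            attn_out, _ = _linear_forward(merged, p[f"l{l}_Wo"], p[f"l{l}_bo"])
            h = x + attn_out
            y2, ln2c = _layernorm_forward(h, p[f"l{l}_ln2_g"], p[f"l{l}_ln2_b"])
            z1, _ = _linear_forward(y2, p[f"l{l}_W1"], p[f"l{l}_b1"])
            a1 = _gelu(z1)
            ffn_out, _ = _linear_forward(a1, p[f"l{l}_W2"], p[f"l{l}_b2"])
            x_new = h + ffn_out
            cache["layers"].append(
                dict(x=x, y=y, ln1c=ln1c, qh=qh, kh=kh, vh=vh, probs=probs,
                     merged=merged, h=h, y2=y2, ln2c=ln2c, z1=z1, a1=a1)
            )
            cache["attn"].append(probs)
            x = x_new
        xf, lnfc = _layernorm_forward(x, p["lnf_g"], p["lnf_b"])
        logits, _ = _linear_forward(xf, p["head_W"], p["head_b"])
        cache["x_final"] = x
        cache["lnfc"] = lnfc
        cache["xf"] = xf
        return logits, cache

    # -- backward -----------------------------------------------------------

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        g = {k: np.zeros_like(v) for k, v in p.items()}
        dxf, g["head_W"], g["head_b"] = _linear_backward(dlogits, cache["xf"], p["head_W"])
        dx, g["lnf_g"], g["lnf_b"] = _layernorm_backward(dxf, cache["lnfc"])
        for l in reversed(range(self.n_layers)):
            c = cache["layers"][l]
            # FFN branch
            dffn = dx
            da1, g[f"l{l}_W2"], g[f"l{l}_b2"] = _linear_backward(dffn, c["a1"], p[f"l{l}_W2"])
            dz1 = da1 * _gelu_grad(c["z1"])
            dy2, g[f"l{l}_W1"], g[f"l{l}_b1"] = _linear_backward(dz1, c["y2"], p[f"l{l}_W1"])
            dh, g[f"l{l}_ln2_g"], g[f"l{l}_ln2_b"] = _layernorm_backward(dy2, c["ln2c"])
            dh = dh + dx  # residual
            # attention branch
            dattn_out = dh
            dmerged, g[f"l{l}_Wo"], g[f"l{l}_bo"] = _linear_backward(
                dattn_out, c["merged"], p[f"l{l}_Wo"]
            )
            dctx = self._split_heads(dmerged)
            dprobs = dctx @ c["vh"].transpose(0, 1, 3, 2)
            dvh = c["probs"].transpose(0, 1, 3, 2) @ dctx
            ds = c["probs"] * (dprobs - (dprobs * c["probs"]).sum(axis=-1, keepdims=True))
            ds_sum = ds.sum(axis=0)  # (H, T, T): gradient w.r.t. the shared bias
            rel_flat = cache["rel_idx"].ravel()
            for h in range(self.n_heads):
                g[f"l{l}_rel"][h] += np.bincount(
                    rel_flat, weights=ds_sum[h].ravel(), minlength=2 * self.rel_window + 1
                )
            ds = ds / np.sqrt(self.d_head)
            dqh = ds @ c["kh"]
            dkh = ds.transpose(0, 1, 3, 2) @ c["qh"]
            dq = self._merge_heads(dqh)
            dk = self._merge_heads(dkh)
            dv = self._merge_heads(dvh)
            dy_q, g[f"l{l}_Wq"], g[f"l{l}_bq"] = _linear_backward(dq, c["y"], p[f"l{l}_Wq"])
            dy_k, g[f"l{l}_Wk"], g[f"l{l}_bk"] = _linear_backward(dk, c["y"], p[f"l{l}_Wk"])
            dy_v, g[f"l{l}_Wv"], g[f"l{l}_bv"] = _linear_backward(dv, c["y"], p[f"l{l}_Wv"])
            dy = dy_q + dy_k + dy_v
            dx_ln, g[f"l{l}_ln1_g"], g[f"l{l}_ln1_b"] = _layernorm_backward(dy, c["ln1c"])
            dx = dh + dx_ln
        # embeddings
        ids, mask = cache["ids"], cache["mask"]
        np.add.at(g["emb"], ids.reshape(-1), dx.reshape(-1, self.d_model))
        g["pos"][: ids.shape[1]] += dx.sum(axis=0)
        return g

    # -- losses -------------------------------------------------------------

    def loss_and_grads(self, ids, mask, labels):
        """Mean token-level cross-entropy over unpadded positions + grads."""
        logits, cache = self.forward(ids, mask)
        probs = softmax(logits)
        B, T, L = probs.shape
        valid = mask > 0
        n_valid = int(valid.sum())
        if n_valid == 0:
            raise ValueError("batch contains no unpadded tokens")
        onehot = np.zeros_like(probs)
        bidx, tidx = np.nonzero(valid)
        onehot[bidx, tidx, labels[valid].astype(int)] = 1.0
        eps = 1e-12
        loss = -np.sum(onehot * np.log(probs + eps)) / n_valid
        dlogits = (probs - onehot) * valid[..., None] / n_valid
        grads = self.backward(dlogits, cache)
        return loss, grads

    def predict_probs(self, ids, mask):
        logits, _ = self.forward(ids, mask)
        return softmax(logits)

    def attention_last_layer(self, ids, mask):
        """Mean-over-heads attention of the last encoder layer, (B, T, T)."""
        _, cache = self.forward(ids, mask)
        return cache["attn"][-1].mean(axis=1)

    # -- (de)serialization --------------------------------------------------

    def get_config(self) -> dict:
        return dict(
            vocab_size=self.vocab_size,
            n_labels=self.n_labels,
            d_model=self.d_model,
            n_heads=self.n_heads,
            n_layers=self.n_layers,
            d_ff=self.d_ff,
            max_len=self.max_len,
            rel_window=self.rel_window,
        )

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params or self.params[k].shape != np.asarray(v).shape:
                raise ValueError(f"state entry {k!r} does not match model shape")
            self.params[k] = np.asarray(v, dtype=float).copy()


class Adam:
    """Plain Adam (no weight decay, no schedule)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, gk in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * gk
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * gk * gk
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
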