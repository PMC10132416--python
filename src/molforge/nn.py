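"""Minimal numpy neural-network core: a stacked-GRU language model.

Implements exactly what the generator needs — an embedding, a stack of GRU
layers, a linear projection to vocabulary logits, backpropagation through
time for (optionally per-sequence-weighted) token cross-entropy, and Adam.
Gate layout and parameter shapes follow the common convention of gates
ordered (reset, update, candidate) with separate input/hidden biases, so
parameter counts match the standard closed form

    P = V*E + sum_layers 3*(d_in*H + H*H + 2*H) + (H*V + V).

Everything is float64 for reproducibility; sizes used in this project are
small enough that this costs little.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GRUStack", "Adam", "weighted_nll_and_grads"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    z = logits - m
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


class GRUStack:
    """Embedding -> ``num_layers`` stacked GRUs -> linear vocab projection."""

    def __init__(self, vocab_size: int, embedding_dim: int, hidden_dim: int,
                 num_layers: int = 3, seed: int = 0):
        if vocab_size < 2 or embedding_dim < 1 or hidden_dim < 1 or num_layers < 1:
            raise ValueError("invalid model dimensions")
        self.vocab_size = vocab_size
        self.embedding_dim = embedding_dim
        self.hidden_dim = hidden_dim
        self.num_layers = num_layers
        rng = np.random.default_rng(seed)
        k = 1.0 / np.sqrt(hidden_dim)
        p: dict[str, np.ndarray] = {}
        p["emb"] = rng.uniform(-k, k, size=(vocab_size, embedding_dim))
        for layer in range(num_layers):
            d_in = embedding_dim if layer == 0 else hidden_dim
            p[f"W_ih{layer}"] = rng.uniform(-k, k, size=(3 * hidden_dim, d_in))
            p[f"W_hh{layer}"] = rng.uniform(-k, k, size=(3 * hidden_dim, hidden_dim))
            p[f"b_ih{layer}"] = rng.uniform(-k, k, size=3 * hidden_dim)
            p[f"b_hh{layer}"] = rng.uniform(-k, k, size=3 * hidden_dim)
        p["W_out"] = rng.uniform(-k, k, size=(hidden_dim, vocab_size))
        p["b_out"] = rng.uniform(-k, k, size=vocab_size)
        self.params = p

    # ------------------------------------------------------------------
    def param_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    # ------------------------------------------------------------------
    def _cell_forward(self, layer: int, x: np.ndarray, h: np.ndarray):
        H = self.hidden_dim
        p = self.params
        gi = x @ p[f"W_ih{layer}"].T + p[f"b_ih{layer}"]
        gh = h @ p[f"W_hh{layer}"].T + p[f"b_hh{layer}"]
        r = _sigmoid(gi[:, :H] + gh[:, :H])
        z = _sigmoid(gi[:, H:2 * H] + gh[:, H:2 * H])
        ghn = gh[:, 2 * H:]
        n = np.tanh(gi[:, 2 * H:] + r * ghn)
        h_new = (1.0 - z) * n + z * h
        return h_new, (x, h, r, z, n, ghn)

    def forward(self, tokens: np.ndarray, h0: list[np.ndarray] | None = None,
                keep_cache: bool = False):
        """Run the whole stack over a (B, T) int matrix of input tokens.

        Returns ``(logits, h_last, cache)`` with logits of shape (B, T, V).
        """
        B, T = tokens.shape
        H = self.hidden_dim
        hs = [np.zeros((B, H)) for _ in range(self.num_layers)] if h0 is None else [h.copy() for h in h0]
        x_seq = self.params["emb"][tokens]  # (B, T, E)
        layer_in = x_seq
        caches = []  # per layer: list over t of cell caches
        for layer in range(self.num_layers):
            outs = np.empty((B, T, H))
            cache_l = []
            h = hs[layer]
            for t in range(T):
                h, c = self._cell_forward(layer, layer_in[:, t, :], h)
                outs[:, t, :] = h
                if keep_cache:
                    cache_l.append(c)
            hs[layer] = h
            caches.append(cache_l)
            layer_in = outs
        logits = layer_in @ self.params["W_out"] + self.params["b_out"]
        cache = (tokens, caches, layer_in) if keep_cache else None
        return logits, hs, cache

    # ------------------------------------------------------------------
    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """BPTT given d(loss)/d(logits); returns grads for every parameter."""
        tokens, caches, top_out = cache
        B, T, _ = dlogits.shape
        H = self.hidden_dim
        p = self.params
        g = self.zero_grads()

        g["W_out"] = np.einsum("bth,btv->hv", top_out, dlogits)
        g["b_out"] = dlogits.sum(axis=(0, 1))
        d_layer_out = dlogits @ p["W_out"].T  # (B, T, H)

        for layer in range(self.num_layers - 1, -1, -1):
            W_ih = p[f"W_ih{layer}"]
            W_hh = p[f"W_hh{layer}"]
            dW_ih = g[f"W_ih{layer}"]
            dW_hh = g[f"W_hh{layer}"]
            db_ih = g[f"b_ih{layer}"]
            db_hh = g[f"b_hh{layer}"]
            d_in_seq = np.empty((B, T, W_ih.shape[1]))
            dh_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                x, h_prev, r, z, n, ghn = caches[layer][t]
                dh = d_layer_out[:, t, :] + dh_next
                dn = dh * (1.0 - z)
                dz = dh * (h_prev - n)
                dh_prev = dh * z
                dn_pre = dn * (1.0 - n * n)
                dghn = dn_pre * r
                dr = dn_pre * ghn
                dr_pre = dr * r * (1.0 - r)
                dz_pre = dz * z * (1.0 - z)
                dgi = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
                dgh = np.concatenate([dr_pre, dz_pre, dghn], axis=1)
                dW_ih += dgi.T @ x
                dW_hh += dgh.T @ h_prev
                db_ih += dgi.sum(axis=0)
                db_hh += dgh.sum(axis=0)
                d_in_seq[:, t, :] = dgi @ W_ih
                dh_next = dh_prev + dgh @ W_hh
            d_layer_out = d_in_seq

        # d_layer_out is now d(embedded inputs); scatter into embedding rows
        np.add.at(g["emb"], tokens.reshape(-1), d_layer_out.reshape(-1, self.embedding_dim))
        return g

    # ------------------------------------------------------------------
    def step(self, tokens_t: np.ndarray, hs: list[np.ndarray]):
        """One autoregressive step: (B,) tokens + hidden states -> logits."""
        x = self.params["emb"][tokens_t]
        new_hs = []
        for layer in range(self.num_layers):
            h, _ = self._cell_forward(layer, x, hs[layer])
            new_hs.append(h)
            x = h
        logits = x @ self.params["W_out"] + self.params["b_out"]
        return logits, new_hs

    def init_hidden(self, batch: int) -> list[np.ndarray]:
        return [np.zeros((batch, self.hidden_dim)) for _ in range(self.num_layers)]


def weighted_nll_and_grads(model: GRUStack, inputs: np.ndarray,
                           targets: np.ndarray, mask: np.ndarray,
                           weights: np.ndarray, sign: float = 1.0,
                           compute_grads: bool = True,
                           logit_mask: np.ndarray | None = None):
    """Loss ``sign * sum_b w_b * NLL_b`` and its parameter gradients.

    ``inputs``/``targets`` are (B, T) shifted token matrices, ``mask`` is 1
    where the target position counts, ``weights`` is a per-sequence factor.
    With ``weights = 1/n_tokens`` this is mean-token cross-entropy; with
    ``weights = R(tau)/N`` and the appropriate sign it is the REINFORCE
    surrogate loss.  ``logit_mask`` (T, V) boolean marks vocabulary entries
    forbidden at each step (their probability is renormalized away, matching
    a sampler that masks the same entries).  Returns
    ``(loss, per_sequence_nll, grads_or_None)``.
    """
    logits, _, cache = model.forward(inputs, keep_cache=compute_grads)
    if logit_mask is not None:
        logits = np.where(logit_mask[None, :, :], -np.inf, logits)
    logp = log_softmax(logits)
    B, T, V = logits.shape
    tok_nll = -np.take_along_axis(logp, targets[..., None], axis=2)[..., 0]
    tok_nll = np.where(mask > 0, tok_nll, 0.0)  # ignored targets may be -inf
    seq_nll = tok_nll.sum(axis=1)
    loss = sign * float(weights @ seq_nll)
    if not compute_grads:
        return loss, seq_nll, None
    probs = np.exp(logp)
    onehot_grad = probs.copy()
    np.add.at(
        onehot_grad.reshape(-1, V),
        (np.arange(B * T), targets.reshape(-1)),
        -1.0,
    )
    dlogits = onehot_grad * (mask[..., None] * (sign * weights)[:, None, None])
    grads = model.backward(cache, dlogits)
    return loss, seq_nll, grads


class Adam:
    """Adam with bias correction; state keyed by parameter name."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * gk * gk
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
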