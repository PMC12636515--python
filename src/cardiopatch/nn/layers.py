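"""Neural-network layers and the Adam optimizer on the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, layer_norm, softmax


def init_uniform(rng: np.random.Generator, *shape, fan_in: int = None) -> Tensor:
    """Glorot-style uniform initialization."""
    fan = fan_in if fan_in is not None else shape[0]
    bound = 1.0 / np.sqrt(max(1, fan))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Module:
    def parameters(self) -> list:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=float)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = init_uniform(rng, d_in, d_out, fan_in=d_in)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv1dSeq(Module):
    """1-D convolution along the time axis of a (B, T, C_in) sequence,
    'same' padding by shortened valid output plus edge replication avoided:
    output length T - kernel + 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        self.kernel = kernel
        self.W = [init_uniform(rng, c_in, c_out, fan_in=c_in * kernel)
                  for _ in range(kernel)]
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        t_out = x.shape[1] - self.kernel + 1
        if t_out < 1:
            raise ValueError("sequence shorter than the convolution kernel")
        out = x[:, 0:t_out, :] @ self.W[0]
        for j in range(1, self.kernel):
            out = out + x[:, j:j + t_out, :] @ self.W[j]
        return out + self.b


class MultiHeadSelfAttention(Module):
    """Standard scaled-dot-product multi-head self-attention.

    ``__call__`` returns (output, attention) with attention of shape
    (B, heads, T, T); the attention probabilities are also exposed as plain
    numpy in ``last_attention`` for interpretability readout.
    """

    def __init__(self, embed_dim: int, n_heads: int, rng: np.random.Generator):
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = embed_dim // n_heads
        self.Wq = Linear(embed_dim, embed_dim, rng)
        self.Wk = Linear(embed_dim, embed_dim, rng)
        self.Wv = Linear(embed_dim, embed_dim, rng)
        self.Wo = Linear(embed_dim, embed_dim, rng)
        self.last_attention = None

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, mask: np.ndarray = None):
        """``mask`` is an optional (T, T) boolean array; False entries are
        excluded from attention (set to -inf before the softmax)."""
        B, T, E = x.shape
        q = self._split(self.Wq(x), B, T)
        k = self._split(self.Wk(x), B, T)
        v = self._split(self.Wv(x), B, T)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        if mask is not None:
            scores = scores + np.where(mask, 0.0, -1e9)
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data.copy()
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, E)
        return self.Wo(ctx), attn


class TransformerBlock(Module):
    """Pre-norm encoder block: x + MHSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, embed_dim: int, n_heads: int, mlp_dim: int,
                 rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(embed_dim, n_heads, rng)
        self.fc1 = Linear(embed_dim, mlp_dim, rng)
        self.fc2 = Linear(mlp_dim, embed_dim, rng)
        self.g1 = Tensor(np.ones(embed_dim), requires_grad=True)
        self.b1 = Tensor(np.zeros(embed_dim), requires_grad=True)
        self.g2 = Tensor(np.ones(embed_dim), requires_grad=True)
        self.b2 = Tensor(np.zeros(embed_dim), requires_grad=True)

    def __call__(self, x: Tensor, dropout_mask=None, attn_mask=None):
        a, attn = self.attn(layer_norm(x, self.g1, self.b1), mask=attn_mask)
        if dropout_mask is not None:
            a = a * dropout_mask[0]
        x = x + a
        h = self.fc2(self.fc1(layer_norm(x, self.g2, self.b2)).relu())
        if dropout_mask is not None:
            h = h * dropout_mask[1]
        return x + h, attn


class GRU(Module):
    """Gated recurrent unit over a (B, T, C) sequence; returns the final
    hidden state (B, H)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.Wz = Linear(d_in, d_hidden, rng)
        self.Uz = Linear(d_hidden, d_hidden, rng)
        self.Wr = Linear(d_in, d_hidden, rng)
        self.Ur = Linear(d_hidden, d_hidden, rng)
        self.Wh = Linear(d_in, d_hidden, rng)
        self.Uh = Linear(d_hidden, d_hidden, rng)

    def step(self, x_t: Tensor, h: Tensor) -> Tensor:
        z = (self.Wz(x_t) + self.Uz(h)).sigmoid()
        r = (self.Wr(x_t) + self.Ur(h)).sigmoid()
        h_tilde = (self.Wh(x_t) + self.Uh(r * h)).tanh()
        return (1.0 - z) * h + z * h_tilde

    def __call__(self, x: Tensor, lengths: np.ndarray = None) -> Tensor:
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.d_hidden)))
        if lengths is None:
            for t in range(T):
                h = self.step(x[:, t, :], h)
            return h
        # masked run: hidden state frozen past each sequence's length
        for t in range(T):
            mask = Tensor((lengths > t).astype(float)[:, None])
            h_new = self.step(x[:, t, :], h)
            h = mask * h_new + (1.0 - mask) * h
        return h


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
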