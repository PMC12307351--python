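"""Small neural-network layers on top of the :mod:`modfus._tensor` engine.

Only what the tiny encoder presets and the fusion/classification blocks need:
linear maps, layer norm, multi-head (self- or cross-) attention, a pre-norm
transformer block and an embedding table.  Initialisation is seeded through an
explicit ``numpy.random.Generator`` so identical configs give bit-identical
weights.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Parameter, Tensor

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "EmbeddingTable",
    "TransformerBlock",
    "multi_head_attention",
    "split_heads",
    "merge_heads",
]


class Module:
    """Parameter container with recursive traversal and (de)serialisation."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def n_parameters(self, trainable_only: bool = False) -> int:
        return sum(
            p.data.size for p in self.parameters() if not (trainable_only and p.frozen)
        )

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, name: str = ""):
        super().__init__()
        scale = 1.0 / np.sqrt(d_in)
        self.W = Parameter(rng.normal(0.0, scale, size=(d_in, d_out)), name=f"{name}.W")
        self.has_bias = bias
        if bias:
            self.b = Parameter(np.zeros(d_out), name=f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        if self.has_bias:
            y = y + self.b
        return y


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class EmbeddingTable(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator, name: str = ""):
        super().__init__()
        self.table = Parameter(rng.normal(0.0, 0.02, size=(n, d)), name=name)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.table.take_rows(np.asarray(ids, dtype=np.intp))


def split_heads(x: Tensor, h: int) -> Tensor:
    """(..., m, d) -> (..., h, m, d/h)."""
    *lead, m, d = x.shape
    if d % h:
        raise ValueError(f"model width {d} not divisible by {h} heads")
    y = x.reshape(*lead, m, h, d // h)
    return y.swapaxes(-2, -3)


def merge_heads(x: Tensor) -> Tensor:
    """(..., h, m, dh) -> (..., m, h*dh)."""
    *lead, h, m, dh = x.shape
    return x.swapaxes(-2, -3).reshape(*lead, m, h * dh)


def multi_head_attention(
    q: Tensor,
    k: Tensor,
    v: Tensor,
    h: int,
    key_mask: np.ndarray | None = None,
    return_weights: bool = False,
):
    """Scaled dot-product attention with ``h`` heads.

    ``q``: (..., m_q, d); ``k``/``v``: (..., m_kv, d).  Per-head scaling is
    ``sqrt(d/h)``.  ``key_mask`` is a boolean array over key positions
    (True = attend) broadcastable to (..., m_kv); masked keys receive a large
    negative additive logit.  Returns the concatenated-head output of shape
    (..., m_q, d), optionally with the softmax weights (..., h, m_q, m_kv)
    as a plain array.
    """
    d = q.shape[-1]
    dh = d // h
    qh = split_heads(q, h)
    kh = split_heads(k, h)
    vh = split_heads(v, h)
    logits = (qh @ kh.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
    mask = None
    if key_mask is not None:
        km = np.asarray(key_mask, dtype=bool)
        mask = np.where(km, 0.0, -1e9)[..., None, None, :]  # broadcast over heads, queries
    weights = logits.softmax(axis=-1, additive_mask=mask)
    out = merge_heads(weights @ vh)
    if return_weights:
        return out, weights.data
    return out


class _MLP(Module):
    def __init__(self, d: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerBlock(Module):
    """Pre-norm self-attention block: LN→MHSA→residual, LN→MLP→residual."""

    def __init__(self, d: int, h: int, rng: np.random.Generator, mlp_ratio: int = 2):
        super().__init__()
        self.h = h
        self.ln1 = LayerNorm(d)
        self.wq = Linear(d, d, rng, bias=False)
        self.wk = Linear(d, d, rng, bias=False)
        self.wv = Linear(d, d, rng, bias=False)
        self.wo = Linear(d, d, rng)
        self.ln2 = LayerNorm(d)
        self.mlp = _MLP(d, mlp_ratio * d, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        z = self.ln1(x)
        att = multi_head_attention(self.wq(z), self.wk(z), self.wv(z), self.h, key_mask)
        x = x + self.wo(att)
        return x + self.mlp(self.ln2(x))
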