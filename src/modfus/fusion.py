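"""Bidirectional multi-head cross-modal attention (CMA) and attention export.

Each modality owns its Q/K/V projections.  Text-guided image enhancement uses
image queries against text keys/values,

    I* = softmax(Q_I K_T^T / sqrt(d_h)) V_T,

and image-guided text enhancement symmetrically uses text queries against
image keys/values.  Both directions are computed from the *same* input
features (one simultaneous pass per layer, no sequential chaining); with
``depth > 1`` the layer is stacked with a residual connection between layers
to keep deep stacks stable.  Heads are concatenated without an output
projection — the printed operator is the bare attention.  Per-head scaling is
``sqrt(d_model / heads)``.

``export_attention_overlay`` turns an attention map whose *keys* are image
patches into a patch-grid saliency overlay on the central axial slice, the
usual way cross-modal attention is visualised on MRI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor
from .exceptions import ConfigError, UnsupportedDirectionError, ValidationError
from .nn import Linear, Module, multi_head_attention

__all__ = [
    "AttentionParams",
    "AttentionMap",
    "cross_attention",
    "CrossModalAttention",
    "bidirectional_cma",
    "export_attention_overlay",
    "pooled_mean",
]


@dataclass(frozen=True)
class AttentionParams:
    """Explicit projection matrices for one attention direction (functional API)."""

    W_Q: np.ndarray
    W_K: np.ndarray
    W_V: np.ndarray
    heads: int = 8

    def __post_init__(self):
        d = np.asarray(self.W_Q).shape[1]
        if d % self.heads:
            raise ConfigError(f"d_model {d} not divisible by {self.heads} heads")


@dataclass(frozen=True)
class AttentionMap:
    """Softmax attention weights (heads × queries × keys) with modality tags."""

    weights: np.ndarray
    query_modality: str
    key_modality: str

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim < 3:
            raise ValidationError("attention weights must be (..., h, m_q, m_kv)")
        sums = w.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValidationError("attention rows must sum to 1")
        if (w < -1e-12).any() or (w > 1 + 1e-12).any():
            raise ValidationError("attention weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)


def cross_attention(
    query_seq: np.ndarray,
    context_seq: np.ndarray,
    params: AttentionParams,
    query_modality: str = "image",
    key_modality: str = "text",
) -> tuple[np.ndarray, AttentionMap]:
    """One attention direction: queries from one modality, K/V from the other.

    ``query_seq``: (m_q, d); ``context_seq``: (m_kv, d).  Returns the enhanced
    query-shaped sequence and the per-head attention map.
    """
    q = np.asarray(query_seq, dtype=np.float64)
    c = np.asarray(context_seq, dtype=np.float64)
    if q.ndim != 2 or c.ndim != 2 or q.shape[1] != c.shape[1]:
        raise ConfigError(f"token widths must match: {q.shape} vs {c.shape}")
    if q.shape[1] != np.asarray(params.W_Q).shape[0]:
        raise ConfigError(
            f"token width {q.shape[1]} does not match projection "
            f"{np.asarray(params.W_Q).shape}"
        )
    out, w = multi_head_attention(
        Tensor(q @ params.W_Q),
        Tensor(c @ params.W_K),
        Tensor(c @ params.W_V),
        params.heads,
        return_weights=True,
    )
    amap = AttentionMap(w, query_modality=query_modality, key_modality=key_modality)
    return out.data, amap


class CrossModalAttention(Module):
    """Trainable bidirectional CMA block (``depth`` stacked layers).

    Layer ``l`` holds six projection matrices: Q/K/V for the image modality
    and Q/K/V for the text modality, all ``d_model × d_model`` without bias.
    """

    def __init__(self, d_model: int = 512, heads: int = 8, depth: int = 1,
                 residual: bool | None = None, seed: int = 0):
        super().__init__()
        if depth < 1:
            raise ConfigError("CMA depth must be >= 1")
        if d_model % heads:
            raise ConfigError(f"d_model {d_model} not divisible by {heads} heads")
        self.d_model = d_model
        self.heads = heads
        self.depth = depth
        # residual connections only matter for stacking; off at depth 1 to
        # keep the single-layer operator exactly the printed attention
        self.residual = (depth > 1) if residual is None else bool(residual)
        rng = np.random.default_rng(seed)
        for layer in range(depth):
            for mod in ("img", "txt"):
                for proj in ("q", "k", "v"):
                    setattr(
                        self,
                        f"w{proj}_{mod}_{layer}",
                        Linear(d_model, d_model, rng, bias=False),
                    )

    def _layer(self, layer: int, I: Tensor, T: Tensor, text_mask: np.ndarray | None):
        wq_i = getattr(self, f"wq_img_{layer}")
        wk_i = getattr(self, f"wk_img_{layer}")
        wv_i = getattr(self, f"wv_img_{layer}")
        wq_t = getattr(self, f"wq_txt_{layer}")
        wk_t = getattr(self, f"wk_txt_{layer}")
        wv_t = getattr(self, f"wv_txt_{layer}")
        # both directions read the SAME input features
        I_star, w_it = multi_head_attention(
            wq_i(I), wk_t(T), wv_t(T), self.heads,
            key_mask=text_mask, return_weights=True,
        )
        T_star, w_ti = multi_head_attention(
            wq_t(T), wk_i(I), wv_i(I), self.heads, return_weights=True,
        )
        return I_star, T_star, w_it, w_ti

    def __call__(self, I_seq: Tensor, T_seq: Tensor,
                 text_mask: np.ndarray | None = None):
        """Enhance both token sequences; returns (I*, T*, maps).

        ``maps`` is a list with one entry per layer, each a pair of
        :class:`AttentionMap` (image-queries→text-keys, text-queries→image-keys).
        """
        if I_seq.shape[-1] != self.d_model or T_seq.shape[-1] != self.d_model:
            raise ConfigError(
                f"token width mismatch: image {I_seq.shape[-1]}, text "
                f"{T_seq.shape[-1]}, expected {self.d_model}"
            )
        I, T = I_seq, T_seq
        maps = []
        for layer in range(self.depth):
            I_star, T_star, w_it, w_ti = self._layer(layer, I, T, text_mask)
            if self.residual:
                I_star = I_star + I
                T_star = T_star + T
            maps.append(
                (
                    AttentionMap(w_it, "image", "text"),
                    AttentionMap(w_ti, "text", "image"),
                )
            )
            I, T = I_star, T_star
        return I, T, maps


def bidirectional_cma(
    I_seq: np.ndarray,
    T_seq: np.ndarray,
    image_params: AttentionParams,
    text_params: AttentionParams,
) -> tuple[np.ndarray, np.ndarray, tuple[AttentionMap, AttentionMap]]:
    """Functional single-layer bidirectional CMA on plain arrays.

    ``image_params`` projects image tokens (Q_I/K_I/V_I) and
    ``text_params`` projects text tokens; I* attends image queries to text
    keys/values and T* the reverse, both from the same inputs.
    """
    I_star, map_it = cross_attention(
        I_seq, T_seq, _mixed(image_params, text_params), "image", "text"
    )
    T_star, map_ti = cross_attention(
        T_seq, I_seq, _mixed(text_params, image_params), "text", "image"
    )
    return I_star, T_star, (map_it, map_ti)


def _mixed(query_params: AttentionParams, context_params: AttentionParams) -> AttentionParams:
    """Queries use the query modality's W_Q; K/V the context modality's."""
    return AttentionParams(
        W_Q=query_params.W_Q,
        W_K=context_params.W_K,
        W_V=context_params.W_V,
        heads=query_params.heads,
    )


def pooled_mean(tokens: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Mean over the token axis, restricted to unmasked positions."""
    if mask is None:
        return tokens.mean(axis=-2)
    m = np.asarray(mask, dtype=np.float64)[..., None]
    denom = m.sum(axis=-2)
    return (tokens * m).sum(axis=-2) * Tensor(1.0 / denom)


def export_attention_overlay(
    amap: AttentionMap,
    volume_shape: tuple[int, int, int],
    patch_size: int,
    out_path,
) -> np.ndarray:
    """Write a per-patch saliency overlay for the central axial slice.

    The map must have image patches on its *key* axis (text queries attending
    image keys); weights are averaged over heads and queries, reshaped to the
    patch grid, upsampled by patch size, and the central axial (z) slice is
    written as an 8-bit grayscale PNG.  Returns the full 3-D overlay volume
    (before quantisation).
    """
    from PIL import Image

    if amap.key_modality != "image":
        raise UnsupportedDirectionError(
            "overlay export needs image patches on the key axis; got a map over "
            f"{amap.key_modality!r} keys"
        )
    w = amap.weights
    if w.ndim > 3:  # batched: use the first element
        w = w.reshape(-1, *w.shape[-3:])[0]
    saliency = w.mean(axis=(0, 1))  # (m_img,)
    nx, ny, nz = (s // patch_size for s in volume_shape)
    if saliency.size != nx * ny * nz:
        raise ValidationError(
            f"{saliency.size} image tokens do not tile {volume_shape} "
            f"with patch {patch_size}"
        )
    grid = saliency.reshape(nx, ny, nz)
    overlay = np.repeat(np.repeat(np.repeat(grid, patch_size, 0), patch_size, 1), patch_size, 2)
    axial = overlay[:, :, overlay.shape[2] // 2]
    lo, hi = axial.min(), axial.max()
    img = np.zeros_like(axial) if hi == lo else (axial - lo) / (hi - lo)
    Image.fromarray((img * 255).round().astype(np.uint8)).save(out_path)
    return overlay
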