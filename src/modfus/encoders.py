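"""Image and text encoders with freeze policies and shared-space projection.

The ``tiny`` preset is a pair of small transformers trainable from scratch on
synthetic cohorts: the image path partitions a 3-D volume into cubic patches,
linearly embeds them and applies ``depth`` self-attention stages; the text
path is a word-level embedding + positional table followed by ``depth``
transformer layers.  Both end in a learned linear projection into the shared
``shared_dim``-dimensional space (default 512).  The pooled embedding used by
the contrastive stage is the token mean for images and the first token for
text; the pre-pooling token sequence feeds the cross-modal attention block.

Stage-wise freezing mirrors the common transfer-learning recipe of keeping
early, task-invariant stages fixed (patch/word embeddings plus the first
block(s)) while fine-tuning the upper stages: ``freeze_mask[i]`` freezes
parameter group ``i``, where group 0 contains the embedding layer(s) together
with the first block, group ``i`` the ``i``-th block, and the final group
additionally owns the shared-space projection (it is task-adaptive and
belongs with the top of the network).

Adapters wrapping published pretrained backbones can be substituted for the
tiny preset wherever an object with the same ``__call__`` contract is passed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor
from .exceptions import ConfigError, NumericError, ValidationError
from .nn import EmbeddingTable, Linear, Module, TransformerBlock

__all__ = [
    "EncoderConfig",
    "Vocab",
    "build_vocab",
    "ImageEncoder",
    "TextEncoder",
    "apply_freeze_policy",
    "trainable_parameter_count",
]

UNK_ID = 0
PAD_ID = 1
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture + freezing description for one modality encoder."""

    modality: str  # "image" | "text"
    preset: str = "tiny"
    d_model: int = 32
    depth: int = 2
    n_heads: int = 4
    shared_dim: int = 512
    patch_size: int = 8  # image only
    max_len: int = 64  # text only
    freeze_mask: tuple[bool, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.modality not in ("image", "text"):
            raise ConfigError(f"unknown modality {self.modality!r}")
        if self.shared_dim <= 0:
            raise ConfigError("shared_dim must be positive")
        if self.depth < 1:
            raise ConfigError("encoder depth must be >= 1")
        if self.freeze_mask is not None and len(self.freeze_mask) != self.depth:
            raise ConfigError(
                f"freeze_mask length {len(self.freeze_mask)} != depth {self.depth}"
            )

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["freeze_mask"] = None if self.freeze_mask is None else list(self.freeze_mask)
        return d


# ----------------------------------------------------------------- vocabulary

@dataclass(frozen=True)
class Vocab:
    """Word-level vocabulary with reserved UNK (0) and PAD (1) ids.

    ``provenance`` records which subjects' prompts built the vocabulary, so
    cross-validation can assert that no held-out subject leaked in.
    """

    token_to_id: dict[str, int]
    provenance: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.token_to_id) + 2

    def encode(self, text: str, max_len: int) -> tuple[np.ndarray, np.ndarray]:
        """Tokenize and pad/truncate to ``max_len``; returns (ids, mask)."""
        toks = tokenize(text)
        if not toks:
            raise ValidationError("cannot encode an empty prompt")
        ids = [self.token_to_id.get(t, UNK_ID) for t in toks[:max_len]]
        mask = np.zeros(max_len, dtype=bool)
        mask[: len(ids)] = True
        ids = ids + [PAD_ID] * (max_len - len(ids))
        return np.asarray(ids, dtype=np.intp), mask


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def build_vocab(corpus, min_count: int = 1, provenance=frozenset()) -> Vocab:
    """Deterministic vocabulary: ids ordered by (count desc, token asc)."""
    corpus = list(corpus)
    if not corpus:
        raise ValidationError("cannot build a vocabulary from an empty corpus")
    counts: dict[str, int] = {}
    for text in corpus:
        for tok in tokenize(text):
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    return Vocab(
        token_to_id={t: i + 2 for i, t in enumerate(kept)},
        provenance=frozenset(provenance),
    )


# ------------------------------------------------------------------- encoders

def patchify(volume: np.ndarray, p: int) -> np.ndarray:
    """(X, Y, Z) volume -> (m, p^3) patch matrix (raster order)."""
    x, y, z = volume.shape
    if x % p or y % p or z % p:
        raise ValidationError(f"volume shape {volume.shape} not divisible by patch {p}")
    v = volume.reshape(x // p, p, y // p, p, z // p, p)
    v = v.transpose(0, 2, 4, 1, 3, 5)
    return v.reshape(-1, p**3)


class ImageEncoder(Module):
    """Patch-embedding + self-attention stages + shared-space projection."""

    def __init__(self, config: EncoderConfig):
        super().__init__()
        if config.modality != "image":
            raise ConfigError("ImageEncoder requires an image-modality config")
        self.config = config
        rng = np.random.default_rng(config.seed)
        p3 = config.patch_size**3
        self.patch_embed = Linear(p3, config.d_model, rng, name="patch_embed")
        for i in range(config.depth):
            setattr(self, f"stage{i}", TransformerBlock(config.d_model, config.n_heads, rng))
        self.proj = Linear(config.d_model, config.shared_dim, rng, name="proj")
        if config.freeze_mask is not None:
            apply_freeze_policy(self, config.freeze_mask)

    # groups the freeze mask indexes over; group 0 owns the patch embedding,
    # the last group owns the shared-space projection
    def stage_groups(self) -> list[list[Module]]:
        groups = []
        for i in range(self.config.depth):
            mods = [getattr(self, f"stage{i}")]
            if i == 0:
                mods.insert(0, self.patch_embed)
            if i == self.config.depth - 1:
                mods.append(self.proj)
            groups.append(mods)
        return groups

    def __call__(self, volumes: np.ndarray) -> tuple[Tensor, Tensor]:
        """Encode (B, X, Y, Z) volumes -> (pooled (B, d), tokens (B, m, d))."""
        volumes = np.asarray(volumes, dtype=np.float64)
        if volumes.ndim == 3:
            volumes = volumes[None]
        if not np.isfinite(volumes).all():
            raise NumericError("volume contains non-finite voxels")
        patches = np.stack([patchify(v, self.config.patch_size) for v in volumes])
        x = self.patch_embed(Tensor(patches))
        for i in range(self.config.depth):
            x = getattr(self, f"stage{i}")(x)
        tokens = self.proj(x)  # (B, m, shared_dim)
        pooled = tokens.mean(axis=1)
        return pooled, tokens


class TextEncoder(Module):
    """Word embedding + positional table + transformer layers + projection.

    A desk-scale stand-in for a pretrained biomedical language model, with
    the same layer-freezing semantics (e.g. freeze the lower layers, tune the
    top ones).
    """

    def __init__(self, config: EncoderConfig, vocab: Vocab):
        super().__init__()
        if config.modality != "text":
            raise ConfigError("TextEncoder requires a text-modality config")
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed)
        self.tok_emb = EmbeddingTable(len(vocab), config.d_model, rng, name="tok_emb")
        self.pos_emb = EmbeddingTable(config.max_len, config.d_model, rng, name="pos_emb")
        for i in range(config.depth):
            setattr(self, f"layer{i}", TransformerBlock(config.d_model, config.n_heads, rng))
        self.proj = Linear(config.d_model, config.shared_dim, rng, name="proj")
        if config.freeze_mask is not None:
            apply_freeze_policy(self, config.freeze_mask)

    def stage_groups(self) -> list[list[Module]]:
        groups = []
        for i in range(self.config.depth):
            mods = [getattr(self, f"layer{i}")]
            if i == 0:
                mods = [self.tok_emb, self.pos_emb] + mods
            if i == self.config.depth - 1:
                mods.append(self.proj)
            groups.append(mods)
        return groups

    def encode_ids(self, prompts: list[str]) -> tuple[np.ndarray, np.ndarray]:
        pairs = [self.vocab.encode(p, self.config.max_len) for p in prompts]
        ids = np.stack([p[0] for p in pairs])
        mask = np.stack([p[1] for p in pairs])
        return ids, mask

    def __call__(self, prompts) -> tuple[Tensor, Tensor, np.ndarray]:
        """Encode prompts -> (pooled (B, d), tokens (B, L, d), mask (B, L)).

        ``prompts`` is a list of strings or a pre-encoded (ids, mask) pair.
        Pooling takes the contextual embedding of the first token.
        """
        if isinstance(prompts, tuple):
            ids, mask = prompts
        else:
            if isinstance(prompts, str):
                prompts = [prompts]
            ids, mask = self.encode_ids(prompts)
        x = self.tok_emb(ids) + self.pos_emb(np.arange(ids.shape[1]))
        for i in range(self.config.depth):
            x = getattr(self, f"layer{i}")(x, key_mask=mask)
        tokens = self.proj(x)  # (B, L, shared_dim)
        pooled = tokens[:, 0, :]
        return pooled, tokens, mask


def apply_freeze_policy(encoder, freeze_mask) -> "Module":
    """Freeze the parameter groups selected by ``freeze_mask`` (True = frozen).

    Group 0 bundles the embedding layer(s) with the first block; group *i*
    is block *i*; the last group also holds the shared-space projection.
    Frozen parameters are excluded from optimiser updates and stay
    bit-identical across training.
    """
    groups = encoder.stage_groups()
    mask = tuple(bool(m) for m in freeze_mask)
    if len(mask) != len(groups):
        raise ConfigError(
            f"freeze_mask length {len(mask)} does not match encoder depth {len(groups)}"
        )
    for frozen, mods in zip(mask, groups):
        for mod in mods:
            for p in mod.parameters():
                p.frozen = frozen
    encoder.freeze_mask = mask
    return encoder


def trainable_parameter_count(module: Module) -> int:
    return sum(p.data.size for p in module.parameters() if not p.frozen)
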