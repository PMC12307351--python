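"""Attention-based feature reduction, classification head and composite loss.

The enhanced token sequences I* and T* are concatenated row-wise into a fused
matrix F (m × d), collapsed to a single d-vector by a self-attention
reduction,

    α = softmax(Q K^T / sqrt(d)),   F̂ = row-mean of α V,

and classified by a two-layer network (ReLU hidden layer, softmax output).
Training minimises the λ-weighted composite

    L = λ · (1 − cos(Ī*, T̄*)) + (1 − λ) · BCE(y, p_PD),

where Ī*, T̄* are the pooled enhanced features, p_PD the softmax probability
of the positive (PD) class, and λ defaults to 0.54.  The alignment term is
computed per sample and batch-averaged; probabilities entering the printed
BCE form are ε-clamped (ε = 1e-7) so the loss stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import AdamW, Tensor, concat
from .exceptions import ConfigError, NumericError, ValidationError
from .fusion import pooled_mean
from .nn import Linear, Module, multi_head_attention

__all__ = [
    "TrainConfig",
    "AttentionReduce",
    "ClassifierHead",
    "attention_reduce",
    "classify",
    "alignment_loss",
    "classification_loss",
    "total_loss",
    "train_full",
]

EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Supervised-phase hyperparameters.

    ``image_noise_sd`` adds fresh Gaussian jitter to every volume
    presentation, the same anti-memorisation augmentation used during
    contrastive pretraining (small cohorts are otherwise trivially separable
    by per-subject noise fingerprints).
    """

    lam: float = 0.54
    lr: float = 1e-5
    weight_decay: float = 1e-5
    batch_size: int = 32
    epochs: int = 30
    hidden: int = 256
    image_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ConfigError(f"lambda must lie in [0, 1], got {self.lam}")
        if self.image_noise_sd < 0:
            raise ConfigError("image_noise_sd must be non-negative")


class AttentionReduce(Module):
    """Single-head self-attention reduction of an m×d matrix to a d-vector."""

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.d = d
        self.wq = Linear(d, d, rng, bias=False)
        self.wk = Linear(d, d, rng, bias=False)
        self.wv = Linear(d, d, rng, bias=False)

    def __call__(self, F: Tensor, key_mask: np.ndarray | None = None,
                 return_weights: bool = False):
        if F.shape[-1] != self.d:
            raise ConfigError(f"expected width {self.d}, got {F.shape[-1]}")
        out = multi_head_attention(
            self.wq(F), self.wk(F), self.wv(F), 1,
            key_mask=key_mask, return_weights=return_weights,
        )
        if return_weights:
            attended, w = out
            return attended.mean(axis=-2), w[..., 0, :, :]
        return out.mean(axis=-2)


class ClassifierHead(Module):
    """Two-layer fully connected network with softmax output."""

    def __init__(self, d: int, hidden: int, rng: np.random.Generator, n_classes: int = 2):
        super().__init__()
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, n_classes, rng)

    def logits(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def __call__(self, x: Tensor) -> Tensor:
        return self.logits(x).softmax(axis=-1)


# ----------------------------------------------------------------- operations

def attention_reduce(F: np.ndarray, reducer: AttentionReduce) -> tuple[np.ndarray, np.ndarray]:
    """Reduce an (m, d) fused matrix to a d-vector; returns (F̂, α)."""
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 2 or F.shape[0] < 1:
        raise ValidationError(f"fused feature matrix must be non-empty 2-D, got {F.shape}")
    fhat, alpha = reducer(Tensor(F), return_weights=True)
    return fhat.data, alpha


def classify(f_hat: np.ndarray, head: ClassifierHead) -> np.ndarray:
    """Class-probability vector for a reduced feature vector (or batch)."""
    f_hat = np.asarray(f_hat, dtype=np.float64)
    if f_hat.shape[-1] != head.fc1.W.shape[0]:
        raise ConfigError(
            f"feature width {f_hat.shape[-1]} does not match head input "
            f"{head.fc1.W.shape[0]}"
        )
    return head(Tensor(f_hat)).data


def alignment_loss(I_star: np.ndarray, T_star: np.ndarray) -> float:
    """Cosine modality-alignment loss 1 − cos(I*, T*), in [0, 2]."""
    a = np.asarray(I_star, dtype=np.float64).ravel()
    b = np.asarray(T_star, dtype=np.float64).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise NumericError("alignment loss undefined for zero-norm features")
    return float(1.0 - (a @ b) / (na * nb))


def classification_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Binary cross-entropy −(1/N) Σ [y log p + (1−y) log(1−p)], ε-clamped."""
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.asarray(p, dtype=np.float64).ravel()
    if y.size == 0:
        raise ValidationError("classification loss needs at least one sample")
    if y.shape != p.shape:
        raise ValidationError(f"label/probability length mismatch: {y.size} vs {p.size}")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("labels must be binary (0/1)")
    pc = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))


def total_loss(a: float, c: float, lam: float = 0.54) -> float:
    """Composite objective λ·a + (1−λ)·c."""
    if not 0.0 <= lam <= 1.0:
        raise ConfigError(f"lambda must lie in [0, 1], got {lam}")
    return float(lam * a + (1.0 - lam) * c)


# --------------------------------------------------------------- tensor paths

def _alignment_loss_t(I_pooled: Tensor, T_pooled: Tensor) -> Tensor:
    """Batched differentiable 1 − cos, averaged over the batch."""
    ni = (I_pooled * I_pooled).sum(axis=-1, keepdims=True).pow(0.5)
    nt = (T_pooled * T_pooled).sum(axis=-1, keepdims=True).pow(0.5)
    cos = ((I_pooled * ni.pow(-1.0)) * (T_pooled * nt.pow(-1.0))).sum(axis=-1)
    return (1.0 - cos).mean()


def _bce_from_logits_t(y: np.ndarray, logits: Tensor) -> Tensor:
    """BCE on the positive-class softmax probability, computed in log space."""
    logp = logits - logits.logsumexp(axis=-1).reshape(-1, 1)
    yv = np.asarray(y, dtype=np.float64)
    picked = logp * np.stack([1.0 - yv, yv], axis=1)
    return -picked.sum(axis=-1).mean()


# ------------------------------------------------------------------- training

def forward_pass(batch_volumes, batch_prompts, image_encoder, text_encoder,
                 cma, reducer, head):
    """Shared forward path: encoders → CMA → pooled features → probabilities.

    Returns a dict of Tensors/arrays for loss computation and inspection.
    """
    _, I_tokens = image_encoder(batch_volumes)
    _, T_tokens, mask = text_encoder(batch_prompts)
    I_star, T_star, maps = cma(I_tokens, T_tokens, text_mask=mask)
    I_pooled = pooled_mean(I_star)
    T_pooled = pooled_mean(T_star, mask)
    fused = concat([I_star, T_star], axis=1)
    m_img = I_star.shape[1]
    key_mask = np.concatenate(
        [np.ones((mask.shape[0], m_img), dtype=bool), mask], axis=1
    )
    f_hat = reducer(fused, key_mask=key_mask)
    logits = head.logits(f_hat)
    return {
        "I_pooled": I_pooled,
        "T_pooled": T_pooled,
        "f_hat": f_hat,
        "logits": logits,
        "probs": logits.softmax(axis=-1),
        "maps": maps,
        "text_mask": mask,
    }


def train_full(dataset, image_encoder, text_encoder, cma, reducer, head,
               config: TrainConfig, rng: np.random.Generator | None = None) -> list[dict]:
    """End-to-end supervised fine-tuning with the λ-weighted composite loss.

    ``dataset`` provides aligned volumes, prompt sets and binary labels; one
    augmented prompt variant is sampled per subject per epoch.  All unfrozen
    encoder stages, the CMA block, the reduction and the head are optimised
    jointly with AdamW.  Returns the per-epoch (alignment, classification,
    total) loss trace.
    """
    from .scales import sample_training_prompt

    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = np.asarray(dataset.labels)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValidationError("training requires binary diagnosis labels")
    n = len(dataset.subject_ids)
    modules = [image_encoder, text_encoder, cma, reducer, head]
    params = [p for m in modules for p in m.parameters()]
    opt = AdamW(params, lr=config.lr, weight_decay=config.weight_decay)
    trace: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        prompts = [sample_training_prompt(dataset.prompt_sets[i], rng) for i in range(n)]
        sums = np.zeros(3)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            vols = dataset.volumes[idx]
            if config.image_noise_sd > 0:
                vols = vols + rng.normal(0.0, config.image_noise_sd, vols.shape)
            out = forward_pass(
                vols, [prompts[i] for i in idx],
                image_encoder, text_encoder, cma, reducer, head,
            )
            a = _alignment_loss_t(out["I_pooled"], out["T_pooled"])
            c = _bce_from_logits_t(labels[idx], out["logits"])
            loss = a * config.lam + c * (1.0 - config.lam)
            loss.backward()
            opt.step()
            sums += [a.item(), c.item(), loss.item()]
            n_batches += 1
        sums /= max(n_batches, 1)
        trace.append(
            {
                "epoch": epoch,
                "L_align": float(sums[0]),
                "L_cls": float(sums[1]),
                "L_total": float(sums[2]),
            }
        )
    return trace
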