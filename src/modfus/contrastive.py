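"""Symmetric temperature-scaled contrastive alignment of paired embeddings.

Given a batch of B matched (text, image) embedding pairs, the B×B cosine
similarity matrix S is sharpened by a temperature τ and scored with two
directional InfoNCE-style losses,

    L_t→i = Σ_b −log[ exp(S[b,b]/τ) / Σ_k exp(S[b,k]/τ) ]   (rows: text)
    L_i→t = Σ_b −log[ exp(S[b,b]/τ) / Σ_k exp(S[k,b]/τ) ]   (columns: image)

whose average L = (L_t→i + L_i→t)/2 is minimised during encoder pretraining.
The printed form is a *sum* over the batch; ``reduction="mean"`` divides by B
for batch-size-invariant training.  All softmax/log-sum-exp computations use
max-subtraction for numerical stability, and embeddings are *not*
pre-normalised — the cosine kernel is computed explicitly.

``pretrain`` runs the mini-batch training loop over paired (prompt, volume)
data, sampling one augmented prompt variant per subject per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import AdamW, Tensor
from .exceptions import ConfigError, NumericError
from .scales import sample_training_prompt

__all__ = [
    "SimilarityMatrix",
    "ContrastiveConfig",
    "cosine_matrix",
    "loss_text_to_image",
    "loss_image_to_text",
    "contrastive_loss",
    "contrastive_objective_with_grad",
    "pretrain",
]

_MIN_TAU = 1e-4


@dataclass(frozen=True)
class SimilarityMatrix:
    """B×B cosine similarities between text rows and image columns."""

    S: np.ndarray
    tau: float = 0.1

    def __post_init__(self):
        S = np.asarray(self.S, dtype=np.float64)
        if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] < 1:
            raise NumericError(f"similarity matrix must be square, got {S.shape}")
        if not np.isfinite(S).all():
            raise NumericError("similarity matrix contains non-finite entries")
        if (np.abs(S) > 1.0 + 1e-9).any():
            raise NumericError("cosine similarities must lie in [-1, 1]")
        if self.tau <= 0:
            raise ConfigError("temperature must be positive")
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "tau", max(float(self.tau), _MIN_TAU))

    @property
    def batch_size(self) -> int:
        return self.S.shape[0]


@dataclass(frozen=True)
class ContrastiveConfig:
    """Pretraining-loop hyperparameters.

    ``image_noise_sd`` adds fresh Gaussian jitter to the volumes at every
    presentation — the standard contrastive-learning augmentation that stops
    the image encoder from memorising per-subject noise fingerprints instead
    of the shared anatomy/severity signal.  Set it to 0 to disable.
    """

    tau: float = 0.1
    batch_size: int = 32
    epochs: int = 20
    lr: float = 1e-5
    weight_decay: float = 1e-5
    reduction: str = "sum"
    image_noise_sd: float = 0.2

    def __post_init__(self):
        if self.tau <= 0:
            raise ConfigError("tau must be positive")
        if self.reduction not in ("sum", "mean"):
            raise ConfigError("reduction must be 'sum' or 'mean'")
        if self.image_noise_sd < 0:
            raise ConfigError("image_noise_sd must be non-negative")


# ------------------------------------------------------------------- numerics

def _as_matrix(S) -> tuple[np.ndarray, float]:
    if isinstance(S, SimilarityMatrix):
        return S.S, S.tau
    return np.asarray(S, dtype=np.float64), None


def cosine_matrix(F_t: np.ndarray, F_i: np.ndarray, tau: float = 0.1) -> SimilarityMatrix:
    """Pairwise cosine similarities S[b, k] = cos(f_tb, f_ik)."""
    F_t = np.asarray(F_t, dtype=np.float64)
    F_i = np.asarray(F_i, dtype=np.float64)
    if F_t.shape != F_i.shape or F_t.ndim != 2:
        raise NumericError(f"embedding batches must match: {F_t.shape} vs {F_i.shape}")
    for name, F in (("text", F_t), ("image", F_i)):
        norms = np.linalg.norm(F, axis=1)
        bad = np.where(norms == 0)[0]
        if bad.size:
            raise NumericError(f"zero-norm {name} embedding at row {bad[0]}")
    Tn = F_t / np.linalg.norm(F_t, axis=1, keepdims=True)
    In = F_i / np.linalg.norm(F_i, axis=1, keepdims=True)
    S = np.clip(Tn @ In.T, -1.0, 1.0)
    return SimilarityMatrix(S, tau)


def _directional_loss(S: np.ndarray, tau: float, axis: int, reduction: str) -> float:
    """−Σ_b log softmax_axis(S/τ)[b, b]; axis=1 is text→image (rows)."""
    if not np.isfinite(S).all():
        raise NumericError("similarity matrix contains non-finite entries")
    Z = S / tau
    m = Z.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(Z - m).sum(axis=axis, keepdims=True)).squeeze(axis) + m.squeeze(axis)
    per_row = lse - np.diag(Z)
    return float(per_row.mean() if reduction == "mean" else per_row.sum())


def loss_text_to_image(S, tau: float | None = None, reduction: str = "sum") -> float:
    """Text→image contrastive loss (rows of S index text, columns image)."""
    M, t = _as_matrix(S)
    tau = t if tau is None else max(float(tau), _MIN_TAU)
    return _directional_loss(M, tau, axis=1, reduction=reduction)


def loss_image_to_text(S, tau: float | None = None, reduction: str = "sum") -> float:
    """Image→text contrastive loss (softmax over rows for each column)."""
    M, t = _as_matrix(S)
    tau = t if tau is None else max(float(tau), _MIN_TAU)
    return _directional_loss(M, tau, axis=0, reduction=reduction)


def contrastive_loss(S, tau: float | None = None, reduction: str = "sum") -> float:
    """Average of the two directional losses."""
    return 0.5 * (
        loss_text_to_image(S, tau, reduction) + loss_image_to_text(S, tau, reduction)
    )


def contrastive_objective_with_grad(S: np.ndarray, tau: float) -> tuple[float, np.ndarray]:
    """Value and exact gradient of L_t→i + L_i→t with respect to S.

    The gradient is produced by reverse-mode differentiation of the stabilised
    objective, suitable for checking against finite differences.
    """
    St = Tensor(np.asarray(S, dtype=np.float64), requires_grad=True)
    loss = _contrastive_loss_t(St, tau, reduction="sum", average=False)
    loss.backward()
    return loss.item(), St.grad


# --------------------------------------------------------------- tensor paths

def _cosine_matrix_t(F_t: Tensor, F_i: Tensor) -> Tensor:
    nt = (F_t * F_t).sum(axis=1, keepdims=True).pow(0.5)
    ni = (F_i * F_i).sum(axis=1, keepdims=True).pow(0.5)
    if (nt.data == 0).any() or (ni.data == 0).any():
        raise NumericError("zero-norm embedding in batch")
    return (F_t * nt.pow(-1.0)) @ (F_i * ni.pow(-1.0)).transpose(1, 0)


def _contrastive_loss_t(S: Tensor, tau: float, reduction: str = "sum",
                        average: bool = True) -> Tensor:
    """Differentiable Eq-style loss on a similarity Tensor."""
    B = S.shape[0]
    Z = S * (1.0 / max(tau, _MIN_TAU))
    diag = Z[np.arange(B), np.arange(B)]
    rows = Z.logsumexp(axis=1) - diag
    cols = Z.transpose(1, 0).logsumexp(axis=1) - diag
    total = (rows + cols).mean() if reduction == "mean" else (rows + cols).sum()
    return total * 0.5 if average else total


# ------------------------------------------------------------------- training

def pretrain(dataset, image_encoder, text_encoder, config: ContrastiveConfig,
             seed: int = 0) -> list[dict]:
    """Contrastively pretrain both encoders on paired (prompt, volume) data.

    One augmented prompt variant is sampled per subject per epoch; batches
    are reshuffled every epoch with the seeded generator.  Returns the per-epoch
    loss trace as a list of dicts (epoch, L_t2i, L_i2t, L_total) on the
    configured reduction scale, averaged over batches.
    """
    import warnings

    rng = np.random.default_rng(seed)
    n = len(dataset.subject_ids)
    params = [p for p in image_encoder.parameters() + text_encoder.parameters()]
    opt = AdamW(params, lr=config.lr, weight_decay=config.weight_decay)
    trace: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        prompts = [sample_training_prompt(dataset.prompt_sets[i], rng) for i in range(n)]
        sums = np.zeros(2)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if idx.size < 2:
                warnings.warn("skipping contrastive batch of size 1 (no negatives)")
                continue
            opt.zero_grad()
            vols = dataset.volumes[idx]
            if config.image_noise_sd > 0:
                vols = vols + rng.normal(0.0, config.image_noise_sd, vols.shape)
            f_i, _ = image_encoder(vols)
            f_t, _, _ = text_encoder([prompts[i] for i in idx])
            S = _cosine_matrix_t(f_t, f_i)
            Z = S * (1.0 / max(config.tau, _MIN_TAU))
            diag = Z[np.arange(idx.size), np.arange(idx.size)]
            rows = Z.logsumexp(axis=1) - diag
            cols = Z.transpose(1, 0).logsumexp(axis=1) - diag
            if config.reduction == "mean":
                l_t2i, l_i2t = rows.mean(), cols.mean()
            else:
                l_t2i, l_i2t = rows.sum(), cols.sum()
            loss = (l_t2i + l_i2t) * 0.5
            loss.backward()
            opt.step()
            sums += [l_t2i.item(), l_i2t.item()]
            n_batches += 1
        if n_batches:
            sums /= n_batches
        trace.append(
            {
                "epoch": epoch,
                "L_t2i": float(sums[0]),
                "L_i2t": float(sums[1]),
                "L_total": float(sums.mean()),
            }
        )
    return trace
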