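"""Scikit-learn style estimators tying the full pipeline together.

:class:`MultimodalFusionClassifier` is the complete method — contrastive
encoder pretraining, bidirectional cross-modal attention fusion, attention
reduction and the λ-weighted composite objective.
:class:`EarlyFusionClassifier` is the standard early-concatenation baseline:
the same encoders, pooled embeddings concatenated straight into the head,
binary cross-entropy only.  Both follow the estimator protocol (``fit`` /
``predict`` / ``predict_proba`` / ``get_params``) and compose with sklearn
model selection; fitted state lives in trailing-underscore attributes.

``X`` for both estimators is either a :class:`~modfus.cohort.MultimodalDataset`
(labels taken from it when ``y`` is None) or a sequence of
``(volume, PromptSet)`` pairs with ``y`` supplied separately.  Inference uses
the deterministic template prompt (variant 0) for every scale.

Defaults follow the published configuration where one exists (τ = 0.1,
λ = 0.54, 8 attention heads, depth-1 CMA, 512-d shared space, N = 8 prompt
variants); the optimiser learning rate defaults to 1e-3, the standard choice
for training the tiny presets from scratch (the published 1e-5 is a
fine-tuning rate for large pretrained backbones and is available via
``lr=1e-5``).
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._tensor import AdamW
from .classify import (
    AttentionReduce,
    ClassifierHead,
    TrainConfig,
    _bce_from_logits_t,
    forward_pass,
    train_full,
)
from .cohort import MultimodalDataset
from .contrastive import ContrastiveConfig, pretrain
from .encoders import (
    EncoderConfig,
    ImageEncoder,
    TextEncoder,
    Vocab,
    build_vocab,
)
from .exceptions import ValidationError
from .fusion import CrossModalAttention
from .scales import PromptSet

__all__ = ["MultimodalFusionClassifier", "EarlyFusionClassifier", "save_model", "load_model"]


def _coerce_dataset(X, y=None, require_labels: bool = False) -> MultimodalDataset:
    from .cohort import replace_dataset

    if isinstance(X, MultimodalDataset):
        if X.prompt_sets is None:
            raise ValidationError(
                "dataset has no prompt sets; call .with_prompts(...) first"
            )
        if y is not None:
            return replace_dataset(X, labels=np.asarray(y, dtype=int))
        return X
    volumes, prompts = [], []
    for vol, ps in X:
        if not isinstance(ps, PromptSet):
            raise ValidationError("each X element must be a (volume, PromptSet) pair")
        volumes.append(np.asarray(vol, dtype=np.float64))
        prompts.append(ps)
    if y is None:
        if require_labels:
            raise ValidationError("y is required when X is not a MultimodalDataset")
        labels = np.zeros(len(volumes), dtype=int)
    else:
        labels = np.asarray(y, dtype=int)
    ids = [ps.subject_id for ps in prompts]
    return MultimodalDataset(
        subject_ids=ids,
        volumes=np.stack(volumes),
        records=[None] * len(ids),
        labels=labels,
        prompt_sets=prompts,
    )


def _corpus(dataset: MultimodalDataset) -> list[str]:
    corpus = []
    for ps in dataset.prompt_sets:
        for sid in ps.scale_ids:
            corpus.extend(ps.variants[sid])
    return corpus


class _EncoderMixin:
    """Shared construction of the two modality encoders."""

    def _build_encoders(self, dataset: MultimodalDataset, seed: int):
        vocab = build_vocab(
            _corpus(dataset), min_count=1, provenance=frozenset(dataset.subject_ids)
        )
        img_cfg = EncoderConfig(
            modality="image",
            d_model=self.d_model,
            depth=self.image_stages,
            n_heads=self.encoder_heads,
            shared_dim=self.shared_dim,
            patch_size=self.patch_size,
            freeze_mask=self.image_freeze_mask,
            seed=seed,
        )
        txt_cfg = EncoderConfig(
            modality="text",
            d_model=self.d_model,
            depth=self.text_layers,
            n_heads=self.encoder_heads,
            shared_dim=self.shared_dim,
            max_len=self.max_len,
            freeze_mask=self.text_freeze_mask,
            seed=seed + 1,
        )
        return vocab, ImageEncoder(img_cfg), TextEncoder(txt_cfg, vocab)

    def _inference_prompts(self, dataset: MultimodalDataset) -> list[str]:
        return [
            " ".join(ps.sentences[sid] for sid in ps.scale_ids)
            for ps in dataset.prompt_sets
        ]


class MultimodalFusionClassifier(_EncoderMixin, ClassifierMixin, BaseEstimator):
    """Contrastive alignment + cross-modal attention fusion classifier."""

    def __init__(
        self,
        shared_dim: int = 512,
        d_model: int = 32,
        image_stages: int = 2,
        text_layers: int = 2,
        encoder_heads: int = 4,
        heads: int = 8,
        cma_depth: int = 1,
        cma_residual: bool = True,
        tau: float = 0.1,
        lam: float = 0.54,
        hidden: int = 256,
        patch_size: int = 8,
        max_len: int = 64,
        pretrain: bool = True,
        pretrain_epochs: int = 15,
        epochs: int = 20,
        batch_size: int = 32,
        lr: float = 1e-3,
        weight_decay: float = 1e-4,
        reduction: str = "mean",
        image_noise_sd: float = 0.2,
        image_freeze_mask: tuple | None = None,
        text_freeze_mask: tuple | None = None,
        pretrained_state: dict | None = None,
        random_state: int = 0,
    ):
        self.shared_dim = shared_dim
        self.d_model = d_model
        self.image_stages = image_stages
        self.text_layers = text_layers
        self.encoder_heads = encoder_heads
        self.heads = heads
        self.cma_depth = cma_depth
        self.cma_residual = cma_residual
        self.tau = tau
        self.lam = lam
        self.hidden = hidden
        self.patch_size = patch_size
        self.max_len = max_len
        self.pretrain = pretrain
        self.pretrain_epochs = pretrain_epochs
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.reduction = reduction
        self.image_noise_sd = image_noise_sd
        self.image_freeze_mask = image_freeze_mask
        self.text_freeze_mask = text_freeze_mask
        self.pretrained_state = pretrained_state
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None):
        dataset = _coerce_dataset(X, y, require_labels=True)
        labels = np.asarray(dataset.labels, dtype=int)
        self.classes_ = np.unique(labels)
        seed = int(self.random_state)
        if self.pretrained_state is not None:
            vocab = Vocab(
                token_to_id=dict(self.pretrained_state["vocab"]),
                provenance=frozenset(self.pretrained_state.get("provenance", ())),
            )
            _, img_enc, txt_enc = self._build_encoders(dataset, seed)
            txt_enc = TextEncoder(txt_enc.config, vocab)
            img_enc.load_state_dict(self.pretrained_state["image"])
            txt_enc.load_state_dict(self.pretrained_state["text"])
            self.pretrain_trace_ = list(self.pretrained_state.get("trace", []))
        else:
            vocab, img_enc, txt_enc = self._build_encoders(dataset, seed)
            self.pretrain_trace_ = []
            if self.pretrain:
                self.pretrain_trace_ = pretrain(
                    dataset,
                    img_enc,
                    txt_enc,
                    ContrastiveConfig(
                        tau=self.tau,
                        batch_size=self.batch_size,
                        epochs=self.pretrain_epochs,
                        lr=self.lr,
                        weight_decay=self.weight_decay,
                        reduction=self.reduction,
                        image_noise_sd=self.image_noise_sd,
                    ),
                    seed=seed,
                )
        rng = np.random.default_rng(seed + 10_000)
        cma = CrossModalAttention(
            d_model=self.shared_dim, heads=self.heads, depth=self.cma_depth,
            residual=self.cma_residual, seed=seed + 2,
        )
        reducer = AttentionReduce(self.shared_dim, np.random.default_rng(seed + 3))
        head = ClassifierHead(self.shared_dim, self.hidden, np.random.default_rng(seed + 4))
        self.train_trace_ = train_full(
            dataset, img_enc, txt_enc, cma, reducer, head,
            TrainConfig(
                lam=self.lam,
                lr=self.lr,
                weight_decay=self.weight_decay,
                batch_size=self.batch_size,
                epochs=self.epochs,
                hidden=self.hidden,
                image_noise_sd=self.image_noise_sd,
                seed=seed,
            ),
            rng=rng,
        )
        self.vocab_ = vocab
        self.image_encoder_ = img_enc
        self.text_encoder_ = txt_enc
        self.cma_ = cma
        self.reduce_ = reducer
        self.head_ = head
        self.provenance_ = frozenset(dataset.subject_ids) | vocab.provenance
        return self

    # ------------------------------------------------------------ inference
    def _forward(self, X):
        dataset = _coerce_dataset(X)
        prompts = self._inference_prompts(dataset)
        return forward_pass(
            dataset.volumes, prompts,
            self.image_encoder_, self.text_encoder_,
            self.cma_, self.reduce_, self.head_,
        )

    def predict_proba(self, X) -> np.ndarray:
        return self._forward(X)["probs"].data

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def decision_scores(self, X) -> np.ndarray:
        """Positive-class (PD) probability, the score used for AUC."""
        return self.predict_proba(X)[:, 1]

    def attention_maps(self, X):
        """Per-layer bidirectional attention maps for the given subjects."""
        return self._forward(X)["maps"]


class EarlyFusionClassifier(_EncoderMixin, ClassifierMixin, BaseEstimator):
    """Early-concatenation baseline: pooled embeddings → two-layer head.

    No contrastive pretraining and no cross-modal attention; the pooled image
    and text embeddings are concatenated and classified with binary
    cross-entropy, at the same epoch budget as the full model.
    """

    def __init__(
        self,
        shared_dim: int = 512,
        d_model: int = 32,
        image_stages: int = 2,
        text_layers: int = 2,
        encoder_heads: int = 4,
        hidden: int = 256,
        patch_size: int = 8,
        max_len: int = 64,
        epochs: int = 20,
        batch_size: int = 32,
        lr: float = 1e-3,
        weight_decay: float = 1e-4,
        image_noise_sd: float = 0.2,
        image_freeze_mask: tuple | None = None,
        text_freeze_mask: tuple | None = None,
        random_state: int = 0,
    ):
        self.shared_dim = shared_dim
        self.d_model = d_model
        self.image_stages = image_stages
        self.text_layers = text_layers
        self.encoder_heads = encoder_heads
        self.hidden = hidden
        self.patch_size = patch_size
        self.max_len = max_len
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.image_noise_sd = image_noise_sd
        self.image_freeze_mask = image_freeze_mask
        self.text_freeze_mask = text_freeze_mask
        self.random_state = random_state

    def fit(self, X, y=None):
        from .scales import sample_training_prompt

        dataset = _coerce_dataset(X, y, require_labels=True)
        labels = np.asarray(dataset.labels, dtype=int)
        self.classes_ = np.unique(labels)
        seed = int(self.random_state)
        vocab, img_enc, txt_enc = self._build_encoders(dataset, seed)
        head = ClassifierHead(
            2 * self.shared_dim, self.hidden, np.random.default_rng(seed + 4)
        )
        rng = np.random.default_rng(seed + 10_000)
        params = img_enc.parameters() + txt_enc.parameters() + head.parameters()
        opt = AdamW(params, lr=self.lr, weight_decay=self.weight_decay)
        n = len(dataset)
        self.train_trace_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            prompts = [
                sample_training_prompt(dataset.prompt_sets[i], rng) for i in range(n)
            ]
            total, n_batches = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                opt.zero_grad()
                vols = dataset.volumes[idx]
                if self.image_noise_sd > 0:
                    vols = vols + rng.normal(0.0, self.image_noise_sd, vols.shape)
                f_i, _ = img_enc(vols)
                f_t, _, _ = txt_enc([prompts[i] for i in idx])
                from ._tensor import concat

                fused = concat([f_i, f_t], axis=1)
                logits = head.logits(fused)
                loss = _bce_from_logits_t(labels[idx], logits)
                loss.backward()
                opt.step()
                total += loss.item()
                n_batches += 1
            self.train_trace_.append(
                {"epoch": epoch, "L_cls": total / max(n_batches, 1)}
            )
        self.vocab_ = vocab
        self.image_encoder_ = img_enc
        self.text_encoder_ = txt_enc
        self.head_ = head
        self.provenance_ = frozenset(dataset.subject_ids) | vocab.provenance
        return self

    def predict_proba(self, X) -> np.ndarray:
        from ._tensor import concat

        dataset = _coerce_dataset(X)
        prompts = self._inference_prompts(dataset)
        f_i, _ = self.image_encoder_(dataset.volumes)
        f_t, _, _ = self.text_encoder_(prompts)
        return self.head_(concat([f_i, f_t], axis=1)).data

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def decision_scores(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]


# -------------------------------------------------------------- persistence

def save_model(est: MultimodalFusionClassifier, path) -> None:
    """Serialise a fitted fusion model to a single .npz archive."""
    arrays: dict[str, np.ndarray] = {}
    for name, module in (
        ("image", est.image_encoder_),
        ("text", est.text_encoder_),
        ("cma", est.cma_),
        ("reduce", est.reduce_),
        ("head", est.head_),
    ):
        for pname, arr in module.state_dict().items():
            arrays[f"{name}:{pname}"] = arr
    meta = {
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in est.get_params().items()
            if k != "pretrained_state"
        },
        "vocab": est.vocab_.token_to_id,
        "provenance": sorted(est.provenance_),
        "classes": est.classes_.tolist(),
    }
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> MultimodalFusionClassifier:
    """Restore a model saved by :func:`save_model`."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
    params = meta["params"]
    for key in ("image_freeze_mask", "text_freeze_mask"):
        if params.get(key) is not None:
            params[key] = tuple(params[key])
    est = MultimodalFusionClassifier(**params)
    vocab = Vocab(
        token_to_id=meta["vocab"], provenance=frozenset(meta["provenance"])
    )
    seed = int(params["random_state"])
    img_cfg = EncoderConfig(
        modality="image", d_model=params["d_model"], depth=params["image_stages"],
        n_heads=params["encoder_heads"], shared_dim=params["shared_dim"],
        patch_size=params["patch_size"], seed=seed,
    )
    txt_cfg = EncoderConfig(
        modality="text", d_model=params["d_model"], depth=params["text_layers"],
        n_heads=params["encoder_heads"], shared_dim=params["shared_dim"],
        max_len=params["max_len"], seed=seed + 1,
    )
    est.vocab_ = vocab
    est.image_encoder_ = ImageEncoder(img_cfg)
    est.text_encoder_ = TextEncoder(txt_cfg, vocab)
    est.cma_ = CrossModalAttention(
        d_model=params["shared_dim"], heads=params["heads"],
        depth=params["cma_depth"], residual=params.get("cma_residual", True),
        seed=seed + 2,
    )
    est.reduce_ = AttentionReduce(params["shared_dim"], np.random.default_rng(seed + 3))
    est.head_ = ClassifierHead(
        params["shared_dim"], params["hidden"], np.random.default_rng(seed + 4)
    )
    groups = {
        "image": est.image_encoder_,
        "text": est.text_encoder_,
        "cma": est.cma_,
        "reduce": est.reduce_,
        "head": est.head_,
    }
    states: dict[str, dict[str, np.ndarray]] = {k: {} for k in groups}
    for key, arr in arrays.items():
        mod, pname = key.split(":", 1)
        states[mod][pname] = arr
    for mod, module in groups.items():
        module.load_state_dict(states[mod])
    est.classes_ = np.asarray(meta["classes"])
    est.provenance_ = frozenset(meta["provenance"])
    return est
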