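"""Attention reduction, classification head and composite-loss contracts."""

import numpy as np
import pytest

from modfus._tensor import Tensor
from modfus.classify import (
    AttentionReduce,
    ClassifierHead,
    TrainConfig,
    _alignment_loss_t,
    _bce_from_logits_t,
    alignment_loss,
    attention_reduce,
    classification_loss,
    classify,
    forward_pass,
    total_loss,
    train_full,
)
from modfus.exceptions import ConfigError, NumericError, ValidationError

RNG = np.random.default_rng(21)


def reduce_oracle(F, Wq, Wk, Wv):
    """Explicit-loop softmax self-attention reduction."""
    Q, K, V = F @ Wq, F @ Wk, F @ Wv
    m, d = F.shape
    alpha = np.zeros((m, m))
    for i in range(m):
        logits = np.array([Q[i] @ K[j] / np.sqrt(d) for j in range(m)])
        e = np.exp(logits - logits.max())
        alpha[i] = e / e.sum()
    attended = alpha @ V
    return attended.mean(axis=0), alpha


class TestAttentionReduce:
    def _reducer(self, d, seed=0):
        return AttentionReduce(d, np.random.default_rng(seed))

    def test_single_token_identity_projection_returns_token(self):
        red = self._reducer(4)
        for name in ("wq", "wk", "wv"):
            getattr(red, name).W.data = np.eye(4)
        F = RNG.normal(size=(1, 4))
        fhat, alpha = attention_reduce(F, red)
        assert np.allclose(fhat, F[0])
        assert np.allclose(alpha, 1.0)

    def test_alpha_rows_sum_to_one(self):
        fhat, alpha = attention_reduce(RNG.normal(size=(5, 6)), self._reducer(6))
        assert np.allclose(alpha.sum(axis=1), 1.0)

    def test_matches_explicit_loop_oracle(self):
        red = self._reducer(8, seed=4)
        for _ in range(10):
            F = RNG.normal(size=(4, 8))
            fhat, alpha = attention_reduce(F, red)
            o_fhat, o_alpha = reduce_oracle(
                F, red.wq.W.data, red.wk.W.data, red.wv.W.data
            )
            assert np.allclose(fhat, o_fhat, atol=1e-6)
            assert np.allclose(alpha, o_alpha, atol=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            attention_reduce(np.zeros((0, 4)), self._reducer(4))


class TestClassifierHead:
    def test_probabilities_sum_to_one(self):
        head = ClassifierHead(6, 4, np.random.default_rng(0))
        p = classify(RNG.normal(size=(3, 6)), head)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_weights_give_uniform_probabilities(self):
        head = ClassifierHead(6, 4, np.random.default_rng(0))
        for _, param in head.named_parameters():
            param.data = np.zeros_like(param.data)
        p = classify(RNG.normal(size=(2, 6)), head)
        assert np.allclose(p, 0.5)

    def test_widening_logit_gap_increases_max_probability(self):
        head = ClassifierHead(2, 2, np.random.default_rng(0))
        logits = Tensor(np.array([[0.0, 1.0]]))
        p1 = logits.softmax(axis=-1).data.max()
        p2 = (logits * 2.0).softmax(axis=-1).data.max()
        assert p2 > p1

    def test_width_mismatch_rejected(self):
        head = ClassifierHead(6, 4, np.random.default_rng(0))
        with pytest.raises(ConfigError):
            classify(RNG.normal(size=(2, 5)), head)


class TestAlignmentLoss:
    def test_extreme_geometries(self):
        v = RNG.normal(size=8)
        assert alignment_loss(v, v) == pytest.approx(0.0)
        assert alignment_loss(v, -v) == pytest.approx(2.0)
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 1.0])
        assert alignment_loss(a, b) == pytest.approx(1.0)

    def test_invariant_to_positive_rescaling(self):
        a, b = RNG.normal(size=8), RNG.normal(size=8)
        assert alignment_loss(a, b) == pytest.approx(alignment_loss(3.7 * a, 0.2 * b))

    def test_range_bound(self):
        for _ in range(50):
            val = alignment_loss(RNG.normal(size=5), RNG.normal(size=5))
            assert 0.0 <= val <= 2.0

    def test_zero_norm_rejected(self):
        with pytest.raises(NumericError):
            alignment_loss(np.zeros(4), np.ones(4))

    def test_batched_tensor_path_matches_per_sample_mean(self):
        A = RNG.normal(size=(6, 5))
        B = RNG.normal(size=(6, 5))
        expected = np.mean([alignment_loss(a, b) for a, b in zip(A, B)])
        assert _alignment_loss_t(Tensor(A), Tensor(B)).item() == pytest.approx(expected)


class TestClassificationLoss:
    def test_ln2_at_coin_flip(self):
        assert classification_loss([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2))

    def test_confident_correct_is_near_zero(self):
        assert classification_loss([1], [1 - 1e-7]) == pytest.approx(0.0, abs=1e-6)

    def test_clamped_never_infinite(self):
        val = classification_loss([0], [1.0])
        assert np.isfinite(val) and val > 10

    def test_matches_per_sample_loop_oracle(self):
        y = RNG.integers(0, 2, size=1000)
        p = RNG.uniform(1e-6, 1 - 1e-6, size=1000)
        loop = -np.mean(
            [yi * np.log(pi) + (1 - yi) * np.log(1 - pi) for yi, pi in zip(y, p)]
        )
        assert classification_loss(y, p) == pytest.approx(loop, abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            classification_loss([], [])

    def test_logit_path_equals_probability_path(self):
        logits = RNG.normal(size=(16, 2))
        y = RNG.integers(0, 2, size=16)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        p_pos = (e / e.sum(axis=1, keepdims=True))[:, 1]
        assert _bce_from_logits_t(y, Tensor(logits)).item() == pytest.approx(
            classification_loss(y, p_pos), abs=1e-9
        )


class TestTotalLoss:
    @pytest.mark.parametrize(
        "lam,a,c,expected", [(0.0, 1.3, 0.5, 0.5), (1.0, 1.3, 0.5, 1.3),
                             (0.54, 1.0, 0.5, 0.77)]
    )
    def test_affine_combination(self, lam, a, c, expected):
        assert total_loss(a, c, lam) == pytest.approx(expected)

    def test_exactly_linear_in_lambda(self):
        a, c = 1.7, 0.3
        lams = np.linspace(0, 1, 11)
        vals = np.array([total_loss(a, c, l) for l in lams])
        slopes = np.diff(vals) / np.diff(lams)
        assert np.allclose(slopes, slopes[0])

    def test_lambda_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigError):
            total_loss(1.0, 1.0, 1.2)
        with pytest.raises(ConfigError):
            TrainConfig(lam=-0.1)


class TestTrainFull:
    def _modules(self, dataset, shared=32):
        from modfus.encoders import EncoderConfig, ImageEncoder, TextEncoder, build_vocab
        from modfus.fusion import CrossModalAttention

        corpus = [
            v for ps in dataset.prompt_sets for s in ps.scale_ids
            for v in ps.variants[s]
        ]
        vocab = build_vocab(corpus, provenance=frozenset(dataset.subject_ids))
        img = ImageEncoder(
            EncoderConfig(modality="image", d_model=16, depth=1, n_heads=2,
                          shared_dim=shared, seed=0)
        )
        txt = TextEncoder(
            EncoderConfig(modality="text", d_model=16, depth=1, n_heads=2,
                          shared_dim=shared, max_len=48, seed=1),
            vocab,
        )
        cma = CrossModalAttention(d_model=shared, heads=2, depth=1,
                                  residual=True, seed=2)
        red = AttentionReduce(shared, np.random.default_rng(3))
        head = ClassifierHead(shared, 16, np.random.default_rng(4))
        return img, txt, cma, red, head

    def test_loss_decreases_and_runs_are_reproducible(self, tiny_cohort):
        results = []
        for _ in range(2):
            mods = self._modules(tiny_cohort)
            cfg = TrainConfig(lam=0.54, lr=1e-3, batch_size=8, epochs=4, seed=9)
            trace = train_full(tiny_cohort, *mods, cfg)
            results.append(trace)
        assert results[0] == results[1]
        assert results[0][-1]["L_total"] < results[0][0]["L_total"]

    def test_lambda_zero_gradients_ignore_alignment(self, tiny_cohort):
        """With λ=0 the parameter gradients equal those of BCE alone."""
        mods = self._modules(tiny_cohort)
        img, txt, cma, red, head = mods
        params = [p for m in mods for p in m.parameters()]
        out = forward_pass(
            tiny_cohort.volumes[:8],
            [" ".join(ps.sentences[s] for s in ps.scale_ids)
             for ps in tiny_cohort.prompt_sets[:8]],
            img, txt, cma, red, head,
        )
        a = _alignment_loss_t(out["I_pooled"], out["T_pooled"])
        c = _bce_from_logits_t(tiny_cohort.labels[:8], out["logits"])
        (a * 0.0 + c * 1.0).backward()
        grads_total = [None if p.grad is None else p.grad.copy() for p in params]
        for p in params:
            p.grad = None
        out = forward_pass(
            tiny_cohort.volumes[:8],
            [" ".join(ps.sentences[s] for s in ps.scale_ids)
             for ps in tiny_cohort.prompt_sets[:8]],
            img, txt, cma, red, head,
        )
        _bce_from_logits_t(tiny_cohort.labels[:8], out["logits"]).backward()
        for g_tot, p in zip(grads_total, params):
            if g_tot is None:
                assert p.grad is None
            else:
                assert np.allclose(g_tot, p.grad, atol=1e-12)

    def test_unlabeled_dataset_rejected(self, tiny_cohort, scale_defs):
        from modfus.cohort import replace_dataset

        bad = replace_dataset(
            tiny_cohort, labels=np.full(len(tiny_cohort), 2, dtype=int)
        )
        mods = self._modules(tiny_cohort)
        with pytest.raises(ValidationError):
            train_full(bad, *mods, TrainConfig(epochs=1, batch_size=8))
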