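"""Closed forms, oracle equivalence and invariances of the contrastive losses."""

import numpy as np
import pytest

from modfus.contrastive import (
    ContrastiveConfig,
    SimilarityMatrix,
    contrastive_loss,
    contrastive_objective_with_grad,
    cosine_matrix,
    loss_image_to_text,
    loss_text_to_image,
    pretrain,
)
from modfus.encoders import EncoderConfig, ImageEncoder, TextEncoder, build_vocab
from modfus.exceptions import ConfigError, NumericError

RNG = np.random.default_rng(3)


def brute_force_cosine(F_t, F_i):
    B = len(F_t)
    S = np.empty((B, B))
    for b in range(B):
        for k in range(B):
            S[b, k] = F_t[b] @ F_i[k] / (
                np.linalg.norm(F_t[b]) * np.linalg.norm(F_i[k])
            )
    return S


def brute_force_t2i(S, tau):
    total = 0.0
    B = len(S)
    for b in range(B):
        denom = sum(np.exp(S[b, k] / tau) for k in range(B))
        total += -np.log(np.exp(S[b, b] / tau) / denom)
    return total


class TestCosineMatrix:
    def test_matched_unit_rows_give_unit_diagonal(self):
        F = np.eye(3)
        assert np.allclose(np.diag(cosine_matrix(F, F).S), 1.0)

    def test_orthogonal_pair_gives_zero(self):
        F_t = np.array([[1.0, 0.0], [1.0, 1.0]])
        F_i = np.array([[0.0, 1.0], [1.0, 1.0]])
        assert abs(cosine_matrix(F_t, F_i).S[0, 0]) < 1e-12

    def test_matches_per_pair_loop_oracle(self):
        F_t = RNG.normal(size=(3, 4))
        F_i = RNG.normal(size=(3, 4))
        assert np.allclose(cosine_matrix(F_t, F_i).S, brute_force_cosine(F_t, F_i))

    def test_zero_norm_row_named(self):
        F = np.ones((3, 4))
        F_bad = F.copy()
        F_bad[1] = 0.0
        with pytest.raises(NumericError, match="row 1"):
            cosine_matrix(F, F_bad)

    def test_entries_validated(self):
        with pytest.raises(NumericError):
            SimilarityMatrix(np.array([[2.0]]))
        with pytest.raises(ConfigError):
            SimilarityMatrix(np.array([[0.5]]), tau=-1.0)


class TestClosedForms:
    def test_batch_of_one_has_zero_loss(self):
        S = np.array([[0.3]])
        assert loss_text_to_image(S, tau=0.1) == pytest.approx(0.0)
        assert contrastive_loss(S, tau=0.1) == pytest.approx(0.0)

    def test_identity_matrix_b2_tau_0p1(self):
        S = np.eye(2)
        expected = 2.0 * np.log(1.0 + np.exp(-10.0))  # ≈ 9.08e-5
        assert loss_text_to_image(S, tau=0.1) == pytest.approx(expected, abs=1e-12)
        assert contrastive_loss(S, tau=0.1) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("value", [0.0, 0.37, -0.8])
    def test_constant_matrix_gives_b_log_b(self, value):
        B = 4
        S = np.full((B, B), value)
        assert loss_text_to_image(S, tau=0.1) == pytest.approx(B * np.log(B))

    def test_directional_losses_against_loop_oracle(self):
        S = np.clip(RNG.normal(scale=0.5, size=(5, 5)), -1, 1)
        assert loss_text_to_image(S, tau=0.3) == pytest.approx(
            brute_force_t2i(S, 0.3)
        )
        assert loss_image_to_text(S, tau=0.3) == pytest.approx(
            brute_force_t2i(S.T, 0.3)
        )

    def test_symmetric_matrix_equalises_directions(self):
        A = RNG.normal(size=(4, 4))
        S = np.clip((A + A.T) / 2, -1, 1)
        assert loss_text_to_image(S, 0.2) == pytest.approx(loss_image_to_text(S, 0.2))

    def test_total_is_arithmetic_mean_of_directions(self):
        S = np.clip(RNG.normal(scale=0.4, size=(4, 4)), -1, 1)
        assert contrastive_loss(S, 0.15) == pytest.approx(
            0.5 * (loss_text_to_image(S, 0.15) + loss_image_to_text(S, 0.15))
        )


class TestInvariances:
    def test_pair_permutation_invariance(self):
        S = np.clip(RNG.normal(scale=0.4, size=(6, 6)), -1, 1)
        perm = RNG.permutation(6)
        Sp = S[np.ix_(perm, perm)]
        for fn in (loss_text_to_image, loss_image_to_text, contrastive_loss):
            assert fn(S, 0.1) == pytest.approx(fn(Sp, 0.1))

    def test_nonnegative_under_diagonal_dominance(self):
        S = np.clip(RNG.normal(scale=0.2, size=(5, 5)), -0.9, 0.9)
        np.fill_diagonal(S, 0.95)
        assert loss_text_to_image(S, 0.1) >= 0.0
        assert loss_image_to_text(S, 0.1) >= 0.0

    def test_loss_increases_with_temperature_when_diagonal_dominant(self):
        S = np.clip(RNG.normal(scale=0.2, size=(4, 4)), -0.8, 0.8)
        np.fill_diagonal(S, 0.9)
        losses = [contrastive_loss(S, tau) for tau in (0.05, 0.1, 0.5, 1.0)]
        assert all(a < b for a, b in zip(losses, losses[1:]))

    def test_mean_reduction_is_sum_over_batch(self):
        S = np.clip(RNG.normal(scale=0.3, size=(5, 5)), -1, 1)
        assert loss_text_to_image(S, 0.1, reduction="mean") == pytest.approx(
            loss_text_to_image(S, 0.1, reduction="sum") / 5
        )


class TestGradient:
    def test_analytic_gradient_matches_central_differences(self):
        S = np.clip(RNG.normal(scale=0.4, size=(4, 4)), -1, 1)
        tau = 0.1
        _, grad = contrastive_objective_with_grad(S, tau)
        eps = 1e-6
        for b in range(4):
            for k in range(4):
                up = S.copy()
                dn = S.copy()
                up[b, k] += eps
                dn[b, k] -= eps
                num = (
                    contrastive_objective_with_grad(up, tau)[0]
                    - contrastive_objective_with_grad(dn, tau)[0]
                ) / (2 * eps)
                assert abs(num - grad[b, k]) < 1e-5


class TestPretrain:
    def _encoders(self, dataset):
        corpus = [
            v
            for ps in dataset.prompt_sets
            for sid in ps.scale_ids
            for v in ps.variants[sid]
        ]
        vocab = build_vocab(corpus, provenance=frozenset(dataset.subject_ids))
        img = ImageEncoder(
            EncoderConfig(modality="image", d_model=16, depth=1, n_heads=2,
                          shared_dim=32, seed=0)
        )
        txt = TextEncoder(
            EncoderConfig(modality="text", d_model=16, depth=1, n_heads=2,
                          shared_dim=32, max_len=48, seed=1),
            vocab,
        )
        return img, txt

    def test_loss_decreases_and_trace_shape(self, tiny_cohort):
        img, txt = self._encoders(tiny_cohort)
        cfg = ContrastiveConfig(tau=0.1, batch_size=8, epochs=4, lr=1e-3,
                                reduction="mean")
        trace = pretrain(tiny_cohort, img, txt, cfg, seed=0)
        assert len(trace) == 4
        assert trace[-1]["L_total"] < trace[0]["L_total"]

    def test_deterministic_given_seed(self, tiny_cohort):
        traces = []
        for _ in range(2):
            img, txt = self._encoders(tiny_cohort)
            cfg = ContrastiveConfig(batch_size=8, epochs=2, lr=1e-3)
            traces.append(pretrain(tiny_cohort, img, txt, cfg, seed=5))
        assert traces[0] == traces[1]

    def test_batch_of_one_warns(self, tiny_cohort):
        sub = tiny_cohort.subset(np.arange(3))
        img, txt = self._encoders(sub)
        cfg = ContrastiveConfig(batch_size=2, epochs=1, lr=1e-3)
        with pytest.warns(UserWarning):
            pretrain(sub, img, txt, cfg, seed=0)
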