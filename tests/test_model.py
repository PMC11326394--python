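"""Sequence-model contracts: embedding determinism, positional encoding,
causality, the LTI limit of the state-space block, scan agreement, top-k
pooling, class weights, Youden thresholds, and training reproducibility."""

import warnings

import numpy as np
import pytest

from icuacuity._autograd import Tensor
from icuacuity.model import (
    AcuityModel,
    AcuityNet,
    ModelConfig,
    compute_class_weights,
    select_thresholds,
    split_by_stay,
)
from icuacuity.nn import SSMBlock, sinusoidal_positional_encoding, topk_pool

TINY = ModelConfig(
    L=16, D=16, state_dim=4, k=4, f=2, conv_kernel=3, dt_rank=4,
    mlp_hidden=32, static_hidden=16, ssm_conv_kernel=3, epochs=2, batch_size=16,
)


def random_batch(rng, n=4, L=12, n_codes=5, f=2):
    times = np.sort(rng.uniform(0, 0.05, (n, L)), axis=1)
    values = rng.uniform(0, 1, (n, L))
    codes = rng.integers(1, n_codes + 1, (n, L))
    mask = np.ones((n, L), dtype=int)
    n_real = rng.integers(3, L + 1, n)
    for i in range(n):
        mask[i, n_real[i] :] = 0
        codes[i, n_real[i] :] = 0
        times[i, n_real[i] :] = 0.0
        values[i, n_real[i] :] = 0.0
    static = rng.uniform(0, 1, (n, f))
    return times, values, codes, mask, static


class TestEmbedding:
    def test_all_padding_embeddings_identical_across_samples(self):
        net = AcuityNet(TINY, vocab_size=5)
        z = np.zeros((3, 8))
        emb = net.embed_triplets(z, z, z.astype(int)).data
        # conv of zeros + zero code row + positional encoding: same for all
        np.testing.assert_array_equal(emb[0], emb[1])
        np.testing.assert_array_equal(emb[0], emb[2])
        pe = sinusoidal_positional_encoding(8, TINY.D)
        bias_part = emb[0] - pe
        assert np.allclose(bias_part, bias_part[0:1], atol=1e-12)

    def test_positional_encoding_closed_form(self):
        D = 16
        pe = sinusoidal_positional_encoding(10, D)
        for p in (0, 3, 9):
            for i in range(D // 2):
                angle = p / (10000 ** (2 * i / D))
                assert pe[p, 2 * i] == pytest.approx(np.sin(angle))
                assert pe[p, 2 * i + 1] == pytest.approx(np.cos(angle))

    def test_out_of_vocabulary_code_rejected(self):
        net = AcuityNet(TINY, vocab_size=5)
        z = np.zeros((1, 4))
        codes = np.array([[1, 2, 6, 0]])
        with pytest.raises(ValueError, match="vocabulary"):
            net.embed_triplets(z, z, codes)


class TestCausality:
    def test_backbone_is_causal(self, rng):
        """Changing the final event leaves all earlier positions unchanged."""
        net = AcuityNet(TINY, vocab_size=5)
        times, values, codes, mask, _ = random_batch(rng)
        out1 = net.backbone(net.embed_triplets(times, values, codes)).data
        t2, v2, c2 = times.copy(), values.copy(), codes.copy()
        t2[:, -1] += 0.01
        v2[:, -1] = 1.0 - v2[:, -1]
        c2[:, -1] = np.where(c2[:, -1] == 1, 2, 1)
        out2 = net.backbone(net.embed_triplets(t2, v2, c2)).data
        np.testing.assert_array_equal(out1[:, :-1], out2[:, :-1])
        assert np.abs(out1[:, -1] - out2[:, -1]).max() > 0

    def test_tail_padding_cannot_leak_into_real_positions(self, rng):
        net = AcuityNet(TINY, vocab_size=5)
        times, values, codes, mask, _ = random_batch(rng, n=2, L=10)
        out1 = net.backbone(net.embed_triplets(times, values, codes)).data
        v2 = values.copy()
        v2[:, -2:] = 0.77  # scribble on padded tail positions
        out2 = net.backbone(net.embed_triplets(times, v2, codes)).data
        n_real = mask.sum(axis=1)
        for i in range(2):
            if n_real[i] <= 8:
                np.testing.assert_array_equal(
                    out1[i, : n_real[i]], out2[i, : n_real[i]]
                )


class TestSSMBlockContracts:
    def test_sequential_and_fused_scan_agree(self, rng):
        blk = SSMBlock(8, 8, 4, 4, 3, rng)
        x = Tensor(rng.standard_normal((3, 20, 8)))
        fused = blk(x).data
        seq = blk(x, sequential_scan=True).data
        np.testing.assert_allclose(fused, seq, atol=1e-5)

    def test_numpy_chunked_and_fused_scan_agree(self, rng):
        blk = SSMBlock(8, 8, 4, 4, 3, rng)
        x = Tensor(rng.standard_normal((3, 20, 8)))
        fused = blk(x).data
        blk.fused = False
        chunked = blk(x).data
        np.testing.assert_allclose(fused, chunked, atol=1e-5)

    def test_lti_limit_matches_direct_convolution(self, rng):
        """Input-independent parameters + no gate/conv/activation reduce the
        block to an LTI system; compare with an explicit convolution with
        the implied impulse response."""
        Di, S, L = 5, 3, 12
        blk = SSMBlock(
            Di, Di, S, 2, 3, rng,
            selective=False, gated=False, use_conv=False, use_activation=False,
        )
        x_data = rng.standard_normal((2, L, Di))
        out = blk(Tensor(x_data)).data

        # oracle: impulse response per inner channel from the raw parameters
        W_in = blk.in_proj.weight.data[:, :Di]
        b_in = blk.in_proj.bias.data[:Di]
        u = x_data @ W_in + b_in
        dt = np.log1p(np.exp(blk.b_dt.data))
        A = np.exp(blk.A_log.data)  # (Di, S)
        a = np.exp(-np.minimum(dt[:, None] * A, SSMBlock.LOG_DECAY_CAP))
        B, C = blk.b_B.data, blk.b_C.data
        y = np.zeros_like(u)
        for lag in range(L):
            K_lag = (C * (a**lag) * (dt[:, None] * B)).sum(axis=1)  # (Di,)
            y[:, lag:] += K_lag * u[:, : L - lag]
        y += blk.D_skip.data * u
        expected = x_data + y @ blk.out_proj.weight.data + blk.out_proj.bias.data
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_block_gradients_flow(self, rng):
        blk = SSMBlock(8, 8, 4, 4, 3, rng)
        x = Tensor(rng.standard_normal((2, 10, 8)))
        (blk(x) ** 2).sum().backward()
        for name, p in blk.parameters().items():
            assert p.grad is not None, name
            assert np.all(np.isfinite(p.grad)), name


class TestTopkPool:
    def test_equals_masked_mean_when_k_covers_all(self, rng):
        x = Tensor(rng.standard_normal((3, 6, 4)))
        mask = np.ones((3, 6), dtype=int)
        mask[1, 4:] = 0
        pooled = topk_pool(x, mask, k=6).data
        for i in range(3):
            np.testing.assert_allclose(
                pooled[i], x.data[i][mask[i] > 0].mean(axis=0), atol=1e-12
            )

    def test_single_dominant_position(self):
        x_data = np.zeros((1, 5, 3))
        x_data[0, 2] = [100.0, -50.0, 10.0]
        pooled = topk_pool(Tensor(x_data), np.ones((1, 5), dtype=int), k=1).data
        np.testing.assert_allclose(pooled[0], x_data[0, 2])

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            N, L, D, k = 3, 8, 4, 3
            x_data = rng.standard_normal((N, L, D))
            mask = (rng.random((N, L)) < 0.7).astype(int)
            mask[:, 0] = 1
            pooled = topk_pool(Tensor(x_data), mask, k).data
            for i in range(N):
                real = np.where(mask[i] > 0)[0]
                norms = np.linalg.norm(x_data[i, real], axis=1)
                chosen = real[np.argsort(-norms, kind="stable")[:k]]
                np.testing.assert_allclose(pooled[i], x_data[i, chosen].mean(axis=0),
                                           atol=1e-12)

    def test_fully_masked_pools_to_zero(self, rng):
        x = Tensor(rng.standard_normal((2, 4, 3)))
        mask = np.zeros((2, 4), dtype=int)
        np.testing.assert_array_equal(topk_pool(x, mask, 2).data, 0.0)

    def test_padded_positions_never_selected(self, rng):
        x_data = rng.standard_normal((1, 6, 3)) * 0.01
        x_data[0, 5] = [99.0, 99.0, 99.0]  # huge but masked
        mask = np.array([[1, 1, 1, 1, 1, 0]])
        pooled = topk_pool(Tensor(x_data), mask, k=2).data
        assert np.abs(pooled).max() < 1.0


class TestForward:
    def test_deterministic_and_in_unit_interval(self, rng, small_pipeline):
        _, _, vocab, dataset = small_pipeline
        cfg = ModelConfig(
            L=64, D=16, state_dim=4, k=4, f=dataset.n_static, conv_kernel=3,
            dt_rank=4, mlp_hidden=32, static_hidden=16, ssm_conv_kernel=3,
        )
        net = AcuityNet(cfg, vocab.size)
        p1 = net.predict_proba(dataset.subset(np.arange(40)))
        p2 = net.predict_proba(dataset.subset(np.arange(40)))
        np.testing.assert_array_equal(p1, p2)
        assert np.all((p1 > 0) & (p1 < 1))

    def test_static_pathway_is_active(self, rng, small_pipeline):
        _, _, vocab, dataset = small_pipeline
        cfg = ModelConfig(
            L=64, D=16, state_dim=4, k=4, f=dataset.n_static, conv_kernel=3,
            dt_rank=4, mlp_hidden=32, static_hidden=16, ssm_conv_kernel=3,
        )
        net = AcuityNet(cfg, vocab.size)
        sub = dataset.subset(np.arange(8))
        base = net.predict_proba(sub)
        sub_zeroed = dataset.subset(np.arange(8))
        sub_zeroed.static = np.zeros_like(sub_zeroed.static)
        assert np.abs(base - net.predict_proba(sub_zeroed)).max() > 0

    def test_static_dimension_mismatch_errors(self, rng, small_pipeline):
        _, _, vocab, dataset = small_pipeline
        cfg = ModelConfig(L=64, D=16, state_dim=4, k=4, f=dataset.n_static + 1,
                          conv_kernel=3, dt_rank=4, mlp_hidden=32, static_hidden=16,
                          ssm_conv_kernel=3)
        net = AcuityNet(cfg, vocab.size)
        with pytest.raises(ValueError, match="static dimension"):
            net.forward(dataset, np.arange(4))

    def test_default_parameter_count_near_one_million(self):
        net = AcuityNet(ModelConfig(), vocab_size=12)
        assert 5e5 <= net.n_parameters() <= 2e6


class TestClassWeights:
    def test_balanced_labels_weight_one(self):
        labels = np.tile([[0.0], [1.0]], (50, 1))
        mask = np.ones_like(labels)
        np.testing.assert_allclose(compute_class_weights(labels, mask), [1.0])

    def test_imbalance_and_cap(self):
        labels = np.zeros((1000, 2))
        labels[:10, 0] = 1.0
        labels[:2, 1] = 1.0
        mask = np.ones_like(labels)
        w = compute_class_weights(labels, mask, cap=100.0)
        assert w[0] == pytest.approx(99.0)
        assert w[1] == 100.0

    def test_masked_labels_excluded(self):
        labels = np.array([[1.0], [1.0], [0.0], [1.0]])
        mask = np.array([[1.0], [1.0], [1.0], [0.0]])
        np.testing.assert_allclose(compute_class_weights(labels, mask), [0.5])

    def test_no_positives_gives_nan(self):
        labels = np.zeros((10, 1))
        w = compute_class_weights(labels, np.ones_like(labels))
        assert np.isnan(w[0])


class TestYoudenThreshold:
    def test_worked_example(self):
        thr = select_thresholds(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert thr == pytest.approx(0.35)

    def test_perfect_separation_returns_lowest_optimum(self):
        thr = select_thresholds(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert thr == pytest.approx(0.8)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 40))
            probs = rng.random(n).round(2)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            thr = select_thresholds(probs, labels)
            best_j, best_t = -np.inf, None
            for t in sorted(set(probs)):
                pred = probs >= t
                sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
                spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
                j = sens + spec - 1
                if j > best_j + 1e-12:
                    best_j, best_t = j, t
            assert thr == pytest.approx(best_t)

    def test_degenerate_labels_error(self):
        with pytest.raises(ValueError, match="both classes"):
            select_thresholds(np.array([0.1, 0.9]), np.array([1, 1]))


class TestTraining:
    def test_split_by_stay_never_splits_a_stay(self, small_pipeline):
        _, _, _, dataset = small_pipeline
        tr, va = split_by_stay(dataset, 0.8, seed=3)
        assert set(dataset.stay_ids[tr]).isdisjoint(set(dataset.stay_ids[va]))
        assert len(tr) + len(va) == len(dataset)

    def test_fit_is_reproducible(self, small_pipeline):
        _, _, vocab, dataset = small_pipeline
        cfg = ModelConfig(
            L=64, D=8, state_dim=2, k=2, f=dataset.n_static, conv_kernel=3,
            dt_rank=2, mlp_hidden=16, static_hidden=8, ssm_conv_kernel=2,
            epochs=1, batch_size=32, seed=5,
        )
        sub = dataset.subset(np.arange(min(len(dataset), 150)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = AcuityModel(sub, cfg, vocab_size=vocab.size).fit()
            r2 = AcuityModel(sub, cfg, vocab_size=vocab.size).fit()
        np.testing.assert_array_equal(r1.val_probs, r2.val_probs)
        assert r1.history.equals(r2.history)
        assert r1.thresholds == r2.thresholds

    def test_gradients_reach_every_parameter_group(self, small_pipeline):
        _, _, vocab, dataset = small_pipeline
        cfg = ModelConfig(
            L=64, D=8, state_dim=2, k=2, f=dataset.n_static, conv_kernel=3,
            dt_rank=2, mlp_hidden=16, static_hidden=8, ssm_conv_kernel=2,
        )
        net = AcuityNet(cfg, vocab.size)
        idx = np.arange(min(len(dataset), 64))
        weights = np.ones(9)
        frozen = np.zeros(9, dtype=bool)
        loss = AcuityModel._loss(net, dataset, idx, weights, frozen)
        loss.backward()
        for name, p in net.parameters().items():
            assert p.grad is not None, name
            assert np.all(np.isfinite(p.grad)), name
            assert np.abs(p.grad).max() > 0, name

    def test_head_without_positives_is_frozen_with_warning(self, small_pipeline):
        _, _, vocab, dataset = small_pipeline
        sub = dataset.subset(np.arange(min(len(dataset), 120)))
        sub.labels[:, 8] = 0.0  # wipe crrt_onset positives
        cfg = ModelConfig(
            L=64, D=8, state_dim=2, k=2, f=sub.n_static, conv_kernel=3,
            dt_rank=2, mlp_hidden=16, static_hidden=8, ssm_conv_kernel=2,
            epochs=1, batch_size=32,
        )
        with pytest.warns(UserWarning, match="crrt_onset"):
            AcuityModel(sub, cfg, vocab_size=vocab.size).fit()
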