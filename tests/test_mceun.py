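"""McEUN network, autodiff core, training and the classical fallback."""

import numpy as np
import pytest

from slacspect import phantom as ph
from slacspect.attenuation import assign_mu, fit_tissue_model
from slacspect.mceun import (
    McEUNConfig,
    build_mceun,
    classical_fallback_segment,
    inverse_frequency_weights,
    kfold_split,
    predict_segmentation,
    train_mceun,
)
from slacspect.mceun import _autograd as ag
from slacspect.mceun.network import BIAS_INIT


def _loss_fn(net, x, y, w):
    logits = net.forward(x, train=False)
    return ag.weighted_softmax_ce(logits, y, w)


class TestAutogradCore:
    def test_full_network_gradient_matches_finite_differences(self):
        cfg = McEUNConfig(depth=2, base_filters=2, dropout_rate=0.0,
                          attention_channels=2)
        net = build_mceun(cfg, seed=1)
        rng = np.random.default_rng(2)
        x = rng.random((1, 2, 8, 8)).astype(np.float32)
        y = rng.integers(0, 6, (1, 8, 8))
        w = np.ones(6)
        loss = _loss_fn(net, x, y, w)
        loss.backward()
        checked = 0
        for name in ("enc0.0.w", "dec0.ag0.psi.w", "dec3.head.b", "enc1.1.b"):
            p = net.params[name]
            g = p.grad
            flat = p.data.ravel()
            for k in [0, flat.size // 2]:
                eps = 1e-2
                orig = flat[k]
                flat[k] = orig + eps
                lp = float(_loss_fn(net, x, y, w).data)
                flat[k] = orig - eps
                lm = float(_loss_fn(net, x, y, w).data)
                flat[k] = orig
                fd = (lp - lm) / (2 * eps)
                an = g.ravel()[k]
                assert an == pytest.approx(fd, abs=max(5e-3, 0.05 * abs(fd)))
                checked += 1
        assert checked == 8

    def test_maxpool_upsample_adjoint_shapes(self):
        rng = np.random.default_rng(3)
        x = ag.Tensor(rng.random((2, 3, 8, 8)), requires_grad=True)
        pooled = ag.maxpool2(x)
        assert pooled.shape == (2, 3, 4, 4)
        up = ag.upsample2(pooled)
        assert up.shape == (2, 3, 8, 8)

    def test_dropout_scales_expectation(self):
        rng = np.random.default_rng(4)
        x = ag.Tensor(np.ones((1, 1, 32, 32), dtype=np.float32))
        d = ag.dropout(x, 0.25, rng, train=True)
        assert d.data.mean() == pytest.approx(1.0, abs=0.1)
        vals = np.unique(d.data)
        assert all(
            min(abs(v - 0.0), abs(v - 1.0 / 0.75)) < 1e-6 for v in vals
        )


class TestBuildMcEUN:
    def test_probabilities_sum_to_one_per_voxel(self):
        net = build_mceun(McEUNConfig(depth=2, base_filters=4), seed=0)
        x = np.random.default_rng(5).random((2, 2, 16, 16)).astype(np.float32)
        proba = net.predict_proba(x)
        assert proba.shape == (2, 6, 16, 16)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-5)

    def test_all_biases_initialized_to_constant(self):
        net = build_mceun(McEUNConfig(), seed=0)
        for name, p in net.params.items():
            if name.endswith(".b"):
                assert np.all(p.data == np.float32(BIAS_INIT))

    def test_forward_deterministic_without_dropout(self):
        net = build_mceun(McEUNConfig(depth=2, base_filters=4), seed=0)
        x = np.random.default_rng(6).random((1, 2, 16, 16)).astype(np.float32)
        assert np.array_equal(net.predict_proba(x), net.predict_proba(x))

    def test_indivisible_input_rejected(self):
        net = build_mceun(McEUNConfig(depth=3), seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 2, 10, 10), dtype=np.float32))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            McEUNConfig(depth=1)
        with pytest.raises(ValueError):
            McEUNConfig(dropout_rate=1.0)


def _synthetic_pairs(n, rng, size=16):
    """Cheap label/image pairs: blocky six-class maps plus noisy channels."""
    pairs = []
    for _ in range(n):
        y = np.zeros((size, size), dtype=np.int64)
        y[4:12, 4:12] = 3
        y[6:10, 6:10] = rng.integers(1, 6)
        y[0:2, :] = 5
        y[2, :8] = 1
        y[3, 8:] = 2
        y[12, :4] = 4
        x = np.stack([
            (y / 5.0) + 0.1 * rng.standard_normal((size, size)),
            (y == 3) + 0.1 * rng.standard_normal((size, size)),
        ]).astype(np.float32)
        pairs.append((x, y))
    return pairs


class TestTraining:
    def test_fold_partition_of_20_samples(self):
        assign = kfold_split(20, folds=5, seed=0)
        sizes = np.bincount(assign, minlength=5)
        assert np.array_equal(sizes, [4] * 5)

    def test_fold_sizes_differ_by_at_most_one(self):
        sizes = np.bincount(kfold_split(23, folds=5, seed=1))
        assert sizes.max() - sizes.min() <= 1

    def test_inverse_frequency_weights_mean_one(self):
        targets = [np.repeat(np.arange(6), [100, 10, 20, 50, 5, 15])]
        w = inverse_frequency_weights(targets)
        assert w.mean() == pytest.approx(1.0)
        assert w[4] == w.max()  # rarest class weighted highest

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            inverse_frequency_weights([np.zeros((4, 4), dtype=np.int64)])

    def test_training_reduces_loss(self):
        rng = np.random.default_rng(7)
        pairs = _synthetic_pairs(10, rng)
        cfg = McEUNConfig(depth=2, base_filters=4, dropout_rate=0.1,
                          attention_channels=2)
        net = build_mceun(cfg, seed=0)
        net, log = train_mceun(net, pairs, epochs=12, batch_size=5, seed=0,
                               run_cv=False)
        assert log.train_loss[-1] < log.train_loss[0]

    def test_identical_seeds_give_identical_weights(self):
        rng = np.random.default_rng(8)
        pairs = _synthetic_pairs(6, rng)
        cfg = McEUNConfig(depth=2, base_filters=2, attention_channels=2)
        nets = []
        for _ in range(2):
            net = build_mceun(cfg, seed=3)
            net, _ = train_mceun(net, pairs, epochs=2, batch_size=3, seed=3,
                                 run_cv=False)
            nets.append(net.state_dict())
        for k in nets[0]:
            assert np.array_equal(nets[0][k], nets[1][k])

    def test_cross_validation_records_per_fold_losses(self):
        rng = np.random.default_rng(9)
        pairs = _synthetic_pairs(10, rng)
        cfg = McEUNConfig(depth=2, base_filters=2, attention_channels=2)
        net = build_mceun(cfg, seed=0)
        _, log = train_mceun(net, pairs, epochs=2, batch_size=5, seed=0,
                             folds=5, run_cv=True)
        assert set(log.val_loss) == set(range(5))
        assert all(len(v) == 2 for v in log.val_loss.values())
        assert np.bincount(log.fold_assignments).tolist() == [2] * 5

    def test_too_few_pairs_rejected(self):
        rng = np.random.default_rng(10)
        net = build_mceun(McEUNConfig(depth=2, base_filters=2), seed=0)
        with pytest.raises(ValueError):
            train_mceun(net, _synthetic_pairs(3, rng), folds=5)


class TestPredictSegmentation:
    def test_argmax_agrees_with_per_voxel_maximum(self):
        net = build_mceun(McEUNConfig(depth=2, base_filters=2,
                                      attention_channels=2), seed=0)
        rng = np.random.default_rng(11)
        scatter = rng.random((16, 16, 8)).astype(np.float32) + 0.5
        photopeak = rng.random((16, 16, 8)).astype(np.float32) + 0.5
        labels = predict_segmentation(net, scatter, photopeak)
        assert labels.shape == scatter.shape
        assert set(np.unique(labels)) <= set(range(6))
        x = np.stack([scatter[:, :, 0], photopeak[:, :, 0]])[None]
        proba = net.predict_proba(x.astype(np.float32))[0]
        oracle = np.empty((16, 16), dtype=np.uint8)
        for i in range(16):
            for j in range(16):
                oracle[i, j] = int(np.argmax([proba[c, i, j] for c in range(6)]))
        assert np.array_equal(labels[:, :, 0], oracle)

    def test_warns_on_unnormalized_input(self):
        net = build_mceun(McEUNConfig(depth=2, base_filters=2,
                                      attention_channels=2), seed=0)
        big = np.full((16, 16, 8), 50.0, dtype=np.float32)
        with pytest.warns(UserWarning, match="normalized"):
            predict_segmentation(net, big, big)


@pytest.fixture(scope="module")
def noiseless_initial_estimates():
    from slacspect.forward_model import (
        AcquisitionGeometry, ProjectionSet, forward_project, simulate_scatter,
    )
    from slacspect.recon import ReconConfig, reconstruct_initial_estimates

    p = ph.generate_phantom(3)
    geom = AcquisitionGeometry(n_angles=30)
    primary = forward_project(p.activity, p.mu, geom)
    scat = simulate_scatter(p.activity, p.mu, geom, primary=primary)
    pset = ProjectionSet(geom, primary.astype(np.float64),
                         scat.astype(np.float64))
    s_rec, pp_rec = reconstruct_initial_estimates(
        pset, ReconConfig(n_subsets=6, n_iterations=5)
    )
    return p, s_rec, pp_rec


class TestClassicalFallback:
    def test_recovers_all_six_classes_with_good_accuracy(
        self, noiseless_initial_estimates
    ):
        p, s_rec, pp_rec = noiseless_initial_estimates
        labels = classical_fallback_segment(s_rec, pp_rec)
        assert set(np.unique(labels)) == set(range(6))
        assert (labels == p.labels).mean() >= 0.85

    def test_deterministic(self, noiseless_initial_estimates):
        _, s_rec, pp_rec = noiseless_initial_estimates
        a = classical_fallback_segment(s_rec, pp_rec)
        b = classical_fallback_segment(s_rec, pp_rec)
        assert np.array_equal(a, b)

    def test_output_consumable_by_assign_mu(self, noiseless_initial_estimates):
        p, s_rec, pp_rec = noiseless_initial_estimates
        labels = classical_fallback_segment(s_rec, pp_rec)
        model = fit_tissue_model([p.mu], [p.labels])
        mu = assign_mu(labels, model)
        assert mu.shape == labels.shape
        assert np.all(mu >= 0)

    def test_empty_input_rejected(self):
        z = np.zeros((16, 16, 16))
        with pytest.raises(ValueError):
            classical_fallback_segment(z, z)


class TestDeskScaleTraining:
    def test_held_out_dice_for_lungs_and_body(self):
        """A short desk-scale training run segments held-out phantoms with
        foreground Dice >= 0.80 for the lungs and the body."""
        from slacspect.pipeline import ExperimentConfig, _simulate_scan
        from slacspect.recon import ReconConfig, reconstruct_initial_estimates
        from slacspect.mceun import train_mceun, volumes_to_slices

        cfg = ExperimentConfig()
        pairs, held = [], None
        for i in range(9):
            p = ph.generate_phantom(500 + i)
            pset = _simulate_scan(p.activity, p.mu, cfg, 900 + i)
            s_rec, pp_rec = reconstruct_initial_estimates(
                pset, ReconConfig(n_subsets=6, n_iterations=2)
            )
            if i < 8:
                pairs += volumes_to_slices(s_rec, pp_rec, p.labels, stride=6)
            else:
                held = (p, s_rec, pp_rec)
        net = build_mceun(McEUNConfig(), seed=0)
        net, log = train_mceun(net, pairs, epochs=8, batch_size=8, seed=0,
                               run_cv=False)
        assert log.train_loss[-1] < log.train_loss[0]
        p, s_rec, pp_rec = held
        labels = predict_segmentation(net, s_rec, pp_rec)

        def dice(a, b):
            return 2 * np.sum(a & b) / max(np.sum(a) + np.sum(b), 1)

        body_pred = (labels > 0) & (labels != ph.TABLE)
        body_true = (p.labels > 0) & (p.labels != ph.TABLE)
        assert dice(labels == ph.LUNGS, p.labels == ph.LUNGS) >= 0.80
        assert dice(body_pred, body_true) >= 0.80
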