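import numpy as np
import pytest

from limbtorsion import autograd as ag
from limbtorsion.artifacts import apply_artifact
from limbtorsion.unet import (AugmentSpec, NetConfig, PlateauHalving,
                              TrainConfig, UNet3D, UNet3DSegmenter, build_unet,
                              combined_loss, predict_mask, train)
from limbtorsion.volume import LabelMask, PreprocessSpec, Volume

TINY = NetConfig(depth=3, base_filters=4)


class TestArchitecture:
    def test_default_encoder_filter_counts_double_per_level(self):
        assert NetConfig().filters == [16, 32, 64, 128, 256, 512]

    def test_softmax_normalized_and_shape_preserved(self, rng):
        net = build_unet(TINY, seed=0)
        x = rng.normal(size=(16, 8, 4)).astype(np.float32)
        probs = net.predict_proba(x)
        assert probs.shape == (4, 16, 8, 4)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    @pytest.mark.parametrize("shape", [(8, 16, 4), (16, 16, 8), (24, 8, 3)])
    def test_shape_preservation_across_valid_inputs(self, shape, rng):
        net = build_unet(TINY, seed=0)
        out = net.forward(rng.normal(size=shape).astype(np.float32))
        assert out.data.shape == (4, *shape)

    def test_indivisible_inplane_axis_raises_with_axis_name(self, rng):
        net = build_unet(TINY, seed=0)
        with pytest.raises(ValueError, match="axis y"):
            net.forward(rng.normal(size=(8, 9, 4)).astype(np.float32))

    def test_z_pooling_only_while_extent_large_and_even(self):
        net = build_unet(NetConfig(depth=6, base_filters=1), seed=0)
        plan = net.pooling_plan((64, 64, 16))
        assert [f[2] for f in plan] == [2, 2, 1, 1, 1]
        plan29 = build_unet(NetConfig(depth=6, base_filters=1), seed=0
                            ).pooling_plan((64, 64, 29))
        assert [f[2] for f in plan29] == [1, 1, 1, 1, 1]

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = build_unet(TINY, seed=3)
        x = rng.normal(size=(8, 8, 4)).astype(np.float32)
        net.save(tmp_path / "m.npz")
        back = UNet3D.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(net.predict_proba(x), back.predict_proba(x))


class TestCombinedLoss:
    def test_perfect_prediction_loss_vanishes(self, rng):
        target = rng.integers(0, 4, size=(6, 6, 2))
        logits = np.full((4, 6, 6, 2), -30.0, np.float32)
        for c in range(4):
            logits[c][target == c] = 30.0
        loss = combined_loss(ag.log_softmax(ag.Tensor(logits), 0), target)
        assert loss.item() < 1e-3

    def test_uniform_probabilities_give_ln4_cross_entropy(self):
        target = np.zeros((4, 4, 2), dtype=int)  # background only: no Dice term
        logp = ag.Tensor(np.full((4, 4, 4, 2), np.log(0.25), np.float32))
        loss = combined_loss(logp, target)
        np.testing.assert_allclose(loss.item(), np.log(4.0), rtol=1e-5)

    def test_missed_foreground_adds_one_dice_unit_per_class_present(self):
        target = np.zeros((4, 4, 2), dtype=int)
        target[0, 0, 0] = 1
        target[1, 1, 1] = 2
        # all probability mass on background
        logits = np.full((4, 4, 4, 2), -30.0, np.float32)
        logits[0] = 30.0
        logp = ag.log_softmax(ag.Tensor(logits), 0)
        ce = -float((logp.data * np.stack([target == c for c in range(4)])).sum()
                    ) / target.size
        loss = combined_loss(logp, target)
        np.testing.assert_allclose(loss.item() - ce, 2.0, atol=1e-4)

    def test_equals_cross_entropy_when_no_foreground(self, rng):
        target = np.zeros((4, 4, 2), dtype=int)
        logp = ag.log_softmax(
            ag.Tensor(rng.normal(size=(4, 4, 4, 2)).astype(np.float32)), 0)
        ce = -float(logp.data[0].sum()) / target.size
        np.testing.assert_allclose(combined_loss(logp, target).item(), ce,
                                   rtol=1e-5)

    def test_loss_nonnegative(self, rng):
        for _ in range(5):
            target = rng.integers(0, 4, size=(4, 4, 2))
            logp = ag.log_softmax(
                ag.Tensor(rng.normal(size=(4, 4, 4, 2)).astype(np.float32)), 0)
            assert combined_loss(logp, target).item() >= 0

    def test_gradient_matches_finite_difference_on_toy_grid(self, rng):
        target = rng.integers(0, 4, size=(4, 4, 2))
        logits = ag.Tensor(rng.normal(size=(4, 4, 4, 2)).astype(np.float32),
                           requires_grad=True)
        loss = combined_loss(ag.log_softmax(logits, 0), target)
        ag.backward(loss)
        d = rng.normal(size=logits.data.shape).astype(np.float32)
        ana = float((logits.grad * d).sum())
        eps = 1e-2

        def value(sign):
            t = ag.Tensor(logits.data + sign * eps * d)
            return combined_loss(ag.log_softmax(t, 0), target).item()

        num = (value(+1) - value(-1)) / (2 * eps)
        assert abs(num - ana) <= 1e-3 * max(1.0, abs(num) + abs(ana))

    def test_shape_mismatch_rejected(self):
        logp = ag.Tensor(np.zeros((4, 4, 4, 2), np.float32))
        with pytest.raises(ValueError):
            combined_loss(logp, np.zeros((4, 4, 3), int))


class TestScheduler:
    def test_halving_on_plateau_reaches_min_lr(self):
        sched = PlateauHalving(0.1, window=2, patience=3, rel_tol=1e-3,
                               min_lr=0.02)
        lrs = [sched.update(1.0)[1] for _ in range(20)]
        assert lrs[0] == 0.1
        drops = {round(a / b, 6) for a, b in zip(lrs, lrs[1:]) if b < a}
        assert drops == {2.0}
        assert min(lrs) == 0.025  # halving again would cross min_lr
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_no_drop_while_improving(self):
        sched = PlateauHalving(0.1, window=2, patience=3, rel_tol=1e-3)
        for i in range(30):
            _, lr = sched.update(1.0 / (i + 1))
        assert lr == 0.1


def tiny_dataset(n=2, shape=(16, 16, 4), seed=0):
    rng = np.random.default_rng(seed)
    data = []
    for _ in range(n):
        labels = np.zeros(shape, np.uint8)
        labels[4:12, 4:12, 1:3] = rng.integers(1, 4)
        vol = Volume(data=(labels > 0).astype(np.float32)
                     + rng.normal(0, 0.05, shape).astype(np.float32),
                     spacing=(1, 1, 1))
        data.append((vol, LabelMask(data=labels, spacing=(1, 1, 1))))
    return data


class TestTraining:
    def test_same_seed_reproduces_history_bitwise(self):
        cfg = TrainConfig(max_iterations=4, seed=7)
        histories = []
        for _ in range(2):
            net = build_unet(TINY, seed=1)
            _, h = train(net, tiny_dataset(), cfg, AugmentSpec())
            histories.append(h)
        assert histories[0].equals(histories[1])

    def test_loss_decreases_and_lr_monotone(self):
        net = build_unet(TINY, seed=1)
        _, h = train(net, tiny_dataset(), TrainConfig(max_iterations=25, seed=0))
        assert h["moving_avg"].iloc[-1] < h["moving_avg"].iloc[0]
        lrs = h["lr"].to_numpy()
        assert np.all(lrs[:-1] >= lrs[1:])
        drops = lrs[:-1] / np.maximum(lrs[1:], 1e-12)
        assert np.all(np.isin(np.round(drops[lrs[:-1] > lrs[1:]], 6), [2.0]))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(build_unet(TINY, seed=0), [], TrainConfig(max_iterations=1))


class TestPredictMask:
    def test_argmax_tie_resolves_to_lowest_class(self):
        net = build_unet(TINY, seed=0)
        net.head_w.data[:] = 0  # uniform class probabilities everywhere
        net.head_b.data[:] = 0
        vol = Volume(data=np.zeros((16, 16, 4), np.float32), spacing=(1, 1, 1))
        mask = predict_mask(net, vol, PreprocessSpec(target_spacing=(1, 1, 1),
                                                     pad_multiple=(4, 4, 1)))
        assert np.all(mask.data == 0)

    def test_native_grid_restored(self, rng):
        net = build_unet(TINY, seed=0)
        vol = Volume(data=rng.normal(size=(19, 21, 5)).astype(np.float32),
                     spacing=(1.1, 0.9, 6.5))
        mask = predict_mask(net, vol, PreprocessSpec(target_spacing=(1, 1, 6.5),
                                                     pad_multiple=(4, 4, 1)))
        assert mask.shape == vol.shape
        assert mask.spacing == vol.spacing


class TestArtifacts:
    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(16, 16, 4)).astype(np.float32)
        for fam in ("motion", "ghosting", "spiking", "bias_field"):
            a = apply_artifact(x, fam, seed=5)
            b = apply_artifact(x, fam, seed=5)
            np.testing.assert_array_equal(a, b)

    def test_zero_amplitude_bias_field_is_identity(self, rng):
        x = rng.normal(size=(8, 8, 4)).astype(np.float32)
        out = apply_artifact(x, "bias_field", seed=0, amplitude=0.0)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_ghosting_touches_only_modulated_kspace_lines(self, rng):
        x = rng.normal(size=(16, 12, 4)).astype(np.float32)
        out = apply_artifact(x, "ghosting", seed=1, axis=0, n_ghosts=4)
        kin = np.fft.fft(x, axis=0)
        kout = np.fft.fft(out, axis=0)
        idx = np.arange(16)
        modulated = (idx % 4 == 0) & (idx != 0)
        np.testing.assert_allclose(kout[~modulated], kin[~modulated], atol=1e-3)
        assert np.abs(kout[modulated] - kin[modulated]).max() > 1e-3

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown artifact"):
            apply_artifact(np.zeros((4, 4, 2), np.float32), "zipper", seed=0)


class TestEstimatorApi:
    def test_get_set_params_roundtrip(self):
        est = UNet3DSegmenter(depth=3, base_filters=4)
        params = est.get_params()
        assert params["depth"] == 3
        est.set_params(max_iterations=2)
        assert est.max_iterations == 2

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = clone(UNet3DSegmenter(depth=3, base_filters=4, max_iterations=2))
        assert est.depth == 3

    def test_fit_predict_smoke(self):
        data = tiny_dataset(n=2)
        X = [v for v, _ in data]
        y = [m for _, m in data]
        est = UNet3DSegmenter(depth=2, base_filters=2, target_spacing=(1, 1, 1),
                              pad_multiple=(4, 4, 1), max_iterations=3,
                              augment=False, random_state=0)
        est.fit(X, y)
        preds = est.predict(X)
        assert preds[0].shape == X[0].shape
        assert hasattr(est, "history_") and len(est.history_) == 3
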