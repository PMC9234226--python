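"""U-net contracts, focal-loss analytics, checkpointing, training loop."""

import numpy as np
import pytest

from fracseg.io import PatientSeries
from fracseg.model import (ModelCheckpoint, UNetSpec, build_model, focal_loss,
                           forward_slice, load_bundle, save_bundle)
from fracseg.preprocess import CropRegion, NormStats, one_hot
from fracseg.estimator import PatientSegmenter, train_patient_model
from fracseg.preprocess import TrainConfig

from conftest import small_phantom_config
from fracseg.phantom import generate_patient

TINY = UNetSpec(depth=2, base_filters=4, bottom_dropout_rate=0.0)


class TestForward:
    def test_softmax_probabilities_on_patch(self):
        net = build_model(TINY, 0)
        x = np.random.default_rng(0).normal(size=(2, 32, 32, 1)).astype(np.float32)
        p = net.forward(x)
        assert p.shape == (2, 32, 32, 4)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-5)
        assert np.all(p >= 0)

    def test_fully_convolutional_train_on_patch_infer_on_slice(self):
        """The same weights accept any divisible input size: train on 32x32,
        run on 64x64."""
        net = build_model(TINY, 0)
        x = np.random.default_rng(1).normal(size=(1, 64, 64, 1)).astype(np.float32)
        p = net.forward(x)
        assert p.shape == (1, 64, 64, 4)

    def test_indivisible_input_rejected_with_divisibility_named(self):
        net = build_model(UNetSpec(depth=3, base_filters=2), 0)
        x = np.zeros((1, 20, 20, 1), dtype=np.float32)
        with pytest.raises(ValueError, match="2\\^depth = 8"):
            net.forward(x)

    def test_same_seed_same_initial_outputs(self):
        x = np.random.default_rng(2).normal(size=(1, 16, 16, 1)).astype(np.float32)
        a = build_model(TINY, 42).forward(x)
        b = build_model(TINY, 42).forward(x)
        np.testing.assert_array_equal(a, b)


class TestFocalLoss:
    def _uniform(self, p_t, n=64):
        """Probability field with the true class at p_t everywhere."""
        prob = np.full((n, 4), (1 - p_t) / 3, dtype=np.float64)
        prob[:, 2] = p_t
        target = np.zeros_like(prob)
        target[:, 2] = 1.0
        return prob, target

    def test_perfect_prediction_gives_zero(self):
        prob, target = self._uniform(1.0)
        assert focal_loss(prob, target, 2.0) == pytest.approx(0.0, abs=1e-9)

    def test_gamma_zero_at_half_is_ln2(self):
        prob, target = self._uniform(0.5)
        assert focal_loss(prob, target, 0.0) == pytest.approx(np.log(2), abs=1e-6)

    def test_gamma_two_at_half_is_quarter_ln2(self):
        prob, target = self._uniform(0.5)
        assert focal_loss(prob, target, 2.0) == pytest.approx(0.25 * np.log(2), abs=1e-6)

    def test_gamma_zero_equals_cross_entropy_oracle(self, rng):
        for _ in range(50):
            prob = rng.dirichlet(np.ones(4), size=(6, 5))
            lab = rng.integers(0, 4, size=(6, 5))
            target = one_hot(lab).astype(np.float64)
            ce = float(-np.log(np.clip((prob * target).sum(-1), 1e-12, 1)).mean())
            assert focal_loss(prob, target, 0.0) == pytest.approx(ce, rel=1e-9)

    def test_monotone_nonincreasing_in_p_t(self):
        for gamma in (0.0, 0.5, 2.0, 5.0):
            losses = [focal_loss(*self._uniform(pt), gamma)
                      for pt in np.linspace(0.05, 1.0, 25)]
            assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            focal_loss(np.ones((2, 4)), np.ones((3, 4)))

    def test_dlogits_matches_finite_differences(self, rng):
        from fracseg.nn.ops import softmax_channels
        z = rng.normal(size=(2, 4, 4, 4))
        target = one_hot(rng.integers(0, 4, size=(2, 4, 4))).astype(np.float64)
        _, dlog = focal_loss(softmax_channels(z), target, 2.0, return_dlogits=True)
        for i in rng.choice(z.size, 10, replace=False):
            eps = 1e-6
            zp = z.ravel().copy(); zp[i] += eps
            zm = z.ravel().copy(); zm[i] -= eps
            num = (focal_loss(softmax_channels(zp.reshape(z.shape)), target, 2.0)
                   - focal_loss(softmax_channels(zm.reshape(z.shape)), target, 2.0)
                   ) / (2 * eps)
            assert dlog.ravel()[i] == pytest.approx(num, rel=1e-4, abs=1e-9)


def test_unet_gradients_match_finite_differences(rng):
    """Whole-network float64 gradient check against central differences."""
    net = build_model(UNetSpec(depth=2, base_filters=2, bottom_dropout_rate=0.0), 1)
    for layer in net.layers():
        layer.params = [p.astype(np.float64) for p in layer.params]
        layer.grads = [np.zeros_like(p) for p in layer.params]
    x = rng.normal(size=(1, 8, 8, 1))
    target = one_hot(rng.integers(0, 4, size=(1, 8, 8))).astype(np.float64)

    def loss():
        return focal_loss(net.forward(x), target, 2.0)

    prob = net.forward(x, train=True)
    _, dlog = focal_loss(prob, target, 2.0, return_dlogits=True)
    net.backward(dlog)
    for layer in net.layers():
        for p_arr, g_arr in zip(layer.params, layer.grads):
            flat = p_arr.ravel()
            for i in rng.choice(flat.size, min(3, flat.size), replace=False):
                eps, old = 1e-6, flat[i]
                flat[i] = old + eps; lp = loss()
                flat[i] = old - eps; lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert g_arr.ravel()[i] == pytest.approx(num, rel=1e-3, abs=1e-8)


class TestForwardSlice:
    def _ckpt_model(self):
        return build_model(TINY, 3)

    def test_repeated_calls_identical(self, rng):
        net = self._ckpt_model()
        s = rng.normal(size=(20, 24)).astype(np.float32)  # indivisible -> padded
        a = forward_slice(net, s)
        b = forward_slice(net, s)
        np.testing.assert_array_equal(a, b)

    def test_output_shape_and_normalization(self, rng):
        net = self._ckpt_model()
        s = rng.normal(size=(21, 18)).astype(np.float32)
        p = forward_slice(net, s)
        assert p.shape == (4, 21, 18)
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-5)


class TestCheckpoints:
    def _make(self, epoch=10):
        net = build_model(TINY, 7)
        return ModelCheckpoint(epoch=epoch, weights=net.get_weights(), spec=TINY,
                               crop=CropRegion((1, 2, 3), (16, 16, 8)),
                               norm_stats=NormStats(10.0, 900.0),
                               train_config_hash="abc")

    def test_bundle_roundtrip(self, tmp_path):
        cks = [self._make(e) for e in (10, 20, 30)]
        save_bundle(cks, tmp_path / "b")
        back = load_bundle(tmp_path / "b")
        assert [c.epoch for c in back] == [10, 20, 30]
        assert back[0].crop == cks[0].crop
        assert back[0].norm_stats == cks[0].norm_stats
        assert back[0].spec == TINY
        for w1, w2 in zip(cks[1].weights, back[1].weights):
            np.testing.assert_array_equal(w1, w2)

    def test_checkpoint_is_self_sufficient_for_inference(self, rng):
        ck = self._make()
        model = ck.build()
        s = rng.normal(size=(16, 16)).astype(np.float32)
        p = forward_slice(model, s)
        assert p.shape == (4, 16, 16)


class TestTrainingLoop:
    def _series(self):
        return generate_patient(small_phantom_config(seed=1, n_fractions=2))

    def _fit(self, **kw):
        kwargs = dict(depth=2, base_filters=4, patch_size=16, batch_size=2,
                      patches_per_epoch=4, epochs=10, checkpoint_interval=5,
                      ensemble_size=2, crop_min_size=(32, 32, 8), seed=3)
        kwargs.update(kw)
        est = PatientSegmenter(**kwargs)
        est.fit(self._series())
        return est

    def test_checkpoint_epochs_follow_interval(self):
        est = self._fit()
        assert [c.epoch for c in est.checkpoints_] == [5, 10]

    def test_full_schedule_checkpoint_arithmetic(self):
        """1000 epochs / interval 100 -> checkpoints at 100..1000 and the
        3-member ensemble is {800, 900, 1000} (verified on the schedule, not
        by running the full training)."""
        cfg = TrainConfig()  # shipped defaults
        epochs = [cfg.checkpoint_interval * i
                  for i in range(1, cfg.epochs // cfg.checkpoint_interval + 1)]
        assert len(epochs) == 10
        assert epochs[-cfg.ensemble_size:] == [800, 900, 1000]

    def test_training_is_reproducible(self):
        a = self._fit()
        b = self._fit()
        for w1, w2 in zip(a.checkpoints_[-1].weights, b.checkpoints_[-1].weights):
            np.testing.assert_array_equal(w1, w2)

    def test_smoke_run_reduces_training_loss(self):
        est = self._fit(epochs=30, checkpoint_interval=10, ensemble_size=3,
                        patches_per_epoch=8)
        assert est.history_[-1]["train_loss"] < est.history_[0]["train_loss"]

    def test_validation_logged_but_never_trained_on(self):
        series = self._series()
        est = PatientSegmenter(depth=2, base_filters=4, patch_size=16,
                               batch_size=2, patches_per_epoch=4, epochs=10,
                               checkpoint_interval=5, ensemble_size=2,
                               crop_min_size=(32, 32, 8), seed=3)
        est.fit(series, validation=(series.fractions[1][0], series.fractions[1][1]))
        ck_recs = [h for h in est.history_ if "val_loss" in h]
        assert len(ck_recs) == 2
        assert all(0 <= r["val_dice"][c] <= 1 for r in ck_recs for c in range(4))
        # weights identical with/without validation: it never updates params
        est2 = self._fit()
        for w1, w2 in zip(est.checkpoints_[-1].weights, est2.checkpoints_[-1].weights):
            np.testing.assert_array_equal(w1, w2)

    def test_train_patient_model_wrapper(self):
        cfg = TrainConfig(patch_size=16, batch_size=2, patches_per_epoch=4,
                          epochs=10, checkpoint_interval=5, ensemble_size=2,
                          crop_min_size=(32, 32, 8), seed=3)
        cks = train_patient_model(self._series(), cfg, TINY)
        assert [c.epoch for c in cks] == [5, 10]
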