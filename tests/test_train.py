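import warnings

import numpy as np
import pytest

from mitseg.autodiff import Tensor, softmax_cross_entropy
from mitseg.network import SegFormer
from mitseg.train import (CalibratedPredictor, TrainConfig, fit_temperature,
                          majority_baseline_miou, train, uncertainty_map)


class TestLoss:
    def test_uniform_logits_give_log_k(self, rng):
        logits = Tensor(np.zeros((50, 12), np.float32), requires_grad=True)
        targets = rng.integers(0, 12, 50)
        loss = softmax_cross_entropy(logits, targets)
        assert float(loss.data) == pytest.approx(np.log(12), abs=1e-6)

    def test_confident_correct_logits_give_near_zero_loss(self, rng):
        targets = rng.integers(0, 12, 50)
        logits = np.full((50, 12), -50.0, np.float32)
        logits[np.arange(50), targets] = 50.0
        loss = softmax_cross_entropy(Tensor(logits), targets)
        assert float(loss.data) < 1e-6

    def test_invalid_rows_excluded(self, rng):
        targets = np.zeros(10, dtype=int)
        logits = np.zeros((10, 3), np.float32)
        logits[5:, 0] = 100.0  # make half the rows perfect
        valid = np.arange(10) >= 5
        loss = softmax_cross_entropy(Tensor(logits), targets, valid)
        assert float(loss.data) < 1e-6

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError, match="class index"):
            softmax_cross_entropy(Tensor(np.zeros((4, 3), np.float32)),
                                  np.array([0, 1, 2, 3]))


class TestTrainLoop:
    def test_mask_class_out_of_range_fails_before_training(self, tiny_spec,
                                                           small_tiles):
        model = SegFormer(tiny_spec, seed=0)
        bad = small_tiles[0]
        bad_tile = type(bad)(image=bad.image,
                             mask=np.full_like(bad.mask, 13),
                             valid=bad.valid, row=0, col=0, size=64)
        with pytest.raises(ValueError, match="num_classes"):
            train(model, [bad_tile], [], TrainConfig(epochs=1))

    def test_short_run_is_seed_reproducible(self, tiny_spec, small_tiles):
        histories = []
        for _ in range(2):
            model = SegFormer(tiny_spec, seed=0)
            _, h = train(model, small_tiles[:2], [],
                         TrainConfig(batch_size=2, epochs=3, seed=4))
            histories.append(h["train_loss"])
        assert histories[0] == histories[1]

    def test_loss_decreases_on_small_overfit(self, tiny_spec, small_tiles):
        model = SegFormer(tiny_spec, seed=0)
        _, h = train(model, small_tiles[:2], [],
                     TrainConfig(batch_size=2, epochs=10, seed=0))
        assert h["train_loss"][-1] < h["train_loss"][0]

    def test_empty_training_set_rejected(self, tiny_spec):
        with pytest.raises(ValueError, match="empty"):
            train(SegFormer(tiny_spec, seed=0), [], [], TrainConfig())


class TestTemperature:
    @staticmethod
    def _make_logits(rng, n=4000, k=6, scale=1.0):
        labels = rng.integers(0, k, n)
        logits = rng.standard_normal((n, k)) * 0.5
        logits[np.arange(n), labels] += 2.0
        return logits * scale, labels

    def test_well_calibrated_logits_give_t_near_one(self, rng):
        # logits that are exact log-probabilities of the label-generating
        # distribution are already calibrated
        k = 5
        probs = rng.dirichlet(np.ones(k), size=3000)
        labels = np.array([rng.choice(k, p=p) for p in probs])
        pred = fit_temperature(np.log(probs), labels)
        assert abs(pred.temperature - 1.0) < 0.1

    def test_overconfident_logits_need_t_above_one(self, rng):
        logits, labels = self._make_logits(rng)
        t1 = fit_temperature(logits, labels).temperature
        t10 = fit_temperature(logits * 10.0, labels).temperature
        assert t10 > 1.0
        assert t10 / t1 == pytest.approx(10.0, rel=0.05)

    def test_fitted_nll_never_worse_than_unit_temperature(self, rng):
        from mitseg.train import _nll
        logits, labels = self._make_logits(rng, scale=3.0)
        pred = fit_temperature(logits, labels)
        assert _nll(logits, labels, pred.temperature) <= \
            _nll(logits, labels, 1.0) + 1e-12

    def test_single_class_validation_warns_and_returns_unit(self, rng):
        logits = rng.standard_normal((20, 4))
        with pytest.warns(UserWarning, match="single-class"):
            pred = fit_temperature(logits, np.zeros(20, dtype=int))
        assert pred.temperature == 1.0

    def test_temperature_never_changes_argmax(self, tiny_spec, small_tiles):
        model = SegFormer(tiny_spec, seed=0)
        img = small_tiles[0].image
        base, _ = model.predict(img, temperature=1.0)
        for t in (0.3, 2.0, 7.5):
            scaled, _ = model.predict(img, temperature=t)
            assert np.array_equal(base, scaled)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            CalibratedPredictor(model=None, temperature=0.0)


class TestUncertainty:
    def test_one_hot_pixel_is_certain(self):
        probs = np.zeros((4, 4, 12))
        probs[..., 3] = 1.0
        assert np.array_equal(uncertainty_map(probs), np.zeros((4, 4)))

    def test_uniform_posterior_is_maximal(self):
        probs = np.full((2, 2, 12), 1 / 12)
        assert uncertainty_map(probs) == pytest.approx(11 / 12)

    def test_invariant_to_class_permutation(self, rng):
        probs = rng.dirichlet(np.ones(12), size=(5, 5))
        perm = rng.permutation(12)
        assert np.allclose(uncertainty_map(probs),
                           uncertainty_map(probs[..., perm]))

    def test_unnormalized_rows_rejected(self):
        probs = np.full((2, 2, 12), 0.2)
        with pytest.raises(ValueError, match="sum to 1"):
            uncertainty_map(probs)

    def test_bounds_hold_on_model_output(self, tiny_spec, small_tiles):
        model = SegFormer(tiny_spec, seed=0)
        _, probs = model.predict(small_tiles[0].image)
        u = uncertainty_map(probs)
        assert (u >= 0).all() and (u <= 11 / 12 + 1e-9).all()


class TestBaseline:
    def test_majority_baseline_on_skewed_mask(self):
        masks = np.zeros((1, 10, 10), dtype=int)
        masks[0, 0, :5] = 1
        # majority = class 0: IoU_0 = 95/100, IoU_1 = 0 -> mean 0.475
        assert majority_baseline_miou(masks, K=2) == pytest.approx(0.475)
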