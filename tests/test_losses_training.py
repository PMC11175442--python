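"""Focal/BCE losses against hand values and a cross-entropy oracle; the
training loop's cropping, determinism and overfitting behavior."""

import math

import numpy as np
import pytest

import ecgdelin as e
from ecgdelin import nn
from ecgdelin.losses import bce_loss_t, focal_loss_t
from ecgdelin.training import _standardize_length
from ecgdelin.types import ConfigError, ConsistencyError


def cross_entropy_reference(probs, labels, floor=1e-7):
    """Independent plain cross-entropy (the gamma = 0 oracle)."""
    pt = probs[np.arange(len(labels)), labels]
    return float(np.mean(-np.log(np.maximum(pt, floor))))


class TestFocalLoss:
    def test_perfect_prediction_is_zero(self):
        labels = np.array([0, 1, 2, 3])
        probs = np.eye(4)[labels]
        assert e.focal_loss(probs, labels, gamma=1.0) == 0.0

    def test_single_point_hand_value(self):
        # true-class probability 0.5 at gamma 1: 0.5 * ln 2
        probs = np.array([[0.5, 0.5, 0.0, 0.0]])
        loss = e.focal_loss(probs, np.array([0]), gamma=1.0)
        assert abs(loss - 0.5 * math.log(2)) < 1e-12

    def test_gamma_zero_equals_cross_entropy(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 50))
            probs = rng.dirichlet(np.ones(4), size=n)
            labels = rng.integers(0, 4, n)
            assert abs(e.focal_loss(probs, labels, gamma=0.0)
                       - cross_entropy_reference(probs, labels)) < 1e-10

    def test_monotone_in_true_class_probability(self):
        values = []
        for p in np.linspace(0.05, 0.95, 19):
            probs = np.array([[p, 1 - p, 0.0, 0.0]])
            values.append(e.focal_loss(probs, np.array([0]), gamma=1.0))
        assert all(a > b for a, b in zip(values, values[1:]))
        assert all(v >= 0 for v in values)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            e.focal_loss(np.eye(4), np.array([0, 1]))

    def test_tensor_form_matches_numpy_form(self, rng, float64_engine):
        probs = rng.dirichlet(np.ones(4), size=30)
        labels = rng.integers(0, 4, 30)
        t = focal_loss_t(nn.Tensor(probs.T[None]), labels[None], 1.0, 1e-7)
        assert abs(float(t.data) - e.focal_loss(probs, labels, 1.0)) < 1e-12


class TestClassificationLoss:
    def test_confident_correct_is_zero(self):
        assert e.classification_loss(e.RhythmProb(1.0), True) == 0.0

    def test_symmetric_half(self):
        assert abs(e.classification_loss(e.RhythmProb(0.5), True) - math.log(2)) < 1e-9

    def test_confident_wrong(self):
        loss = e.classification_loss(e.RhythmProb(0.9), False)
        assert abs(loss - (-math.log(0.1))) < 1e-9

    def test_tensor_form(self, float64_engine):
        probs = nn.Tensor(np.array([[0.9, 0.1], [0.3, 0.7]]))
        loss = bce_loss_t(probs, np.array([0, 1]), 1e-12)
        expected = -(math.log(0.9) + math.log(0.7)) / 2
        assert abs(float(loss.data) - expected) < 1e-12


class TestTotalLoss:
    def test_alpha_zero(self):
        assert e.total_loss(0.3, 0.7, alpha=0.0) == 0.3

    def test_unit_alpha(self):
        assert e.total_loss(0.3, 0.7, alpha=1.0) == 1.0

    def test_scaled(self):
        assert e.total_loss(0.0, 0.5, alpha=2.0) == 1.0


class TestTrainingCrop:
    def test_central_six_seconds_at_500hz(self, nsr_record):
        out = e.training_crop(nsr_record)
        assert out.signal.n_samples == 3000
        np.testing.assert_array_equal(out.signal.samples,
                                      nsr_record.signal.samples[1000:4000])
        np.testing.assert_array_equal(out.mask.labels,
                                      nsr_record.mask.labels[1000:4000])

    def test_same_rule_at_250hz(self, specs):
        rec = e.synthesize_record(specs["NSR"], 10, 250, 0)
        out = e.training_crop(rec)
        assert out.signal.n_samples == 1500
        np.testing.assert_array_equal(out.signal.samples, rec.signal.samples[500:2000])

    def test_short_record_rejected(self, specs):
        rec = e.synthesize_record(specs["NSR"], 4, 500, 0)
        with pytest.raises(ConfigError):
            e.training_crop(rec)

    def test_standardize_length(self):
        s = np.arange(10.0)
        l = np.arange(10) % 4
        s2, l2 = _standardize_length(s, l, 6)
        assert s2.size == l2.size == 6 and s2[0] == 2.0
        s3, l3 = _standardize_length(s, l, 13)
        assert s3.size == 13 and np.all(s3[10:] == 9.0) and np.all(l3[10:] == l[-1])


MICRO = e.ModelConfig(encoder_channels=(4, 6, 8, 10, 12), agg_channels=3,
                      decoder_convs_per_block=1, convs_per_block=1)


def micro_dataset(n=4, rhythm="NSR", duration=6.0):
    specs = e.default_specs()
    return [e.synthesize_record(specs[rhythm], duration, 500, 7, record_id=f"r{i}")
            for i in range(n)]


class TestTrain:
    def test_overfits_identical_records(self):
        data = micro_dataset(8)
        cfg = e.TrainConfig(epochs=50, batch_size=2, seed=0, augment=None)
        _, history = e.train(data, MICRO, e.LossConfig(), cfg)
        assert history[-1] < 0.1 * history[0]

    def test_two_runs_identical(self):
        data = micro_dataset(4)
        cfg = e.TrainConfig(epochs=2, batch_size=4, seed=3)
        net_a, hist_a = e.train(data, MICRO, e.LossConfig(), cfg)
        net_b, hist_b = e.train(data, MICRO, e.LossConfig(), cfg)
        assert hist_a == hist_b
        for pa, pb in zip(net_a.params(), net_b.params()):
            assert np.array_equal(pa.data, pb.data)

    def test_loss_history_finite_on_random_data(self, rng):
        records = []
        for i in range(4):
            samples = rng.normal(0, 1, 3000)
            labels = rng.integers(0, 4, 3000).astype(np.int8)
            mask = e.LabelMask(labels, 500)
            records.append(e.SynthRecord(
                signal=e.EcgSignal(samples, 500, "I", f"x{i}"), mask=mask,
                truth=e.mask_to_delineation(mask), rhythm="NSR"))
        cfg = e.TrainConfig(epochs=2, batch_size=2, seed=0, crop_margin_s=1.0)
        _, history = e.train(records, MICRO, e.LossConfig(), cfg)
        assert all(np.isfinite(history))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ConfigError):
            e.train([], MICRO, e.LossConfig(), e.TrainConfig(epochs=1))

    def test_rate_mismatch_rejected(self, specs):
        rec250 = e.synthesize_record(specs["NSR"], 10, 250, 0)
        with pytest.raises(ConsistencyError):
            e.train([rec250], MICRO, e.LossConfig(), e.TrainConfig(epochs=1))
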