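"""Shallow features, subject split, metrics identity, training behavior."""

import numpy as np
import pandas as pd
import pytest

from leansense import (
    DatasetSplit,
    Metrics,
    SoftSensorConfig,
    build_model,
    evaluate,
    shallow_features,
    split_by_subject,
    train,
)
from leansense.encoder import EncodedImage, ImageDatasetManifest
from leansense.nn import softmax
from leansense.preprocess import Segment


def make_segment(data, fs=128.0):
    return Segment("S01", "KATA", "KATA-III", 0, fs, np.asarray(data, float))


class TestShallowFeatures:
    def test_length_is_five_per_channel(self, rng):
        f = shallow_features(make_segment(rng.uniform(0, 1, (14, 128))))
        assert f.shape == (70,)

    def test_constant_channel_zero_sd_and_band_power(self):
        data = np.full((14, 128), 0.5)
        f = shallow_features(make_segment(data)).reshape(14, 5)
        assert np.allclose(f[:, 0], 0.5)       # mean
        assert np.allclose(f[:, 1], 0.0)       # sd
        assert np.allclose(f[:, 2:], 0.0)      # band powers

    def test_alpha_band_dominates_for_10hz_tone(self):
        """Periodogram oracle: a pure 10 Hz sinusoid concentrates its
        power in the alpha band (8-13 Hz)."""
        t = np.arange(128) / 128.0
        data = np.tile(0.5 + 0.5 * np.sin(2 * np.pi * 10 * t), (14, 1))
        f = shallow_features(make_segment(data)).reshape(14, 5)
        theta, alpha, beta = f[0, 2], f[0, 3], f[0, 4]
        assert alpha > 10 * theta and alpha > 10 * beta

    def test_wrong_sample_count_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            shallow_features(make_segment(np.zeros((14, 100))))


def manifest_of(subjects, n_per_class=4, seed=0):
    """Tiny in-memory image dataset with both classes per subject."""
    rng = np.random.default_rng(seed)
    rows, images = [], []
    for sid in subjects:
        for task in ("KATA", "CPDnA"):
            for i in range(n_per_class):
                pix = rng.integers(0, 256, (5, 128, 3), dtype=np.uint8)
                images.append(EncodedImage(pix, task, sid, i))
                rows.append({"path": "", "subject_id": sid, "task": task,
                             "subtask": "x", "segment_index": i})
    return ImageDatasetManifest(pd.DataFrame(rows), images)


class TestSplitBySubject:
    def test_24_subjects_split_20_2_2(self):
        man = manifest_of([f"S{i:02d}" for i in range(24)], n_per_class=1)
        split = split_by_subject(man, seed=1)
        assert (len(split.train_subjects), len(split.validation_subjects),
                len(split.test_subjects)) == (20, 2, 2)

    def test_disjoint_and_complete(self):
        subjects = [f"S{i:02d}" for i in range(24)]
        split = split_by_subject(manifest_of(subjects, 1), seed=3)
        parts = [set(split.train_subjects), set(split.validation_subjects),
                 set(split.test_subjects)]
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
        assert parts[0] | parts[1] | parts[2] == set(subjects)

    def test_seed_determinism(self):
        man = manifest_of([f"S{i:02d}" for i in range(10)], 1)
        assert split_by_subject(man, seed=9) == split_by_subject(man, seed=9)
        assert split_by_subject(man, seed=9) != split_by_subject(man, seed=10)

    def test_bad_ratios_rejected(self):
        man = manifest_of(["A", "B", "C", "D"], 1)
        with pytest.raises(ValueError, match="sum"):
            split_by_subject(man, ratios=(0.5, 0.2, 0.2))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            split_by_subject(manifest_of(["A", "B"], 1))


class TestModel:
    def test_softmax_normalized_and_forward_shapes(self, rng):
        sensor = build_model(SoftSensorConfig(seed=1))
        x = rng.uniform(0, 1, (6, 5, 128, 3)).astype(np.float32)
        f = rng.standard_normal((6, 70)).astype(np.float32)
        p = sensor.predict_proba(x, f)
        assert p.shape == (6, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_untrained_model_near_chance(self, small_dataset):
        from leansense.softsensor import dataset_arrays
        sensor = build_model(SoftSensorConfig(seed=2))
        x, f, y, _ = dataset_arrays(small_dataset)
        acc = (sensor.predict(x, f) == y).mean()
        assert 0.4 <= acc <= 0.6

    def test_wrong_feature_width_rejected(self, rng):
        sensor = build_model(SoftSensorConfig(seed=0))
        x = rng.uniform(0, 1, (2, 5, 128, 3)).astype(np.float32)
        with pytest.raises(ValueError, match="features"):
            sensor.predict_proba(x, rng.standard_normal((2, 10)))

    def test_oversized_pooling_rejected(self):
        cfg = SoftSensorConfig(conv_blocks=[(8, (3, 3), (2, 2)),
                                            (8, (3, 3), (2, 2)),
                                            (8, (3, 3), (2, 200))])
        with pytest.raises(ValueError, match="ooling"):
            build_model(cfg)


class TestMetrics:
    def test_acc_identity(self):
        m = Metrics(TP=250, TN=250, FP=0, FN=0)
        assert m.ACC == 1.0
        m = Metrics(TP=0, TN=250, FP=0, FN=250)  # all-KATA predictor
        assert m.ACC == 0.5
        m = Metrics(TP=37, TN=41, FP=11, FN=13)
        assert m.ACC == pytest.approx((37 + 41) / 102)
        assert m.confusion.sum() == 102

    def test_leakage_rejected(self, small_dataset):
        sensor = build_model(SoftSensorConfig(seed=0))
        bad = DatasetSplit(("S01", "S02"), ("S03",), ("S04",))
        overlapping = DatasetSplit.__new__(DatasetSplit)
        overlapping.train_subjects = ("S01", "S04")
        overlapping.validation_subjects = ("S03",)
        overlapping.test_subjects = ("S04",)
        overlapping.ratios = (0.8, 0.1, 0.1)
        with pytest.raises(ValueError, match="overlap"):
            evaluate(sensor, small_dataset, overlapping)
        with pytest.raises(ValueError):
            DatasetSplit(("S01", "S04"), ("S03",), ("S04",))
        assert bad  # constructing a valid split raises nothing


class TestTraining:
    def test_zero_learning_rate_stays_at_chance(self, small_dataset):
        cfg = SoftSensorConfig(learning_rate=0.0, epochs=2, seed=4)
        split = split_by_subject(small_dataset, seed=4)
        sensor, hist = train(build_model(cfg), small_dataset, split, cfg)
        assert (hist["train_acc"] - 0.5).abs().max() < 0.1

    def test_learns_separable_classes_and_plateaus(self, small_dataset):
        """On regime-separated data the loss drops from epoch 1 and the
        accuracy plateaus once converged (last four epochs within 0.05)."""
        cfg = SoftSensorConfig(seed=5)  # default 10 epochs
        split = split_by_subject(small_dataset, seed=5)
        sensor, hist = train(build_model(cfg), small_dataset, split, cfg)
        assert hist["train_loss"].iloc[0] > hist["train_loss"].min()
        tail = hist["train_acc"].iloc[-4:]
        assert tail.max() - tail.min() <= 0.05
        m = evaluate(sensor, small_dataset, split)
        assert m.ACC >= 0.95
        assert m.TP + m.TN + m.FP + m.FN == 500

    def test_history_schema(self, small_dataset):
        cfg = SoftSensorConfig(epochs=1, seed=6)
        split = split_by_subject(small_dataset, seed=6)
        _, hist = train(build_model(cfg), small_dataset, split, cfg)
        assert list(hist.columns) == ["epoch", "train_acc", "val_acc",
                                      "train_loss", "val_loss"]


def test_save_load_round_trip(tmp_path, small_dataset, rng):
    from leansense.softsensor import SoftSensor, dataset_arrays
    cfg = SoftSensorConfig(epochs=1, seed=7)
    split = split_by_subject(small_dataset, seed=7)
    sensor, _ = train(build_model(cfg), small_dataset, split, cfg)
    sensor.save(tmp_path / "model")
    back = SoftSensor.load(tmp_path / "model")
    x, f, _, _ = dataset_arrays(small_dataset)
    assert np.allclose(sensor.predict_proba(x[:8], f[:8]),
                       back.predict_proba(x[:8], f[:8]), atol=1e-6)
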