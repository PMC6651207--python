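"""The convolutional soft sensor: KATA vs (CPD)nA from encoded segments.

A small CNN ingests the 5 x 128 x 3 RGB encodings of 1-s segments. Its
flattened deep features are merged with a vector of shallow features
(per-channel mean, standard deviation and theta/alpha/beta band powers)
on the last fully connected layer, followed by a softmax over the two
behavioral classes. Dataset splitting is by *subject* (80/10/10), never
by segment, so evaluation is always on unseen subjects and segment-level
leakage is impossible by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .encoder import ImageDatasetManifest, decode_image
from .montage import CHANNELS
from .nn import Adam, ConvNet, softmax_xent
from .preprocess import Segment

#: Class order: index 0 = KATA, index 1 = (CPD)nA (the "positive" class).
CLASSES = ("KATA", "CPDnA")

#: EEG frequency bands for the shallow band-power features, Hz.
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}


@dataclass
class SoftSensorConfig:
    """Architecture and training hyperparameters.

    Defaults: two conv blocks (32 then 64 filters, 3x3 kernels, 2x2 max
    pooling, pool clipped to the remaining height), a 128-unit dense
    layer, Adam at 1e-3, batch 32, 10 epochs. One seed drives weight
    init, shuffling and the subject split.
    """

    conv_blocks: list = field(default_factory=lambda: [
        (32, (3, 3), (2, 2)),
        (64, (3, 3), (2, 2)),
    ])
    dense_units: int = 128
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0
    shallow_features: tuple[str, ...] = ("mean", "sd", "theta", "alpha", "beta")
    global_avg_pool: bool = True

    def __post_init__(self) -> None:
        if not self.conv_blocks:
            raise ValueError("need at least one conv block")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1 or self.dense_units < 1:
            raise ValueError("sizes must be positive")


@dataclass
class DatasetSplit:
    """Disjoint subject-id partitions."""

    train_subjects: tuple[str, ...]
    validation_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self) -> None:
        parts = [set(self.train_subjects), set(self.validation_subjects),
                 set(self.test_subjects)]
        if sum(len(p) for p in parts) != len(set().union(*parts)):
            raise ValueError("split partitions must be disjoint")


@dataclass
class Metrics:
    """Binary confusion counts and accuracy ((CPD)nA is the positive class)."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def ACC(self) -> float:
        return (self.TP + self.TN) / (self.TP + self.TN + self.FP + self.FN)

    @property
    def confusion(self) -> np.ndarray:
        """2x2 matrix, rows = true (KATA, CPDnA), cols = predicted."""
        return np.array([[self.TN, self.FP], [self.FN, self.TP]])

    def to_dict(self) -> dict:
        return {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
                "ACC": self.ACC}


def shallow_feature_vector(data: np.ndarray, fs: float,
                           names: tuple[str, ...] = ("mean", "sd", "theta",
                                                     "alpha", "beta")) -> np.ndarray:
    """Shallow features of one ``(n_channels, n_samples)`` segment.

    Per channel: mean, standard deviation and periodogram band powers in
    theta (4-8 Hz), alpha (8-13 Hz), beta (13-30 Hz) — channel-major
    ordering, so the default montage yields 5 x 14 = 70 values.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    freqs, psd = sp_signal.periodogram(data, fs=fs, axis=-1)
    cols = []
    for name in names:
        if name == "mean":
            cols.append(data.mean(axis=-1))
        elif name == "sd":
            cols.append(data.std(axis=-1))
        elif name in BANDS:
            lo, hi = BANDS[name]
            band = (freqs >= lo) & (freqs < hi)
            cols.append(psd[..., band].sum(axis=-1))
        else:
            raise ValueError(f"unknown shallow feature {name!r}")
    return np.stack(cols, axis=-1).ravel()  # (n_channels * n_features,)


def shallow_features(segment: Segment,
                     names: tuple[str, ...] = ("mean", "sd", "theta",
                                               "alpha", "beta")) -> np.ndarray:
    """Shallow feature vector of a normalized 1-s segment."""
    expected = int(round(segment.fs))
    if segment.data.shape[-1] != expected:
        raise ValueError(
            f"segment has {segment.data.shape[-1]} samples, expected {expected}"
        )
    return shallow_feature_vector(segment.data, segment.fs, names)


class SoftSensor:
    """Trained classifier: CNN + input normalization + class order.

    Each image row-channel is standardized over time before the first
    convolution: the class signal is cross-channel co-movement, which is
    amplitude-invariant, whereas per-session amplitude profiles are
    subject fingerprints that must not drive the decision. The shallow
    features are likewise z-scored per recording session upstream (see
    :func:`dataset_arrays`) and per-feature on the training set here.
    """

    def __init__(self, net: ConvNet, config: SoftSensorConfig,
                 montage: tuple[str, ...] = CHANNELS, fs: float = 128.0) -> None:
        self.net = net
        self.config = config
        self.montage = tuple(montage)
        self.fs = fs
        self.feat_mean = np.zeros(net.n_features, dtype=np.float32)
        self.feat_sd = np.ones(net.n_features, dtype=np.float32)

    @staticmethod
    def standardize_images(images: np.ndarray) -> np.ndarray:
        """Zero-mean/unit-variance per image row-channel over time."""
        x = np.asarray(images, dtype=np.float32)
        m = x.mean(axis=2, keepdims=True)
        s = x.std(axis=2, keepdims=True)
        return ((x - m) / (s + 1e-6)).astype(np.float32)

    def _prep_features(self, feats: np.ndarray) -> np.ndarray:
        feats = np.asarray(feats, dtype=np.float32)
        if feats.ndim != 2 or feats.shape[1] != self.net.n_features:
            raise ValueError(
                f"expected {self.net.n_features} shallow features per image"
            )
        return (feats - self.feat_mean) / self.feat_sd

    def predict_proba(self, images: np.ndarray, feats: np.ndarray) -> np.ndarray:
        """Class probabilities for raw [0, 1] images + shallow features."""
        return self.net.predict_proba(self.standardize_images(images),
                                      self._prep_features(feats))

    def predict(self, images: np.ndarray, feats: np.ndarray) -> np.ndarray:
        return self.predict_proba(images, feats).argmax(axis=1)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "weights.npz",
                 *self.net.get_weights(),
                 feat_mean=self.feat_mean, feat_sd=self.feat_sd)
        (out / "model.json").write_text(json.dumps({
            "conv_blocks": self.config.conv_blocks,
            "dense_units": self.config.dense_units,
            "learning_rate": self.config.learning_rate,
            "epochs": self.config.epochs,
            "batch_size": self.config.batch_size,
            "seed": self.config.seed,
            "shallow_features": list(self.config.shallow_features),
            "global_avg_pool": self.config.global_avg_pool,
            "montage": list(self.montage),
            "fs": self.fs,
            "input_shape": list(self.net.input_shape),
        }, indent=2))

    @classmethod
    def load(cls, out_dir: str | Path) -> "SoftSensor":
        out = Path(out_dir)
        meta = json.loads((out / "model.json").read_text())
        config = SoftSensorConfig(
            conv_blocks=[(f, tuple(k), tuple(p)) for f, k, p in meta["conv_blocks"]],
            dense_units=meta["dense_units"],
            learning_rate=meta["learning_rate"],
            epochs=meta["epochs"],
            batch_size=meta["batch_size"],
            seed=meta["seed"],
            shallow_features=tuple(meta["shallow_features"]),
            global_avg_pool=meta.get("global_avg_pool", True),
        )
        sensor = build_model(config, input_shape=tuple(meta["input_shape"]),
                             montage=tuple(meta["montage"]), fs=meta["fs"])
        with np.load(out / "weights.npz") as z:
            n = len(sensor.net.params)
            sensor.net.set_weights([z[f"arr_{i}"] for i in range(n)])
            sensor.feat_mean = z["feat_mean"]
            sensor.feat_sd = z["feat_sd"]
        return sensor


def build_model(config: SoftSensorConfig,
                input_shape: tuple[int, int, int] = (5, 128, 3),
                n_classes: int = 2,
                montage: tuple[str, ...] = CHANNELS,
                fs: float = 128.0) -> SoftSensor:
    """Assemble the soft sensor for a given image shape and montage."""
    n_features = len(config.shallow_features) * len(montage)
    net = ConvNet(
        input_shape=input_shape,
        conv_blocks=[(f, tuple(k), tuple(p)) for f, k, p in config.conv_blocks],
        n_features=n_features,
        dense_units=config.dense_units,
        n_classes=n_classes,
        seed=config.seed,
        global_avg_pool=config.global_avg_pool,
    )
    return SoftSensor(net, config, montage=montage, fs=fs)


def split_by_subject(manifest: ImageDatasetManifest,
                     ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     seed: int = 0) -> DatasetSplit:
    """Random 80/10/10 split by subject (20/2/2 at a 24-subject cohort)."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    subjects = sorted(manifest.entries["subject_id"].unique())
    n = len(subjects)
    if n < 4:
        raise ValueError("need at least 4 subjects to split 80/10/10")
    n_val = max(1, round(n * ratios[1]))
    n_test = max(1, round(n * ratios[2]))
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [subjects[i] for i in order]
    test = tuple(shuffled[:n_test])
    val = tuple(shuffled[n_test:n_test + n_val])
    train = tuple(shuffled[n_test + n_val:])
    split = DatasetSplit(train, val, test, ratios)
    # every partition must contain both classes
    for part in (train, val, test):
        tasks = set(manifest.entries.loc[
            manifest.entries["subject_id"].isin(part), "task"])
        if set(CLASSES) - tasks:
            raise ValueError("a partition lacks one of the classes")
    return split


def dataset_arrays(manifest: ImageDatasetManifest,
                   montage: tuple[str, ...] = CHANNELS,
                   fs: float = 128.0,
                   feature_names: tuple[str, ...] = ("mean", "sd", "theta",
                                                     "alpha", "beta"),
                   session_standardize: bool = True
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Images, shallow features, integer labels and subject ids as arrays.

    Shallow features are computed from the decoded images, so training
    and inference see identical (quantized) inputs. With
    ``session_standardize`` (default) each feature is z-scored within its
    recording session (subject x task): session-level amplitude profiles
    are arbitrary after the anonymizing [0, 1] normalization and act as
    subject fingerprints, so only within-session feature variation is
    presented to the classifier. Session statistics never cross subjects,
    so the subject-level train/test separation is untouched.
    """
    imgs = np.stack([img.pixels for img in manifest.images])
    x = imgs.astype(np.float32) / 255.0
    decoded = np.stack([decode_image(img, montage) for img in manifest.images])
    freqs, psd = sp_signal.periodogram(decoded, fs=fs, axis=-1)
    cols = []
    for name in feature_names:
        if name == "mean":
            cols.append(decoded.mean(axis=-1))
        elif name == "sd":
            cols.append(decoded.std(axis=-1))
        elif name in BANDS:
            lo, hi = BANDS[name]
            band = (freqs >= lo) & (freqs < hi)
            cols.append(psd[..., band].sum(axis=-1))
        else:
            raise ValueError(f"unknown shallow feature {name!r}")
    feats = np.stack(cols, axis=-1).reshape(len(manifest.images), -1).astype(np.float32)
    y = np.array([CLASSES.index(img.label) for img in manifest.images])
    subjects = manifest.entries["subject_id"].to_numpy()
    if session_standardize:
        tasks = manifest.entries["task"].to_numpy()
        sessions = np.char.add(subjects.astype(str), np.char.add("/", tasks.astype(str)))
        for sess in np.unique(sessions):
            rows = sessions == sess
            m = feats[rows].mean(axis=0)
            s = feats[rows].std(axis=0)
            feats[rows] = (feats[rows] - m) / (s + 1e-6)
    return x, feats, y, subjects


def train(sensor: SoftSensor, manifest: ImageDatasetManifest,
          split: DatasetSplit,
          config: SoftSensorConfig | None = None
          ) -> tuple[SoftSensor, pd.DataFrame]:
    """Train on the train partition; select the best epoch on validation.

    Returns the sensor (weights restored to the best-validation epoch,
    ties broken toward the earliest epoch) and a per-epoch history table
    (epoch, train_acc, val_acc, train_loss, val_loss).
    """
    if config is None:
        config = sensor.config
    x, feats, y, subjects = dataset_arrays(
        manifest, sensor.montage, sensor.fs, config.shallow_features)
    x = sensor.standardize_images(x)
    tr = np.isin(subjects, split.train_subjects)
    va = np.isin(subjects, split.validation_subjects)
    if tr.sum() == 0 or va.sum() == 0:
        raise ValueError("empty train or validation partition")

    # standardize shallow features on the training partition only
    sensor.feat_mean = feats[tr].mean(axis=0)
    sd = feats[tr].std(axis=0)
    sd[sd == 0] = 1.0
    sensor.feat_sd = sd
    f_std = sensor._prep_features(feats)

    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(sensor.net.params, lr=config.learning_rate)
    idx_tr = np.nonzero(tr)[0]
    history = []
    best = (-1.0, None, None)  # (val_acc, epoch, weights)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(idx_tr)
        losses, correct = [], 0
        for i in range(0, len(order), config.batch_size):
            b = order[i:i + config.batch_size]
            logits = sensor.net.forward(x[b], f_std[b])
            loss, dlogits = softmax_xent(logits, y[b])
            grads = sensor.net.backward(dlogits)
            opt.step(grads)
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y[b]).sum())
        train_acc = correct / len(order)
        val_p = sensor.net.predict_proba(x[va], f_std[va])
        val_pred = val_p.argmax(axis=1)
        val_acc = float((val_pred == y[va]).mean())
        val_loss = float(-np.log(np.clip(
            val_p[np.arange(va.sum()), y[va]], 1e-12, None)).mean())
        history.append({"epoch": epoch, "train_acc": train_acc,
                        "val_acc": val_acc,
                        "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss})
        if val_acc > best[0]:
            best = (val_acc, epoch, sensor.net.get_weights())
    if best[2] is not None:
        sensor.net.set_weights(best[2])
    return sensor, pd.DataFrame(history)


def evaluate(sensor: SoftSensor, manifest: ImageDatasetManifest,
             split: DatasetSplit) -> Metrics:
    """Confusion counts and accuracy on the held-out test subjects."""
    if set(split.train_subjects) & set(split.test_subjects):
        raise ValueError("train and test subjects overlap")
    x, feats, y, subjects = dataset_arrays(
        manifest, sensor.montage, sensor.fs, sensor.config.shallow_features)
    te = np.isin(subjects, split.test_subjects)
    if te.sum() == 0:
        raise ValueError("empty test partition")
    pred = sensor.predict(x[te], feats[te])
    truth = y[te]
    return Metrics(
        TP=int(np.sum((pred == 1) & (truth == 1))),
        TN=int(np.sum((pred == 0) & (truth == 0))),
        FP=int(np.sum((pred == 1) & (truth == 0))),
        FN=int(np.sum((pred == 0) & (truth == 1))),
    )
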