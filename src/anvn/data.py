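"""Labeled image-like data for the energy-coupled perceptron.

Two sources: a synthetic generator producing an MNIST-like 10-class,
784-feature problem (per-class random prototype plus Gaussian pixel
noise, clipped to [0, 1]) so every experiment runs without downloads, and
a reader/writer for the IDX binary format in which the real digit
datasets are distributed.

Default sample sizes are 500 training and 200 test points.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Dataset",
    "make_synthetic",
    "make_transfer_pair",
    "one_hot",
    "nearest_prototype_accuracy",
    "read_idx",
    "write_idx_images",
    "write_idx_labels",
    "load_idx_dataset",
]

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


@dataclass
class Dataset:
    """Flat-vector classification data with disjoint train/test splits."""

    x_train: np.ndarray   # (n_train, n_features), values in [0, 1]
    y_train: np.ndarray   # int labels in 0..n_classes-1
    x_test: np.ndarray
    y_test: np.ndarray
    n_classes: int
    prototypes: np.ndarray | None = None   # (n_classes, n_features), synthetic only

    @property
    def n_features(self) -> int:
        return self.x_train.shape[1]


def one_hot(labels: np.ndarray, n_classes: int = 10) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError("label outside 0..n_classes-1")
    out = np.zeros((labels.shape[0], n_classes))
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def _sample(prototypes, n, n_classes, noise_sd, rng):
    labels = rng.integers(0, n_classes, size=n)
    x = prototypes[labels] + rng.normal(0.0, noise_sd, size=(n, prototypes.shape[1]))
    return np.clip(x, 0.0, 1.0), labels


def _stroke_prototypes(n_classes, n_features, density, rng):
    # digit-like sparse patterns: a dark background with a class-specific
    # subset of bright pixels.  Stroke density varies by class (a "1" has
    # far less ink than an "8"), drawn around the nominal density; this
    # heterogeneity is what gives hidden neurons diverse thresholds.
    protos = np.zeros((n_classes, n_features))
    for c in range(n_classes):
        class_density = rng.uniform(0.5 * density, 1.8 * density)
        brightness = rng.uniform(0.3, 0.65)
        n_on = max(1, int(round(class_density * n_features)))
        idx = rng.choice(n_features, size=n_on, replace=False)
        protos[c, idx] = np.clip(
            brightness + rng.uniform(-0.1, 0.1, size=n_on), 0.0, 1.0
        )
    return protos


def make_synthetic(
    n_train: int = 500,
    n_test: int = 200,
    n_classes: int = 10,
    n_features: int = 784,
    noise_sd: float = 0.25,
    seed: int | np.random.Generator = 0,
    prototypes: np.ndarray | None = None,
    stroke_density: float = 0.15,
) -> Dataset:
    """Class-prototype data: each class has a fixed random prototype in
    [0, 1]^n_features; samples are the prototype plus N(0, noise_sd) pixel
    noise, clipped back to [0, 1].

    Prototypes are sparse and stroke-like — a dark background with a
    class-specific subset (``stroke_density`` of the pixels) of bright
    values — matching the statistics of handwritten-digit images.  At the
    default noise level the classes are cleanly separable (a
    nearest-prototype classifier scores well above 95%), mimicking the
    regime in which a small perceptron trained on 500 digits reaches high
    accuracy.  Fully reproducible under a fixed seed.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("split sizes must be positive")
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    if prototypes is None:
        prototypes = _stroke_prototypes(n_classes, n_features, stroke_density, rng)
    else:
        prototypes = np.asarray(prototypes, dtype=float)
    x_train, y_train = _sample(prototypes, n_train, n_classes, noise_sd, rng)
    x_test, y_test = _sample(prototypes, n_test, n_classes, noise_sd, rng)
    return Dataset(x_train, y_train, x_test, y_test, n_classes, prototypes)


def make_transfer_pair(
    seed: int = 0, mix: float = 0.5, **kwargs
) -> tuple[Dataset, Dataset]:
    """A pair of related datasets for transfer-learning experiments.

    Dataset B's prototypes are a convex mix (weight ``mix``) of A's
    prototypes with a fresh random set, emulating retraining on a similar
    but distinct problem (digits then letters).
    """
    rng = np.random.default_rng(seed)
    a = make_synthetic(seed=rng, **kwargs)
    fresh = _stroke_prototypes(
        a.prototypes.shape[0], a.prototypes.shape[1],
        kwargs.get("stroke_density", 0.15), rng,
    )
    proto_b = mix * a.prototypes + (1.0 - mix) * fresh
    b = make_synthetic(seed=rng, prototypes=proto_b, **kwargs)
    return a, b


def nearest_prototype_accuracy(ds: Dataset) -> float:
    """Percent of test points whose nearest class prototype is their label."""
    if ds.prototypes is None:
        raise ValueError("dataset has no prototypes")
    d2 = ((ds.x_test[:, None, :] - ds.prototypes[None, :, :]) ** 2).sum(axis=2)
    return 100.0 * np.mean(np.argmin(d2, axis=1) == ds.y_test)


# ---------------------------------------------------------------------------
# IDX binary format (big-endian; magic 0x00000803 images, 0x00000801 labels)

def read_idx(images_path, labels_path) -> tuple[np.ndarray, np.ndarray]:
    """Read an IDX image/label pair: pixels rescaled to [0, 1] and images
    flattened row-major; labels as integers.  Raises ``ValueError`` on a
    bad magic number or an image/label count mismatch."""
    img_raw = Path(images_path).read_bytes()
    magic, n, rows, cols = struct.unpack(">IIII", img_raw[:16])
    if magic != _IDX_IMAGES_MAGIC:
        raise ValueError(f"bad image magic 0x{magic:08x}")
    pixels = np.frombuffer(img_raw, dtype=np.uint8, offset=16)
    if pixels.size != n * rows * cols:
        raise ValueError("image payload length mismatch")
    x = pixels.reshape(n, rows * cols).astype(float) / 255.0

    lab_raw = Path(labels_path).read_bytes()
    magic, n_lab = struct.unpack(">II", lab_raw[:8])
    if magic != _IDX_LABELS_MAGIC:
        raise ValueError(f"bad label magic 0x{magic:08x}")
    labels = np.frombuffer(lab_raw, dtype=np.uint8, offset=8)
    if labels.size != n_lab or n_lab != n:
        raise ValueError("label count does not match image count")
    return x, labels.astype(np.int64)


def write_idx_images(path, images: np.ndarray) -> None:
    """Write uint8 images of shape (n, rows, cols) in IDX format."""
    images = np.asarray(images, dtype=np.uint8)
    n, rows, cols = images.shape
    with open(path, "wb") as fh:
        fh.write(struct.pack(">IIII", _IDX_IMAGES_MAGIC, n, rows, cols))
        fh.write(images.tobytes())


def write_idx_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels, dtype=np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">II", _IDX_LABELS_MAGIC, labels.size))
        fh.write(labels.tobytes())


def load_idx_dataset(
    train_images, train_labels, test_images, test_labels, n_classes: int = 10
) -> Dataset:
    x_tr, y_tr = read_idx(train_images, train_labels)
    x_te, y_te = read_idx(test_images, test_labels)
    return Dataset(x_tr, y_tr, x_te, y_te, n_classes)
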