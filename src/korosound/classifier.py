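"""Scalogram-image classification with a compact convolutional network.

Recordings become fixed-size RGB scalogram images; a subject-level
stratified split (no subject ever straddles splits) feeds a small
from-scratch CNN (~1e5 parameters), and evaluation reports the
confusion-matrix layout used for binary screening tasks: per-class
recall (sensitivity/specificity), per-class precision, and overall
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._nn import CompactCNN
from .io import Recording
from .preprocess import detect_window
from .timefrequency import cwt_scalogram, scalogram_to_rgb

__all__ = [
    "LabeledImageSet",
    "ConfusionMetrics",
    "TrainConfig",
    "build_dataset",
    "train_compact_cnn",
    "evaluate_classifier",
]


@dataclass
class LabeledImageSet:
    """Labelled scalogram images with subject-level split tags."""

    images: np.ndarray  # (N, H, W, 3) uint8
    labels: np.ndarray  # (N,) int, binary
    subject_ids: np.ndarray  # (N,) str
    split: np.ndarray  # (N,) in {"train", "val", "test"}

    def __post_init__(self):
        n = self.images.shape[0]
        if not (self.labels.size == self.subject_ids.size == self.split.size == n):
            raise ValueError("images, labels, subject_ids, split must align")
        for tag_a in ("train", "val", "test"):
            for tag_b in ("train", "val", "test"):
                if tag_a >= tag_b:
                    continue
                overlap = set(self.subject_ids[self.split == tag_a]) & set(
                    self.subject_ids[self.split == tag_b]
                )
                if overlap:
                    raise ValueError(f"subject(s) {sorted(overlap)} appear in both "
                                     f"{tag_a} and {tag_b} splits")

    def subset(self, tag: str) -> "LabeledImageSet":
        m = self.split == tag
        return LabeledImageSet(
            self.images[m], self.labels[m], self.subject_ids[m], self.split[m]
        )

    def __len__(self) -> int:
        return int(self.images.shape[0])


def _recording_image(
    rec: Recording,
    image_size: int,
    f_min: float,
    f_max: float,
    n_scales: int,
    window_only: bool,
    decimate: int = 4,
) -> np.ndarray:
    x = rec.sound
    if window_only:
        try:
            w = detect_window(rec)
            x = rec.sound[w.start : w.end]
        except ValueError:
            x = rec.sound
    fs = rec.fs
    if decimate > 1 and f_max < fs / (2 * decimate):
        # the analysis band sits far below Nyquist; decimating first cuts
        # the CWT cost by ~decimate^2 without touching the band
        from scipy.signal import decimate as _dec

        x = _dec(x, decimate, zero_phase=True)
        fs = fs / decimate
    sc = cwt_scalogram(x, fs, f_min=f_min, f_max=f_max, n_scales=n_scales)
    return scalogram_to_rgb(sc, image_size, image_size)


def build_dataset(
    recordings: Sequence[Recording],
    labels: Sequence[int],
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
    image_size: int = 64,
    f_min: float = 5.0,
    f_max: float = 100.0,
    n_scales: int = 64,
    window_only: bool = True,
) -> LabeledImageSet:
    """Scalogram images + stratified subject-level train/val/test split.

    Subjects (not recordings) are shuffled and allocated per class at
    the given fractions, so a subject with several recordings lands
    wholly in one split and per-split class ratios track the global
    ratio to within one subject.  Deterministic under ``seed``.
    """
    labels = np.asarray(labels, int)
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if len(recordings) != labels.size:
        raise ValueError("one label per recording required")
    sids = np.array([r.subject_id for r in recordings])
    subj_label = {}
    for sid, lab in zip(sids, labels):
        if subj_label.setdefault(sid, lab) != lab:
            raise ValueError(f"subject {sid} has conflicting labels")
    for cls in np.unique(labels):
        n_cls = len({s for s, l in subj_label.items() if l == cls})
        if n_cls < 10:
            raise ValueError(f"class {cls} has only {n_cls} subjects (need >= 10)")

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for cls in np.unique(labels):
        subj = sorted(s for s, l in subj_label.items() if l == cls)
        subj = [subj[i] for i in rng.permutation(len(subj))]
        n = len(subj)
        n_train = int(round(split_fractions[0] * n))
        n_val = int(round(split_fractions[1] * n))
        n_val = min(n_val, n - n_train)
        for i, s in enumerate(subj):
            assignment[s] = "train" if i < n_train else ("val" if i < n_train + n_val else "test")

    images = np.stack(
        [
            _recording_image(r, image_size, f_min, f_max, n_scales, window_only)
            for r in recordings
        ]
    )
    split = np.array([assignment[s] for s in sids])
    return LabeledImageSet(images=images, labels=labels, subject_ids=sids, split=split)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 25
    batch_size: int = 16
    learning_rate: float = 1e-3


def _to_gray(images: np.ndarray, mean: float = None, sd: float = None):
    x = images.astype(float).mean(axis=-1) / 255.0
    if mean is None:
        mean, sd = float(x.mean()), float(x.std()) or 1.0
    return (x - mean) / sd, mean, sd


def train_compact_cnn(
    train: LabeledImageSet,
    val: LabeledImageSet,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
):
    """Train the compact CNN; returns ``(model, history)``.

    ``history`` is a DataFrame with per-epoch train/val loss and
    accuracy.  Images are collapsed to grayscale and standardized by
    the training-set moments.  Fixed seed gives a reproducible fit.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if np.unique(train.labels).size < 2:
        raise ValueError("degenerate single-class training set")
    x_train, mean, sd = _to_gray(train.images)
    x_val, _, _ = _to_gray(val.images, mean, sd)
    y_train, y_val = train.labels, val.labels

    model = CompactCNN(image_size=train.images.shape[1], n_classes=2, seed=seed)
    model.norm_stats = (mean, sd)
    rng = np.random.default_rng(seed + 1)
    rows = []
    n = x_train.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            model.train_step(x_train[idx], y_train[idx], lr=config.learning_rate)
        tr_loss, tr_acc = model.evaluate(x_train, y_train)
        va_loss, va_acc = model.evaluate(x_val, y_val)
        rows.append(
            {
                "epoch": epoch + 1,
                "train_loss": tr_loss,
                "train_accuracy": tr_acc,
                "val_loss": va_loss,
                "val_accuracy": va_acc,
            }
        )
    return model, pd.DataFrame(rows)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Binary confusion counts and the derived screening metrics."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / max(self.tp + self.fn + self.fp + self.tn, 1)

    @property
    def sensitivity(self) -> float:
        """Recall of the positive class."""
        return self.tp / max(self.tp + self.fn, 1)

    @property
    def specificity(self) -> float:
        """Recall of the negative class."""
        return self.tn / max(self.tn + self.fp, 1)

    @property
    def precision_positive(self) -> float:
        return self.tp / max(self.tp + self.fp, 1)

    @property
    def precision_negative(self) -> float:
        return self.tn / max(self.tn + self.fn, 1)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision_positive": self.precision_positive,
            "precision_negative": self.precision_negative,
        }


def evaluate_classifier(model: CompactCNN, test: LabeledImageSet) -> ConfusionMetrics:
    """Confusion metrics of argmax predictions on a labelled set."""
    if len(test) == 0:
        raise ValueError("empty test set")
    mean, sd = getattr(model, "norm_stats", (None, None))
    x, _, _ = _to_gray(test.images, mean, sd)
    pred = model.predict(x)
    y = test.labels
    return ConfusionMetrics(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        tn=int(np.sum((pred == 0) & (y == 0))),
    )
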