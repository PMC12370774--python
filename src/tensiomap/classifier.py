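"""Supervised pixel classification of untensed vs. non-untensed fiber pixels.

A random forest over hand-crafted multiscale features (raw intensity,
Gaussian-smoothed intensity, gradient magnitude and Laplacian at several
scales, per channel) is trained on sparse manual annotations and applied
within the fibronectin-positive universe: classifier-positive fiber pixels
become the untensed mask and the complement within the fiber mask becomes
the stretched mask, so the two always partition the fiber universe and
background can never count as stretched fiber.

A non-learned baseline (Otsu on the probe channel restricted to the fiber
mask) is provided as a floor the learned model must not fall under.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from ._errors import ConfigError
from .image_io import MultiChannelImage, PixelMask
from .ratiometrics import otsu_threshold

__all__ = [
    "AnnotationSet",
    "PixelClassifierModel",
    "TrainConfig",
    "extract_features",
    "train_pixel_classifier",
    "apply_classifier",
    "threshold_baseline_masks",
    "sample_annotations",
]

FEATURE_VERSION = 1
DEFAULT_SCALES = (1.0, 2.0, 4.0)
DEFAULT_CHANNELS = ("FNBPA5", "FN")

# label-image convention for annotation files: 0 unlabeled, 1 negative, 2 positive
ANNOT_UNLABELED, ANNOT_NEGATIVE, ANNOT_POSITIVE = 0, 1, 2


def feature_names(channels=DEFAULT_CHANNELS, scales=DEFAULT_SCALES) -> list:
    names = []
    for ch in channels:
        names.append(f"{ch}:raw")
        for s in scales:
            names += [f"{ch}:gauss{s:g}", f"{ch}:gradmag{s:g}", f"{ch}:laplace{s:g}"]
    return names


def extract_features(
    image: MultiChannelImage,
    scales=DEFAULT_SCALES,
    channels=DEFAULT_CHANNELS,
) -> np.ndarray:
    """Per-pixel feature stack, shape (rows, cols, n_features), float32.

    Feature order is fixed and versioned (see :func:`feature_names`).
    """
    if any(s <= 0 for s in scales):
        raise ConfigError(f"feature scales must be > 0, got {scales}")
    image.require(*channels)
    stack = []
    for ch in channels:
        a = image[ch]
        stack.append(a)
        for s in scales:
            stack.append(ndimage.gaussian_filter(a, s))
            stack.append(ndimage.gaussian_gradient_magnitude(a, s))
            stack.append(ndimage.gaussian_laplace(a, s))
    return np.stack(stack, axis=-1).astype(np.float32)


@dataclass
class AnnotationSet:
    """Sparse manual annotations: untensed-positive and negative pixels."""

    positive_mask: PixelMask
    negative_mask: PixelMask

    def __post_init__(self):
        if self.positive_mask.grid.shape != self.negative_mask.grid.shape:
            raise ConfigError("annotation mask shapes differ")
        if (self.positive_mask.grid & self.negative_mask.grid).any():
            raise ConfigError("positive and negative annotations overlap")

    @classmethod
    def from_label_grid(cls, labels: np.ndarray, pixel_size_um: float) -> "AnnotationSet":
        labels = np.asarray(labels)
        return cls(
            PixelMask(labels == ANNOT_POSITIVE, "annot_positive", pixel_size_um),
            PixelMask(labels == ANNOT_NEGATIVE, "annot_negative", pixel_size_um),
        )


@dataclass
class TrainConfig:
    scales: tuple = DEFAULT_SCALES
    channels: tuple = DEFAULT_CHANNELS
    n_trees: int = 100
    seed: int = 0
    prob_threshold: float = 0.5
    min_pixels_per_class: int = 100
    holdout_fraction: float = 0.2


@dataclass
class PixelClassifierModel:
    """A fitted forest plus the feature spec that produced its inputs.

    Applying the model twice to the same image yields identical masks:
    the forest seed, feature scales/channels and probability threshold are
    all frozen inside the model.
    """

    forest: RandomForestClassifier
    scales: tuple
    channels: tuple
    prob_threshold: float
    seed: int
    feature_version: int = FEATURE_VERSION
    training_report: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, Path(path))

    @classmethod
    def load(cls, path) -> "PixelClassifierModel":
        model = joblib.load(Path(path))
        if model.feature_version != FEATURE_VERSION:
            raise ConfigError(
                f"model feature version {model.feature_version} != {FEATURE_VERSION}"
            )
        return model


def train_pixel_classifier(
    annotations: AnnotationSet,
    image: MultiChannelImage,
    config: TrainConfig | None = None,
) -> PixelClassifierModel:
    """Fit the forest on annotated pixels; report held-out accuracy.

    A stratified 20% pixel holdout estimates accuracy; the training report
    flags chance-level performance (degenerate annotations). Raises
    :class:`ConfigError` when a class has fewer than
    ``min_pixels_per_class`` annotated pixels.
    """
    cfg = config or TrainConfig()
    n_pos = annotations.positive_mask.count
    n_neg = annotations.negative_mask.count
    if min(n_pos, n_neg) < cfg.min_pixels_per_class:
        raise ConfigError(
            f"need >= {cfg.min_pixels_per_class} annotated pixels per class, "
            f"got positive={n_pos}, negative={n_neg}"
        )
    feats = extract_features(image, cfg.scales, cfg.channels)
    X = np.concatenate(
        [feats[annotations.positive_mask.grid], feats[annotations.negative_mask.grid]]
    )
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=cfg.holdout_fraction, stratify=y, random_state=cfg.seed
    )
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees, random_state=cfg.seed, n_jobs=1
    )
    forest.fit(X_tr, y_tr)
    acc = float(forest.score(X_te, y_te))
    report = {
        "n_positive": int(n_pos),
        "n_negative": int(n_neg),
        "holdout_accuracy": acc,
        "chance_level": acc < 0.6,
        "feature_names": feature_names(cfg.channels, cfg.scales),
        "feature_version": FEATURE_VERSION,
    }
    return PixelClassifierModel(
        forest=forest,
        scales=tuple(cfg.scales),
        channels=tuple(cfg.channels),
        prob_threshold=cfg.prob_threshold,
        seed=cfg.seed,
        training_report=report,
    )


def _partition(positive_grid: np.ndarray, fn_mask: PixelMask) -> tuple:
    untensed = PixelMask(positive_grid & fn_mask.grid, "untensed_mask", fn_mask.pixel_size_um)
    stretched = PixelMask(
        fn_mask.grid & ~untensed.grid, "stretched_mask", fn_mask.pixel_size_um
    )
    return untensed, stretched


def apply_classifier(
    model: PixelClassifierModel, image: MultiChannelImage, fn_mask: PixelMask
) -> tuple:
    """Classify fiber pixels into (untensed_mask, stretched_mask).

    The two masks always partition ``fn_mask``: untensed = forest-positive
    within the fiber universe, stretched = the rest of it.
    """
    if fn_mask.grid.shape != image.shape:
        raise ConfigError("fn_mask shape does not match image")
    positive = np.zeros(image.shape, dtype=bool)
    idx = np.nonzero(fn_mask.grid)
    if idx[0].size:
        feats = extract_features(image, model.scales, model.channels)
        proba = model.forest.predict_proba(feats[fn_mask.grid])
        pos_col = list(model.forest.classes_).index(1)
        positive[idx] = proba[:, pos_col] > model.prob_threshold
    return _partition(positive, fn_mask)


def threshold_baseline_masks(
    image: MultiChannelImage, fn_mask: PixelMask, n_bins: int = 256
) -> tuple:
    """Non-learned floor: Otsu on the probe channel within the fiber mask."""
    image.require("FNBPA5")
    if fn_mask.count == 0:
        return _partition(np.zeros(image.shape, dtype=bool), fn_mask)
    vals = image["FNBPA5"][fn_mask.grid]
    thr = otsu_threshold(vals, n_bins)
    return _partition(image["FNBPA5"] > thr, fn_mask)


def sample_annotations(
    label_grid: np.ndarray,
    pixel_size_um: float,
    n_per_class: int = 2000,
    seed: int = 0,
    positive_label: int = 2,
) -> AnnotationSet:
    """Draw an annotation set from a ground-truth tension label grid.

    Emulates a user annotating untensed fiber pixels (positive) versus
    everything else (stretched fiber and background, negative); used to
    train/score the classifier on simulated scenes.
    """
    rng = np.random.default_rng(seed)
    flat = np.asarray(label_grid).ravel()
    pos_idx = np.flatnonzero(flat == positive_label)
    neg_idx = np.flatnonzero(flat != positive_label)
    pos_pick = rng.choice(pos_idx, size=min(n_per_class, pos_idx.size), replace=False)
    neg_pick = rng.choice(neg_idx, size=min(n_per_class, neg_idx.size), replace=False)
    pos = np.zeros(flat.size, dtype=bool)
    neg = np.zeros(flat.size, dtype=bool)
    pos[pos_pick] = True
    neg[neg_pick] = True
    shape = np.asarray(label_grid).shape
    return AnnotationSet(
        PixelMask(pos.reshape(shape), "annot_positive", pixel_size_um),
        PixelMask(neg.reshape(shape), "annot_negative", pixel_size_um),
    )
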