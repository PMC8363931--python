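"""Pixel classification into masks and tumor/stroma compartment splitting.

Masking follows a scribble-trainable pixel-classification scheme: a random
forest over per-channel intensities plus Gaussian-smoothed intensities at two
scales predicts four mutually exclusive classes (autofluorescence, vessel,
background, tissue).  Masked tissue is then split into the mesothelioma
(tumor-cell) compartment and stroma by thresholding the smoothed combined
tumor-marker signal, followed by light morphological cleanup.  Vessels never
belong to tumor or stroma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from sklearn.ensemble import RandomForestClassifier

from .image import MultiplexImage

__all__ = [
    "CLASS_NAMES", "LABEL_CODES", "FEATURE_SIGMAS",
    "MaskSet", "CompartmentMap", "PixelClassifier",
    "compute_features", "sample_training_pixels",
    "train_pixel_classifier", "classify_pixels", "segment_components",
]

CLASS_NAMES = ("autofluorescence", "vessel", "background", "tissue")
FEATURE_SIGMAS = (1.0, 2.0)
#: label-map code table (written to 8-bit TIFF labels)
LABEL_CODES = {"excluded": 0, "tumor": 1, "stroma": 2, "vessel": 3}

CLASSIFIER_FORMAT_VERSION = 1


@dataclass
class MaskSet:
    """Mutually exclusive masks covering the frame, plus class posteriors."""

    autofluorescence: np.ndarray
    vessel: np.ndarray
    background: np.ndarray
    tissue: np.ndarray
    posterior: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (self.autofluorescence.astype(int) + self.vessel
                 + self.background + self.tissue)
        if not np.all(total == 1):
            raise ValueError("masks must partition the frame")
        if self.posterior:
            s = sum(self.posterior.values())
            if not np.allclose(s, 1.0, atol=1e-6):
                raise ValueError("posteriors must sum to 1 per pixel")

    def mask(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class CompartmentMap:
    """Per-pixel compartment labels {0 excluded, 1 tumor, 2 stroma, 3 vessel}.

    ``tumor_posterior`` is the classifier's tissue-class posterior, reused as
    the per-pixel confidence score when filtering tumor areas (the analogue
    of a detection model's class confidence).
    """

    labels: np.ndarray
    tumor_posterior: np.ndarray

    @property
    def tumor(self) -> np.ndarray:
        return self.labels == LABEL_CODES["tumor"]

    @property
    def stroma(self) -> np.ndarray:
        return self.labels == LABEL_CODES["stroma"]

    @property
    def vessel(self) -> np.ndarray:
        return self.labels == LABEL_CODES["vessel"]

    @property
    def excluded(self) -> np.ndarray:
        return self.labels == LABEL_CODES["excluded"]

    @property
    def tissue(self) -> np.ndarray:
        return self.tumor | self.stroma


@dataclass
class PixelClassifier:
    """Trained decision forest plus the feature recipe it expects."""

    forest: RandomForestClassifier
    channel_names: tuple[str, ...]
    sigmas: tuple[float, ...] = FEATURE_SIGMAS
    classes: tuple[str, ...] = CLASS_NAMES
    format_version: int = CLASSIFIER_FORMAT_VERSION

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "PixelClassifier":
        clf = joblib.load(Path(path))
        if clf.format_version != CLASSIFIER_FORMAT_VERSION:
            raise ValueError("unsupported classifier format version")
        return clf


def compute_features(image: MultiplexImage,
                     sigmas: tuple[float, ...] = FEATURE_SIGMAS,
                     channel_order: tuple[str, ...] | None = None
                     ) -> np.ndarray:
    """Per-pixel feature matrix: raw intensity plus Gaussian-smoothed
    intensity at each scale, for every channel.  Shape (H*W, C*(1+len(sigmas)))."""
    feats = []
    for name in channel_order or image.channel_names:
        ch = image.channels[name]
        feats.append(ch)
        for s in sigmas:
            feats.append(ndimage.gaussian_filter(ch, s))
    return np.stack([f.ravel() for f in feats], axis=1)


def sample_training_pixels(image: MultiplexImage,
                           class_masks: dict[str, np.ndarray],
                           n_per_class: int = 1500,
                           rng: np.random.Generator | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Draw labelled feature vectors from reference masks (e.g. phantom
    ground truth, or rasterized user scribbles)."""
    rng = rng or np.random.default_rng(0)
    features = compute_features(image)
    xs, ys = [], []
    for cname, mask in class_masks.items():
        idx = np.flatnonzero(mask.ravel())
        if len(idx) == 0:
            continue
        take = rng.choice(idx, size=min(n_per_class, len(idx)), replace=False)
        xs.append(features[take])
        ys.extend([cname] * len(take))
    return np.concatenate(xs), np.asarray(ys)


def train_pixel_classifier(features: np.ndarray, labels: np.ndarray,
                           channel_names: tuple[str, ...],
                           seed: int = 0, n_estimators: int = 30,
                           classes: tuple[str, ...] = CLASS_NAMES
                           ) -> PixelClassifier:
    """Fit the decision forest on labelled pixels.

    Every class in ``classes`` must appear at least once in ``labels``;
    training is deterministic given ``seed``.
    """
    present = set(np.unique(labels))
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"missing class in labels: {missing}")
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1,
        min_samples_leaf=2)
    forest.fit(features, labels)
    return PixelClassifier(forest=forest, channel_names=tuple(channel_names),
                           classes=tuple(classes))


def classify_pixels(image: MultiplexImage,
                    classifier: PixelClassifier) -> MaskSet:
    """Predict class posteriors per pixel and take the argmax masks.

    Invalid pixels (flagged during round fusion) are forced to background
    with a degenerate one-hot posterior, so they never enter tissue means.
    """
    if set(image.channel_names) != set(classifier.channel_names):
        raise ValueError(
            "channel mismatch: classifier trained on "
            f"{classifier.channel_names}, image has {image.channel_names}")
    features = compute_features(image, classifier.sigmas,
                                channel_order=classifier.channel_names)
    proba = classifier.forest.predict_proba(features)
    order = list(classifier.forest.classes_)
    h, w = image.shape
    posterior = {c: proba[:, order.index(c)].reshape(h, w)
                 for c in classifier.classes}

    invalid = ~image.valid()
    if invalid.any():
        for c in classifier.classes:
            posterior[c][invalid] = 1.0 if c == "background" else 0.0

    stackp = np.stack([posterior[c] for c in classifier.classes])
    arg = stackp.argmax(axis=0)
    masks = {c: arg == i for i, c in enumerate(classifier.classes)}
    return MaskSet(autofluorescence=masks["autofluorescence"],
                   vessel=masks["vessel"], background=masks["background"],
                   tissue=masks["tissue"], posterior=posterior)


def segment_components(image: MultiplexImage, masks: MaskSet,
                       tumor_channels: tuple[str, ...],
                       tumor_threshold: float | None = None,
                       smooth_sigma: float = 2.0,
                       morph_radius: int = 2) -> CompartmentMap:
    """Split masked tissue into tumor and stroma.

    The tumor-marker signal is the pixelwise maximum over the (Gaussian
    smoothed, sigma ``smooth_sigma`` px) tumor channels.  Tissue pixels with
    signal >= threshold (Otsu over tissue pixels when not given) form the
    tumor compartment after closing-then-opening with a disc structuring
    element; the rest of tissue is stroma.  The tumor + stroma partition of
    tissue is exact by construction.
    """
    missing = [c for c in tumor_channels if c not in image.channels]
    if missing:
        raise ValueError(f"tumor channels missing from image: {missing}")
    tissue = masks.tissue & image.valid()
    if not tissue.any():
        raise ValueError("no tissue")

    signal = np.max(
        [ndimage.gaussian_filter(image.channels[c], smooth_sigma)
         for c in tumor_channels], axis=0)
    if tumor_threshold is None:
        vals = signal[tissue]
        if np.ptp(vals) == 0:
            tumor_threshold = np.inf  # degenerate: nothing to split on
        else:
            tumor_threshold = float(threshold_otsu(vals))

    tumor = tissue & (signal >= tumor_threshold)
    # cleanup targets speckle along the tumor/stroma interface; when the
    # threshold puts all tissue on one side there is no interface to clean
    if morph_radius > 0 and tumor.any() and not np.array_equal(tumor, tissue):
        selem = disk(morph_radius)
        tumor = ndimage.binary_opening(
            ndimage.binary_closing(tumor, structure=selem),
            structure=selem)
        tumor &= tissue
    stroma = tissue & ~tumor

    labels = np.zeros(image.shape, dtype=np.uint8)
    labels[tumor] = LABEL_CODES["tumor"]
    labels[stroma] = LABEL_CODES["stroma"]
    labels[masks.vessel & image.valid()] = LABEL_CODES["vessel"]
    tumor_posterior = masks.posterior.get(
        "tissue", tissue.astype(np.float64))
    return CompartmentMap(labels=labels, tumor_posterior=tumor_posterior)
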