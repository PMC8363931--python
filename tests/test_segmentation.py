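"""Pixel classification and tumor/stroma compartment splitting."""

import numpy as np
import pytest

from mesozone.image import MultiplexImage
from mesozone.phantom import TUMOR_MARKERS
from mesozone.segmentation import (classify_pixels, sample_training_pixels,
                                   segment_components,
                                   train_pixel_classifier)

from conftest import make_phantom


def test_linearly_separable_toy_is_learned_perfectly():
    rng = np.random.default_rng(0)
    xa = rng.normal(0.0, 0.1, (200, 3))
    xb = rng.normal(2.0, 0.1, (200, 3))
    feats = np.vstack([xa, xb])
    labels = np.array(["a"] * 200 + ["b"] * 200)
    clf = train_pixel_classifier(feats, labels, channel_names=("c",),
                                 classes=("a", "b"), seed=0)
    assert (clf.forest.predict(feats) == labels).all()


def test_missing_class_rejected():
    feats = np.zeros((10, 3))
    labels = np.array(["tissue"] * 10)
    with pytest.raises(ValueError, match="missing class"):
        train_pixel_classifier(feats, labels, channel_names=("c",))


def test_phantom_accuracy_on_held_out_core(trained_classifier,
                                           held_out_phantom):
    """>= 95% per-class pixel accuracy against ground truth the classifier
    never saw."""
    image, truth = held_out_phantom
    masks = classify_pixels(image, trained_classifier)
    for cname in ("autofluorescence", "vessel", "background", "tissue"):
        agree = (masks.mask(cname) == truth.masks[cname]).mean()
        assert agree >= 0.95, cname


def test_posteriors_sum_to_one_and_match_argmax(trained_classifier,
                                                held_out_phantom):
    image, _ = held_out_phantom
    masks = classify_pixels(image, trained_classifier)
    total = sum(masks.posterior.values())
    assert np.allclose(total, 1.0, atol=1e-9)
    stack = np.stack([masks.posterior[c] for c in
                      ("autofluorescence", "vessel", "background", "tissue")])
    arg = stack.argmax(axis=0)
    assert np.array_equal(masks.tissue, arg == 3)


def test_training_is_deterministic(held_out_phantom):
    image, truth = held_out_phantom
    rng1 = np.random.default_rng(5)
    rng2 = np.random.default_rng(5)
    f1, l1 = sample_training_pixels(image, truth.masks, 400, rng1)
    f2, l2 = sample_training_pixels(image, truth.masks, 400, rng2)
    c1 = train_pixel_classifier(f1, l1, image.channel_names, seed=3)
    c2 = train_pixel_classifier(f2, l2, image.channel_names, seed=3)
    m1 = classify_pixels(image, c1)
    m2 = classify_pixels(image, c2)
    for name in m1.posterior:
        assert np.array_equal(m1.posterior[name], m2.posterior[name])


def test_all_zero_image_is_background(trained_classifier):
    image, _ = make_phantom(55, with_zone_truth=False)
    zero = MultiplexImage(
        channels={n: np.zeros(image.shape) for n in image.channel_names},
        pixel_size_um=image.pixel_size_um, round_ids=dict(image.round_ids))
    masks = classify_pixels(zero, trained_classifier)
    assert masks.background.mean() > 0.99


def test_channel_mismatch_rejected(trained_classifier):
    bad = MultiplexImage(channels={"ONLY": np.zeros((16, 16))},
                         pixel_size_um=2.0)
    with pytest.raises(ValueError, match="channel mismatch"):
        classify_pixels(bad, trained_classifier)


def test_classifier_save_load_round_trip(tmp_path, trained_classifier,
                                         held_out_phantom):
    from mesozone.segmentation import PixelClassifier
    path = tmp_path / "clf.joblib"
    trained_classifier.save(path)
    back = PixelClassifier.load(path)
    image, _ = held_out_phantom
    a = classify_pixels(image, trained_classifier)
    b = classify_pixels(image, back)
    assert np.array_equal(a.tissue, b.tissue)


# --- compartment splitting --------------------------------------------


def test_compartment_partition_is_exact(trained_classifier,
                                        held_out_phantom):
    image, _ = held_out_phantom
    masks = classify_pixels(image, trained_classifier)
    comp = segment_components(image, masks, TUMOR_MARKERS)
    assert comp.tumor.sum() + comp.stroma.sum() == masks.tissue.sum()
    assert not np.any(comp.tumor & comp.stroma)
    assert np.array_equal(comp.vessel, masks.vessel)


def test_constant_high_tumor_marker_means_no_stroma(trained_classifier,
                                                    held_out_phantom):
    image, _ = held_out_phantom
    masks = classify_pixels(image, trained_classifier)
    high = {n: (np.full(image.shape, 0.9) if n in TUMOR_MARKERS
                else image.channels[n]) for n in image.channel_names}
    img2 = MultiplexImage(channels=high, pixel_size_um=image.pixel_size_um,
                          round_ids=dict(image.round_ids))
    comp = segment_components(img2, masks, TUMOR_MARKERS,
                              tumor_threshold=0.5)
    assert not comp.stroma.any()
    assert np.array_equal(comp.tumor, masks.tissue)


def test_zero_tumor_marker_means_no_tumor(trained_classifier,
                                          held_out_phantom):
    image, _ = held_out_phantom
    masks = classify_pixels(image, trained_classifier)
    low = {n: (np.zeros(image.shape) if n in TUMOR_MARKERS
               else image.channels[n]) for n in image.channel_names}
    img2 = MultiplexImage(channels=low, pixel_size_um=image.pixel_size_um,
                          round_ids=dict(image.round_ids))
    comp = segment_components(img2, masks, TUMOR_MARKERS,
                              tumor_threshold=0.5)
    assert not comp.tumor.any()
    assert np.array_equal(comp.stroma, masks.tissue)


def test_tumor_area_recovers_disc(trained_classifier):
    """Segmented tumor area of a phantom tumor disc lands within 3% of the
    analytic disc area."""
    from mesozone.phantom import (Disc, PhantomSpec, default_channel_models,
                                  generate_core_phantom)
    spec = PhantomSpec(core_diameter_um=1000.0, pixel_size_um=1000.0 / 128,
                       tumor_shapes=(Disc(500, 500, 200),),
                       channel_models=default_channel_models(),
                       noise_sd=0.05, seed=21)
    image, truth = generate_core_phantom(spec, with_zone_truth=False)
    masks = classify_pixels(image, trained_classifier)
    comp = segment_components(image, masks, TUMOR_MARKERS)
    analytic = np.pi * (200.0 / (1000.0 / 128)) ** 2
    assert comp.tumor.sum() == pytest.approx(analytic, rel=0.03)


def test_tumor_area_monotone_in_threshold(trained_classifier,
                                          held_out_phantom):
    image, _ = held_out_phantom
    masks = classify_pixels(image, trained_classifier)
    areas = [segment_components(image, masks, TUMOR_MARKERS,
                                tumor_threshold=t).tumor.sum()
             for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
    assert all(a >= b for a, b in zip(areas, areas[1:]))


def test_dice_against_ground_truth_across_seeds(trained_classifier):
    """Tumor Dice >= 0.9 vs ground truth over 10 random phantoms."""
    for seed in range(200, 210):
        image, truth = make_phantom(seed, with_zone_truth=False)
        masks = classify_pixels(image, trained_classifier)
        comp = segment_components(image, masks, TUMOR_MARKERS)
        inter = (comp.tumor & truth.tumor).sum()
        dice = 2.0 * inter / (comp.tumor.sum() + truth.tumor.sum())
        assert dice >= 0.9, seed


def test_empty_tissue_rejected():
    from mesozone.segmentation import MaskSet
    image, _ = make_phantom(77, with_zone_truth=False)
    empty = MaskSet(autofluorescence=np.zeros(image.shape, bool),
                    vessel=np.zeros(image.shape, bool),
                    background=np.ones(image.shape, bool),
                    tissue=np.zeros(image.shape, bool))
    with pytest.raises(ValueError, match="no tissue"):
        segment_components(image, empty, TUMOR_MARKERS)
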