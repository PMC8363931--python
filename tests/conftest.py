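"""Shared fixtures: phantoms and a trained pixel classifier.

Everything is generated programmatically; session scope keeps the forest
training cost to one fit for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from mesozone.phantom import (PhantomSpec, default_channel_models,
                              generate_core_phantom, random_core_geometry)
from mesozone.segmentation import sample_training_pixels, \
    train_pixel_classifier

FRAME = 128
PIXEL_UM = 1000.0 / FRAME


def make_phantom(seed: int, noise_sd: float = 0.05, frame: int = FRAME,
                 with_zone_truth: bool = True, **model_kwargs):
    """One randomized core phantom at the default panel."""
    rng = np.random.default_rng(seed)
    spec = PhantomSpec(
        core_diameter_um=1000.0, pixel_size_um=1000.0 / frame,
        channel_models=default_channel_models(**model_kwargs),
        noise_sd=noise_sd, seed=seed)
    spec = random_core_geometry(spec, rng)
    return generate_core_phantom(spec, with_zone_truth=with_zone_truth)


@pytest.fixture(scope="session")
def trained_classifier():
    """Forest fitted on ground-truth-labelled pixels of two phantoms."""
    rng = np.random.default_rng(123)
    feats, labels = [], []
    names = None
    for seed in (11, 12):
        image, truth = make_phantom(seed, with_zone_truth=False)
        names = image.channel_names
        f, l = sample_training_pixels(image, truth.masks, n_per_class=1500,
                                      rng=rng)
        feats.append(f)
        labels.append(l)
    return train_pixel_classifier(np.concatenate(feats),
                                  np.concatenate(labels),
                                  channel_names=names, seed=7)


@pytest.fixture(scope="session")
def held_out_phantom():
    """A phantom the classifier never saw, with full ground truth."""
    return make_phantom(99)
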