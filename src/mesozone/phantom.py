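"""Synthetic TMA-core phantoms with exact geometric and intensity ground truth.

A phantom is a square raster covering one circular 1.0 mm core.  Discs placed
inside the core define tumor nests, vessels and autofluorescent debris; the
remaining in-core area is stroma, everything outside the core disc is empty
background.  Each channel is rendered as a compartment-dependent constant
field (optionally plus a linear radial gradient away from the tumor boundary
within stroma) with additive Gaussian noise clamped to [0, 1].

Raster convention: pixel centres sit at (i + 0.5, j + 0.5) * pixel_size_um in
0-based row-major order; a pixel belongs to a shape iff its centre is inside.
This makes every area oracle an exact point-in-disc count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.stats import norm

from .image import MultiplexImage
from .zones import ZoneConfig, zone_labels_bruteforce

__all__ = [
    "Disc", "ChannelModel", "PhantomSpec", "GroundTruth",
    "generate_core_phantom", "default_channel_models", "random_core_geometry",
    "COMPARTMENTS",
]

#: compartment names used throughout rendering and ground truth
COMPARTMENTS = ("tumor", "stroma", "vessel", "debris", "background")


@dataclass(frozen=True)
class Disc:
    """A disc in physical coordinates (um); (cy, cx) from the frame origin."""

    cy_um: float
    cx_um: float
    radius_um: float

    def __post_init__(self) -> None:
        if self.radius_um < 0:
            raise ValueError("radius_um must be >= 0")


@dataclass(frozen=True)
class ChannelModel:
    """Intensity model of one channel.

    value(pixel) = baseline + offsets[compartment]
                 (+ gradient_slope_per_um * distance-from-tumor, stroma only)
    Offsets default to 0 for compartments not listed.
    """

    baseline: float = 0.0
    offsets: Mapping[str, float] = field(default_factory=dict)
    gradient_slope_per_um: float = 0.0
    round_id: int = 1

    def __post_init__(self) -> None:
        for key in self.offsets:
            if key not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {key!r}")


@dataclass
class PhantomSpec:
    """Geometry + intensity recipe for one synthetic core."""

    core_diameter_um: float = 1000.0
    pixel_size_um: float = 2.0
    tumor_shapes: tuple[Disc, ...] = ()
    vessel_shapes: tuple[Disc, ...] = ()
    debris_shapes: tuple[Disc, ...] = ()
    channel_models: Mapping[str, ChannelModel] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0
    zone_config: ZoneConfig = field(default_factory=ZoneConfig)

    def __post_init__(self) -> None:
        if not self.core_diameter_um > 0:
            raise ValueError("core_diameter_um must be > 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.channel_models:
            raise ValueError("at least one channel model is required")

    @property
    def frame_px(self) -> int:
        return int(round(self.core_diameter_um / self.pixel_size_um))


@dataclass
class GroundTruth:
    """Exact per-pixel truth for one phantom.

    ``masks`` (autofluorescence / vessel / background / tissue) are pairwise
    disjoint and cover the frame; tumor and stroma partition tissue.
    ``zone_maps`` hold oracle meso/vessel ring labels from a brute-force
    nearest-source search.  ``expected_mean`` is the analytic expectation of
    each rendered channel over each non-empty compartment (equal to the
    clean compartment value when noise is off; clamped-noise corrected
    otherwise).
    """

    masks: dict[str, np.ndarray]
    tumor: np.ndarray
    stroma: np.ndarray
    expected_mean: dict[str, dict[str, float]]
    zone_maps: dict[str, np.ndarray]
    tumor_distance_um: np.ndarray

    @property
    def compartment_masks(self) -> dict[str, np.ndarray]:
        return {
            "tumor": self.tumor,
            "stroma": self.stroma,
            "vessel": self.masks["vessel"],
            "debris": self.masks["autofluorescence"],
            "background": self.masks["background"],
        }


def _clamped_noise_mean(clean: np.ndarray, sd: float) -> np.ndarray:
    """E[clip(v + eps, 0, 1)] with eps ~ N(0, sd): the closed-form mean of
    the clamped-Gaussian noise model, so expectations stay exact even where
    a compartment sits near an intensity bound."""
    if sd == 0.0:
        return clean
    a = (0.0 - clean) / sd
    b = (1.0 - clean) / sd
    return (clean * (norm.cdf(b) - norm.cdf(a))
            - sd * (norm.pdf(b) - norm.pdf(a))
            + (1.0 - norm.cdf(b)))


def _pixel_centers(n: int, px: float) -> tuple[np.ndarray, np.ndarray]:
    c = (np.arange(n) + 0.5) * px
    return np.meshgrid(c, c, indexing="ij")


def _disc_mask(yy: np.ndarray, xx: np.ndarray, disc: Disc) -> np.ndarray:
    return ((yy - disc.cy_um) ** 2 + (xx - disc.cx_um) ** 2
            <= disc.radius_um ** 2)


def _union(yy, xx, discs) -> np.ndarray:
    out = np.zeros(yy.shape, dtype=bool)
    for d in discs:
        out |= _disc_mask(yy, xx, d)
    return out


def generate_core_phantom(spec: PhantomSpec, with_zone_truth: bool = True
                          ) -> tuple[MultiplexImage, GroundTruth]:
    """Render one phantom core and its exact ground truth.

    Identical specs (including seed) produce bit-identical images.  Shapes
    extending past the core disc are clipped to it.  ``with_zone_truth``
    skips the (comparatively slow) brute-force zone oracle when large batches
    of phantoms only need masks and intensities.
    """
    n = spec.frame_px
    if n < 8:
        raise ValueError("degenerate raster: core diameter < 8 px")
    px = spec.pixel_size_um
    yy, xx = _pixel_centers(n, px)
    r = spec.core_diameter_um / 2.0
    core = ((yy - r) ** 2 + (xx - r) ** 2) <= r ** 2

    debris = _union(yy, xx, spec.debris_shapes) & core
    vessel = _union(yy, xx, spec.vessel_shapes) & core & ~debris
    tumor = _union(yy, xx, spec.tumor_shapes) & core & ~debris & ~vessel
    tissue = core & ~debris & ~vessel
    stroma = tissue & ~tumor
    background = ~core

    masks = {
        "autofluorescence": debris,
        "vessel": vessel,
        "background": background,
        "tissue": tissue,
    }

    comp_masks = {
        "tumor": tumor, "stroma": stroma, "vessel": vessel,
        "debris": debris, "background": background,
    }

    # distance from the tumor compartment, for radial-gradient channels
    if tumor.any():
        dist_px = ndimage.distance_transform_edt(~tumor)
        tumor_distance_um = dist_px * px
    else:
        tumor_distance_um = np.zeros((n, n))

    rng = np.random.default_rng(spec.seed)
    channels: dict[str, np.ndarray] = {}
    round_ids: dict[str, int] = {}
    expected: dict[str, dict[str, float]] = {}
    for name, model in spec.channel_models.items():
        clean = np.full((n, n), model.baseline, dtype=np.float64)
        for comp, mask in comp_masks.items():
            off = model.offsets.get(comp, 0.0)
            if off:
                clean[mask] += off
        if model.gradient_slope_per_um and tumor.any():
            clean[stroma] += (model.gradient_slope_per_um
                              * tumor_distance_um[stroma])
        clean = np.clip(clean, 0.0, 1.0)
        # analytic mean of the rendered (noise-clamped) channel per pixel
        emap = _clamped_noise_mean(clean, spec.noise_sd)
        exp: dict[str, float] = {}
        for comp, mask in comp_masks.items():
            if mask.any():
                exp[comp] = float(emap[mask].mean())
        if tissue.any():
            exp["tissue"] = float(emap[tissue].mean())
        expected[name] = exp
        img = clean
        if spec.noise_sd > 0:
            img = np.clip(clean + rng.normal(0.0, spec.noise_sd, clean.shape),
                          0.0, 1.0)
        channels[name] = img
        round_ids[name] = model.round_id

    zone_maps = {}
    if with_zone_truth:
        zone_maps = {
            "meso": zone_labels_bruteforce(tumor, stroma,
                                           spec.zone_config, px),
            "vessel": zone_labels_bruteforce(vessel, stroma,
                                             spec.zone_config, px),
        }

    image = MultiplexImage(channels=channels, pixel_size_um=px,
                           round_ids=round_ids)
    truth = GroundTruth(masks=masks, tumor=tumor, stroma=stroma,
                        expected_mean=expected, zone_maps=zone_maps,
                        tumor_distance_um=tumor_distance_um)
    return image, truth


# ---------------------------------------------------------------------------
# default study-like channel panel and randomized core geometry

FIBROBLAST_MARKERS = ("PDGFRA", "PDGFRB", "aSMA", "FAP",
                      "SPARC", "POSTN", "COL1")
TUMOR_MARKERS = ("CK5", "CK5CALRET")
NUCLEAR_CHANNEL = "DAPI"

#: round membership mirroring a two-panel staining design
_ROUND_OF = {
    "DAPI": 1, "CK5": 1, "PDGFRA": 1, "PDGFRB": 1, "aSMA": 1, "FAP": 1,
    "DAPI2": 2, "CK5CALRET": 2, "SPARC": 2, "POSTN": 2, "COL1": 2,
}


def default_channel_models(
    marker_offsets: Mapping[str, Mapping[str, float]] | None = None,
    gradient_slopes: Mapping[str, float] | None = None,
) -> dict[str, ChannelModel]:
    """Two-round panel: nuclear counterstain per round, tumor markers, and
    the seven fibroblast markers with moderate stromal expression.

    ``marker_offsets`` overrides per-marker compartment offsets (e.g. to give
    one patient a specific tumor-cell PDGFRB level); ``gradient_slopes`` adds
    a linear stromal gradient (intensity per um from the tumor boundary).
    """
    marker_offsets = dict(marker_offsets or {})
    gradient_slopes = dict(gradient_slopes or {})
    models: dict[str, ChannelModel] = {}
    for name in ("DAPI", "DAPI2"):
        models[name] = ChannelModel(
            baseline=0.02,
            offsets={"tumor": 0.55, "stroma": 0.35, "vessel": 0.30,
                     "debris": 0.25},
            round_id=_ROUND_OF[name])
    for name in TUMOR_MARKERS:
        models[name] = ChannelModel(
            baseline=0.02,
            offsets={"tumor": 0.60, "stroma": 0.05, "vessel": 0.04,
                     "debris": 0.30},
            round_id=_ROUND_OF[name])
    for name in FIBROBLAST_MARKERS:
        offsets = {"tumor": 0.08, "stroma": 0.20, "vessel": 0.25,
                   "debris": 0.30}
        offsets.update(marker_offsets.get(name, {}))
        models[name] = ChannelModel(
            baseline=0.02, offsets=offsets,
            gradient_slope_per_um=gradient_slopes.get(name, 0.0),
            round_id=_ROUND_OF[name])
    return models


def random_core_geometry(spec: PhantomSpec, rng: np.random.Generator,
                         n_tumor: tuple[int, int] = (2, 4),
                         n_vessel: tuple[int, int] = (2, 4),
                         n_debris: tuple[int, int] = (1, 2)) -> PhantomSpec:
    """Place random tumor nests, vessels and debris inside the core disc.

    Radii scale with the core so small test rasters still contain every
    compartment.
    """
    d = spec.core_diameter_um
    c = d / 2.0

    def discs(k_range, r_range):
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        out = []
        for _ in range(k):
            rad = rng.uniform(*r_range) * d
            rho = rng.uniform(0.0, 0.38) * d
            ang = rng.uniform(0, 2 * np.pi)
            out.append(Disc(c + rho * np.sin(ang), c + rho * np.cos(ang), rad))
        return tuple(out)

    return replace(
        spec,
        tumor_shapes=discs(n_tumor, (0.10, 0.18)),
        vessel_shapes=discs(n_vessel, (0.02, 0.04)),
        debris_shapes=discs(n_debris, (0.02, 0.05)),
    )
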