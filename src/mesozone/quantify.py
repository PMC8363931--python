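"""Per-core and per-patient marker quantification.

The analysis variable for survival modelling is the "average mean intensity":
the arithmetic mean of a marker channel over a compartment's pixels within
one core, averaged across the patient's QC-passed cores.  Variables are named
``<MARKER>_<compartment>`` with compartments meso, stroma, meso_Z1..Z4 and
vessel_Z1..Z4 (10 per marker).  Intensities stay on the raw [0, 1] scale
until :func:`scale_for_cox` multiplies them by 1,000 for hazard-ratio
readability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .cohort import COX_SCALE
from .image import MultiplexImage
from .segmentation import CompartmentMap
from .zones import ZoneMap

__all__ = [
    "COMPARTMENT_VARIABLES", "PositivityResult",
    "mean_intensity", "measure_core", "build_patient_table",
    "scale_for_cox", "classify_tumor_positivity", "pool_positivity",
]

log = logging.getLogger(__name__)

COMPARTMENT_VARIABLES = (
    "meso", "stroma",
    "meso_Z1", "meso_Z2", "meso_Z3", "meso_Z4",
    "vessel_Z1", "vessel_Z2", "vessel_Z3", "vessel_Z4",
)


def mean_intensity(channel: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of ``channel`` over ``mask``; NaN for an empty mask
    (missing, never 0)."""
    if mask.shape != channel.shape:
        raise ValueError("mask shape does not match channel")
    n = int(mask.sum())
    if n == 0:
        return float("nan")
    return float(channel[mask].mean())


def measure_core(image: MultiplexImage, compartments: CompartmentMap,
                 meso_zones: ZoneMap, vessel_zones: ZoneMap,
                 markers: tuple[str, ...]) -> pd.DataFrame:
    """Long-format measurements of one core: one row per marker x compartment.

    Invalid pixels are excluded from every mean.  ``meso`` is the mean over
    the tumor-cell compartment, ``stroma`` over all stroma regardless of zone.
    """
    valid = image.valid()
    masks: dict[str, np.ndarray] = {
        "meso": compartments.tumor & valid,
        "stroma": compartments.stroma & valid,
    }
    for k in range(1, meso_zones.config.n_zones + 1):
        masks[f"meso_Z{k}"] = meso_zones.zone_mask(k) & valid
    for k in range(1, vessel_zones.config.n_zones + 1):
        masks[f"vessel_Z{k}"] = vessel_zones.zone_mask(k) & valid

    rows = []
    for marker in markers:
        ch = image.channels[marker]
        for comp, mask in masks.items():
            rows.append({
                "patient_id": image.patient_id,
                "core_id": image.core_id,
                "variable": f"{marker}_{comp}",
                "value": mean_intensity(ch, mask),
                "pixel_count": int(mask.sum()),
            })
    return pd.DataFrame(rows)


def build_patient_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Average core-level values per patient and variable.

    ``measurements`` is the long format produced by :func:`measure_core`
    (possibly concatenated over cores).  Returns a wide table indexed by
    patient_id with one column per variable and a ``.attrs['intensity_scale']``
    of 1.0 (raw scale); per-cell core counts live in ``.attrs['n_cores']``.
    Missing core values propagate as missing; patients whose every core
    failed QC are simply absent.
    """
    if measurements.duplicated(["patient_id", "core_id", "variable"]).any():
        raise ValueError("duplicate (patient, core, variable) measurements")
    table = measurements.pivot_table(index="patient_id", columns="variable",
                                     values="value", aggfunc="mean")
    n_cores = measurements.dropna(subset=["value"]).pivot_table(
        index="patient_id", columns="variable", values="value",
        aggfunc="count").reindex(index=table.index, columns=table.columns)
    table.attrs["intensity_scale"] = 1.0
    table.attrs["n_cores"] = n_cores
    dropped = (set(measurements["patient_id"])
               - set(table.dropna(how="all").index))
    if dropped:
        log.info("patients with no usable core values: %s", sorted(dropped))
    return table


def scale_for_cox(table: pd.DataFrame) -> pd.DataFrame:
    """Multiply every intensity by 1,000 (once) for Cox modelling."""
    if table.attrs.get("intensity_scale", 1.0) != 1.0:
        raise ValueError("table already scaled")
    out = table * COX_SCALE
    out.attrs = dict(table.attrs)
    out.attrs["intensity_scale"] = COX_SCALE
    return out


@dataclass
class PositivityResult:
    """Marker-positive fraction of the tumor-cell area for one core or
    patient.  ``ratio_percent`` is NaN when no tumor area is eligible."""

    patient_id: str
    positive_area_px: int
    total_tumor_area_px: int
    ratio_percent: float
    confidence_threshold: float
    positivity_threshold: float

    def __post_init__(self) -> None:
        if self.positive_area_px > self.total_tumor_area_px:
            raise ValueError("positive area exceeds tumor area")


def classify_tumor_positivity(image: MultiplexImage,
                              compartments: CompartmentMap,
                              marker_channel: str,
                              positivity_threshold: float | None = None,
                              confidence_threshold: float = 0.85
                              ) -> PositivityResult:
    """Fraction of confident tumor area positive for ``marker_channel``.

    Tumor pixels whose classifier confidence is >= ``confidence_threshold``
    (default 0.85) are eligible; eligible pixels at or above the intensity
    threshold (Otsu over tumor pixels when not given) count as positive.
    """
    ch = image.channels[marker_channel]
    eligible = (compartments.tumor & image.valid()
                & (compartments.tumor_posterior >= confidence_threshold))
    if positivity_threshold is None:
        tumor_vals = ch[compartments.tumor & image.valid()]
        if tumor_vals.size == 0 or np.ptp(tumor_vals) == 0:
            positivity_threshold = np.inf
        else:
            positivity_threshold = float(threshold_otsu(tumor_vals))
    positive = eligible & (ch >= positivity_threshold)
    n_elig = int(eligible.sum())
    n_pos = int(positive.sum())
    ratio = 100.0 * n_pos / n_elig if n_elig else float("nan")
    return PositivityResult(
        patient_id=image.patient_id, positive_area_px=n_pos,
        total_tumor_area_px=n_elig, ratio_percent=ratio,
        confidence_threshold=confidence_threshold,
        positivity_threshold=float(positivity_threshold))


def pool_positivity(results: list[PositivityResult],
                    patient_id: str) -> PositivityResult:
    """Pool per-core positivity into one patient estimate by aggregating
    areas before forming the ratio (area-weighted pooled fraction)."""
    pos = sum(r.positive_area_px for r in results)
    tot = sum(r.total_tumor_area_px for r in results)
    ratio = 100.0 * pos / tot if tot else float("nan")
    return PositivityResult(
        patient_id=patient_id, positive_area_px=pos, total_tumor_area_px=tot,
        ratio_percent=ratio,
        confidence_threshold=results[0].confidence_threshold if results
        else float("nan"),
        positivity_threshold=results[0].positivity_threshold if results
        else float("nan"))
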