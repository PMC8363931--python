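"""Fixture bundles: phantom cores + ground truth + clinical table on disk.

Layout of a bundle directory::

    cores/<core_id>.tif            multi-page TIFF, one page per channel
    cores/<core_id>.channels.csv   channel manifest
    truth/<core_id>.npz            ground-truth masks / zone maps (optional)
    clinical.csv                   one row per patient (optional)

Round trips are exact: arrays are stored in their native dtype.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .image import MultiplexImage, read_core_tiff, write_core_tiff
from .phantom import GroundTruth

__all__ = ["write_fixture_bundle", "read_fixture_bundle", "read_truth"]

CLINICAL_COLUMNS = ["patient_id", "age", "sex", "side", "histology",
                    "stage", "months", "event"]


def write_fixture_bundle(path: str | Path,
                         images: Sequence[MultiplexImage],
                         truths: Sequence[GroundTruth] | None = None,
                         cohort: pd.DataFrame | None = None) -> Path:
    """Write cores (and optionally ground truth and a clinical CSV)."""
    path = Path(path)
    (path / "cores").mkdir(parents=True, exist_ok=True)
    if truths is not None:
        if len(truths) != len(images):
            raise ValueError("one ground truth per image required")
        (path / "truth").mkdir(exist_ok=True)
    for i, image in enumerate(images):
        cid = image.core_id or f"core{i:04d}"
        write_core_tiff(image, path / "cores" / f"{cid}.tif")
        if truths is not None:
            t = truths[i]
            np.savez_compressed(
                path / "truth" / f"{cid}.npz",
                tumor=t.tumor, stroma=t.stroma,
                zone_meso=t.zone_maps["meso"],
                zone_vessel=t.zone_maps["vessel"],
                tumor_distance_um=t.tumor_distance_um,
                **{f"mask_{k}": v for k, v in t.masks.items()},
            )
    if cohort is not None:
        cols = [c for c in CLINICAL_COLUMNS if c in cohort.columns]
        extra = [c for c in cohort.columns if c not in cols]
        cohort[cols + extra].to_csv(path / "clinical.csv", index=False)
    return path


def read_fixture_bundle(path: str | Path) -> tuple[list[MultiplexImage],
                                                   pd.DataFrame | None]:
    """Read every core of a bundle (sorted by core id) and the clinical CSV."""
    path = Path(path)
    images = [read_core_tiff(p)
              for p in sorted((path / "cores").glob("*.tif"))]
    clinical = None
    if (path / "clinical.csv").exists():
        clinical = pd.read_csv(path / "clinical.csv")
    return images, clinical


def read_truth(path: str | Path, core_id: str) -> dict[str, np.ndarray]:
    """Ground-truth arrays of one core as a plain dict."""
    with np.load(Path(path) / "truth" / f"{core_id}.npz") as z:
        return {k: z[k] for k in z.files}
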