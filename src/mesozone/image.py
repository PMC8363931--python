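"""Multi-channel TMA core image container and TIFF round-trip I/O.

A "core" is one ~1 mm tissue-microarray spot imaged in several fluorescence
channels, possibly acquired over two staining rounds.  Channels are kept as
named 2-D float arrays on a common pixel grid; intensities are unitless and
nominally in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["MultiplexImage", "write_core_tiff", "read_core_tiff"]


@dataclass
class MultiplexImage:
    """Named channel stack for one TMA core.

    Parameters
    ----------
    channels
        Mapping of marker name to 2-D intensity array.  All arrays must share
        one shape; intensities must be finite and non-negative.
    pixel_size_um
        Physical edge length of a pixel in micrometres (> 0).
    core_id, patient_id
        Identifiers carried through the pipeline.
    round_ids
        Staining round of each channel (1-based); channels absent from the
        mapping default to round 1.
    valid_mask
        Boolean map of pixels that carry trustworthy signal after fusing
        staining rounds.  ``None`` means every pixel is valid.  Pixels shifted
        out of frame during registration are flagged invalid and are excluded
        from every downstream mask and mean.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    core_id: str = ""
    patient_id: str = ""
    round_ids: dict[str, int] = field(default_factory=dict)
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("MultiplexImage needs at least one channel")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} has non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
        if self.valid_mask is not None and self.valid_mask.shape != self.shape:
            raise ValueError("valid_mask shape does not match channels")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def round_of(self, name: str) -> int:
        return self.round_ids.get(name, 1)

    def valid(self) -> np.ndarray:
        """Boolean validity map (all-True when no mask is set)."""
        if self.valid_mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.valid_mask

    def stack(self) -> np.ndarray:
        """Channels as a (n_channels, H, W) array in channel-name order."""
        return np.stack([self.channels[n] for n in self.channel_names])


def write_core_tiff(image: MultiplexImage, tiff_path: str | Path,
                    manifest_path: str | Path | None = None) -> Path:
    """Write one core as a multi-page TIFF (one page per channel).

    The channel manifest (channel_index, marker_name, round_id) is written as
    CSV next to the TIFF unless an explicit path is given.
    """
    tiff_path = Path(tiff_path)
    if manifest_path is None:
        manifest_path = tiff_path.with_suffix(".channels.csv")
    pages = image.stack()  # native dtype so the round trip is bit-exact
    tifffile.imwrite(tiff_path, pages, metadata={
        "core_id": image.core_id,
        "patient_id": image.patient_id,
        "pixel_size_um": image.pixel_size_um,
    })
    manifest = pd.DataFrame({
        "channel_index": np.arange(len(image.channel_names)),
        "marker_name": list(image.channel_names),
        "round_id": [image.round_of(n) for n in image.channel_names],
    })
    manifest.to_csv(manifest_path, index=False)
    return tiff_path


def read_core_tiff(tiff_path: str | Path,
                   manifest_path: str | Path | None = None) -> MultiplexImage:
    """Read a core written by :func:`write_core_tiff` (exact round trip)."""
    tiff_path = Path(tiff_path)
    if manifest_path is None:
        manifest_path = tiff_path.with_suffix(".channels.csv")
    with tifffile.TiffFile(tiff_path) as tf:
        pages = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if pages.ndim == 2:
        pages = pages[None]
    manifest = pd.read_csv(manifest_path)
    names = list(manifest["marker_name"])
    rounds = {n: int(r) for n, r in zip(names, manifest["round_id"])}
    channels = {n: pages[i].astype(np.float64) for i, n in enumerate(names)}
    return MultiplexImage(
        channels=channels,
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        core_id=str(meta.get("core_id", "")),
        patient_id=str(meta.get("patient_id", "")),
        round_ids=rounds,
    )
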