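"""Overlay of the two staining rounds of one core, plus spot-level QC.

Serial staining rounds of the same section differ mainly by a stage offset,
so registration is modelled as a rigid integer-pixel translation estimated by
maximizing the normalized cross-correlation of a shared reference channel
(the nuclear counterstain) over a bounded shift window.  Pixels that leave
the frame when the moving round is aligned are flagged invalid and excluded
from every downstream mask and mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import MultiplexImage

__all__ = ["RegistrationError", "QCReport", "register_rounds", "qc_core"]


class RegistrationError(RuntimeError):
    """Raised when the shift estimate is degenerate or hits the search
    boundary."""


@dataclass
class QCReport:
    """Spot-level quality-control verdict for one core."""

    core_id: str
    tissue_fraction: float
    registration_shift_um: tuple[float, float]
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.passed and not self.reasons:
            raise ValueError("a failed QC report must carry reasons")


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def _estimate_shift(ref1: np.ndarray, ref2: np.ndarray,
                    max_shift_px: int) -> tuple[int, int]:
    """Best (dy, dx) such that ref2 ~= translate(ref1, by=(dy, dx))."""
    if ref1.std() == 0 or ref2.std() == 0:
        raise RegistrationError(
            "registration failed: constant reference channel")
    best, best_shift = -np.inf, (0, 0)
    h, w = ref1.shape
    for dy in range(-max_shift_px, max_shift_px + 1):
        for dx in range(-max_shift_px, max_shift_px + 1):
            # overlap of ref1 with ref2 shifted back by (dy, dx)
            y1a, y1b = max(0, dy), min(h, h + dy)
            x1a, x1b = max(0, dx), min(w, w + dx)
            a = ref1[y1a - dy:y1b - dy, x1a - dx:x1b - dx]
            b = ref2[y1a:y1b, x1a:x1b]
            if a.size == 0:
                continue
            score = _ncc(a, b)
            if np.isnan(score):
                continue
            if score > best:
                best, best_shift = score, (dy, dx)
    if not np.isfinite(best):
        raise RegistrationError("registration failed: correlation undefined")
    if max_shift_px > 0 and (abs(best_shift[0]) == max_shift_px
                             or abs(best_shift[1]) == max_shift_px):
        raise RegistrationError(
            "registration failed: shift hit the search boundary")
    return best_shift


def _translate(arr: np.ndarray, dy: int, dx: int,
               fill: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Shift ``arr`` by (dy, dx); returns the shifted array and a validity
    map that is False where data moved out of frame."""
    out = np.full_like(arr, fill)
    valid = np.zeros(arr.shape, dtype=bool)
    h, w = arr.shape
    ya, yb = max(0, dy), min(h, h + dy)
    xa, xb = max(0, dx), min(w, w + dx)
    out[ya:yb, xa:xb] = arr[ya - dy:yb - dy, xa - dx:xb - dx]
    valid[ya:yb, xa:xb] = True
    return out, valid


def register_rounds(round1: MultiplexImage, round2: MultiplexImage,
                    reference_channel: str = "DAPI",
                    max_shift_um: float = 50.0
                    ) -> tuple[tuple[int, int], MultiplexImage]:
    """Overlay round 2 onto round 1 and fuse the channel stacks.

    Returns the estimated (dy, dx) pixel displacement of round 2 relative to
    round 1 (i.e. round2 looks like round1 translated by that shift) and the
    fused image.  Round-1 pixel values are never altered; round-2 channels
    are shifted by the negated estimate.  The reference channel of round 2 is
    stored under ``<name>2`` if the name collides.
    """
    if round1.pixel_size_um != round2.pixel_size_um:
        raise ValueError("rounds have mismatched pixel sizes")
    ref1 = _reference(round1, reference_channel)
    ref2 = _reference(round2, reference_channel)
    max_shift_px = int(max_shift_um / round1.pixel_size_um)
    dy, dx = _estimate_shift(ref1, ref2, max_shift_px)

    channels = dict(round1.channels)
    round_ids = dict(round1.round_ids)
    valid = round1.valid().copy()
    for name, arr in round2.channels.items():
        moved, ok = _translate(arr, -dy, -dx)
        out_name = name if name not in channels else f"{name}2"
        channels[out_name] = moved
        round_ids[out_name] = round2.round_of(name)
        valid &= ok
    fused = MultiplexImage(channels=channels,
                           pixel_size_um=round1.pixel_size_um,
                           core_id=round1.core_id,
                           patient_id=round1.patient_id,
                           round_ids=round_ids, valid_mask=valid)
    return (dy, dx), fused


def _reference(image: MultiplexImage, name: str) -> np.ndarray:
    for cand in (name, f"{name}2"):
        if cand in image.channels:
            return image.channels[cand]
    raise ValueError(f"reference channel {name!r} missing from image")


def qc_core(image: MultiplexImage, tissue_mask: np.ndarray,
            min_tissue_fraction: float = 0.1,
            core_diameter_um: float | None = None,
            registration_ok: bool = True,
            shift_px: tuple[int, int] = (0, 0)) -> QCReport:
    """Spot-level QC: tissue coverage of the nominal core disc.

    ``tissue_fraction`` is tissue pixels over the pixel count of the core
    disc (diameter defaulting to the frame's short side).  The threshold is
    inclusive: a fraction exactly equal to ``min_tissue_fraction`` passes.
    """
    if tissue_mask.shape != image.shape:
        raise ValueError("tissue_mask shape does not match image")
    px = image.pixel_size_um
    if core_diameter_um is None:
        core_diameter_um = min(image.shape) * px
    r_px = core_diameter_um / (2.0 * px)
    # analytic disc pixel count from the raster convention
    n = min(image.shape)
    ii, jj = np.indices((n, n)) + 0.5
    disc_px = int((((ii - n / 2) ** 2 + (jj - n / 2) ** 2) <= r_px ** 2).sum())
    tissue_px = int((tissue_mask & image.valid()).sum())
    fraction = tissue_px / disc_px if disc_px else 0.0

    reasons: list[str] = []
    if fraction < min_tissue_fraction:
        reasons.append("insufficient tissue")
    if not registration_ok:
        reasons.append("registration failed")
    return QCReport(
        core_id=image.core_id,
        tissue_fraction=fraction,
        registration_shift_um=(shift_px[0] * px, shift_px[1] * px),
        passed=not reasons,
        reasons=reasons,
    )
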