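"""Neck-landmark pre-alignment of follow-up images to a reference.

Each image row is scanned for consecutive-pixel temperature differences;
large signed peaks mark the background-to-body transitions.  Pixels lying
between the outermost transitions that are warmer than a temperature
threshold (default 25 °C) form the foreground.  The neck is the row with
the fewest foreground pixels, and its outer-left coordinate anchors an
integer-pixel shift of each follow-up onto the reference.

The shift is integer-only by design: no interpolation touches the raw
temperatures before the non-rigid registration stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LandmarkNotFoundError
from .thermal_io import ThermalImage, pixel_size_cm

__all__ = [
    "ForegroundMask",
    "NeckLandmark",
    "TranslationOffset",
    "row_gradient",
    "segment_foreground",
    "detect_neck",
    "prealign",
    "DEFAULT_TEMP_THRESHOLD",
    "DEFAULT_GRAD_THRESHOLD",
]

DEFAULT_TEMP_THRESHOLD = 25.0  # degC, between room (~22) and skin (>= ~29.9)
DEFAULT_GRAD_THRESHOLD = 5.0  # degC per pixel, ~half the body-background step


@dataclass
class ForegroundMask:
    """Binary body/background mask (1 = body)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("foreground mask must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_counts(self) -> np.ndarray:
        return self.values.sum(axis=1)


@dataclass(frozen=True)
class NeckLandmark:
    """Detected neck anchor: row, outer-left x, and row foreground count."""

    row: int
    left_x: int
    foreground_count: int


@dataclass(frozen=True)
class TranslationOffset:
    """Integer pixel shift plus its physical equivalent in cm."""

    dx_px: int
    dy_px: int
    dx_cm: float
    dy_cm: float


def row_gradient(img: ThermalImage, row: int) -> np.ndarray:
    """Consecutive-pixel temperature differences along one row.

    Element ``i`` is ``T[row, i+1] - T[row, i]``; length is width - 1.
    """
    h = img.shape[0]
    if not 0 <= row < h:
        raise IndexError(f"row {row} out of range [0, {h})")
    return np.diff(img.values[row])


def segment_foreground(
    img: ThermalImage,
    temp_threshold: float = DEFAULT_TEMP_THRESHOLD,
    grad_threshold: float = DEFAULT_GRAD_THRESHOLD,
) -> ForegroundMask:
    """Row-wise gradient segmentation of body versus background.

    Per row: the leftmost gradient element >= +grad_threshold and the
    rightmost <= -grad_threshold bound the body interval; pixels strictly
    between the two transitions are foreground if warmer than
    ``temp_threshold``.  Rows missing either transition stay background.
    An empty mask is a legal output.
    """
    if temp_threshold <= 0 or grad_threshold <= 0:
        raise ValueError("thresholds must be positive")
    vals = img.values
    h, w = vals.shape
    grads = np.diff(vals, axis=1)  # (h, w-1)
    mask = np.zeros((h, w), dtype=np.uint8)

    rising = grads >= grad_threshold
    falling = grads <= -grad_threshold
    for y in range(h):
        r = np.nonzero(rising[y])[0]
        f = np.nonzero(falling[y])[0]
        if r.size == 0 or f.size == 0:
            continue
        left, right = r[0], f[-1]
        # gradient index i sits between pixels i and i+1: interior pixels
        # are left+1 .. right inclusive
        if left + 1 > right:
            continue
        seg = slice(left + 1, right + 1)
        mask[y, seg] = (vals[y, seg] > temp_threshold).astype(np.uint8)
    return ForegroundMask(mask)


def detect_neck(mask: ForegroundMask) -> NeckLandmark:
    """Find the row with the smallest positive foreground count.

    Ties break toward the smallest row index.  ``left_x`` is the leftmost
    foreground pixel on that row.
    """
    counts = mask.row_counts()
    pos = np.nonzero(counts > 0)[0]
    if pos.size == 0:
        raise LandmarkNotFoundError("no foreground pixels: cannot locate neck")
    row = int(pos[np.argmin(counts[pos])])  # argmin returns first minimum
    left_x = int(np.argmax(mask.values[row]))
    return NeckLandmark(row=row, left_x=left_x, foreground_count=int(counts[row]))


def _shift_with_fill(values: np.ndarray, dx: int, dy: int, fill: float) -> np.ndarray:
    h, w = values.shape
    out = np.full((h, w), fill, dtype=values.dtype)
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    if src_y.start < src_y.stop and src_x.start < src_x.stop:
        out[dst_y, dst_x] = values[src_y, src_x]
    return out


def prealign(
    follow_up: ThermalImage,
    reference: ThermalImage,
    temp_threshold: float = DEFAULT_TEMP_THRESHOLD,
    grad_threshold: float = DEFAULT_GRAD_THRESHOLD,
) -> tuple[ThermalImage, TranslationOffset]:
    """Shift a follow-up image so its neck lands on the reference neck.

    The integer shift is reference minus follow-up neck coordinates.
    Pixels exposed at the borders are filled with the follow-up's median
    background (mask-0) temperature.  Landmark detection failures in
    either image propagate as :class:`LandmarkNotFoundError`.
    """
    ref_mask = segment_foreground(reference, temp_threshold, grad_threshold)
    fol_mask = segment_foreground(follow_up, temp_threshold, grad_threshold)
    ref_neck = detect_neck(ref_mask)
    fol_neck = detect_neck(fol_mask)

    dx = ref_neck.left_x - fol_neck.left_x
    dy = ref_neck.row - fol_neck.row

    bg = follow_up.values[fol_mask.values == 0]
    fill = float(np.median(bg)) if bg.size else float(np.median(follow_up.values))

    if dx == 0 and dy == 0:
        shifted = follow_up.copy()
    else:
        shifted = ThermalImage(
            _shift_with_fill(follow_up.values, dx, dy, fill),
            follow_up.geometry,
            follow_up.label,
        )

    px_cm = pixel_size_cm(follow_up.geometry)
    offset = TranslationOffset(
        dx_px=dx, dy_px=dy, dx_cm=dx * px_cm, dy_cm=dy * px_cm
    )
    return shifted, offset
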