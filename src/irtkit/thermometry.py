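"""Temperature outcomes inside a region of interest."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateROIError, DimensionError, EmptyROIError
from .roi_tools import ROIMask
from .thermal_io import ThermalImage, pixel_size_cm

__all__ = ["TemperatureStats", "roi_stats", "gradient_homogeneity"]


@dataclass(frozen=True)
class TemperatureStats:
    """Mean/maximum ROI temperature, pixel count, and physical area."""

    mean_temp: float
    max_temp: float
    n_pixels: int
    area_cm2: float


def roi_stats(
    img: ThermalImage, mask: ROIMask, pixel_size_convention: str = "rounded"
) -> TemperatureStats:
    """Arithmetic mean and maximum temperature over mask-1 pixels.

    ``area_cm2`` is ``n_pixels * pixel_size^2``; the default "rounded"
    convention uses the 1-decimal pixel size (0.2 cm at the default
    geometry, i.e. 25 px per cm^2), matching reported areas.  Pass
    ``"exact"`` for the unrounded iFOV footprint.
    """
    if img.shape != mask.shape:
        raise DimensionError(
            f"image shape {img.shape} does not match mask {mask.shape}"
        )
    sel = mask.values == 1
    n = int(sel.sum())
    if n == 0:
        raise EmptyROIError("cannot compute statistics over an empty ROI")
    if pixel_size_convention not in ("rounded", "exact"):
        raise ValueError("pixel_size_convention must be 'rounded' or 'exact'")
    px = pixel_size_cm(img.geometry, rounded=pixel_size_convention == "rounded")
    vals = img.values[sel]
    return TemperatureStats(
        mean_temp=float(vals.mean()),
        max_temp=float(vals.max()),
        n_pixels=n,
        area_cm2=n * px * px,
    )


def gradient_homogeneity(
    img: ThermalImage, mask: ROIMask
) -> tuple[float, float]:
    """Mean and SD of the temperature-gradient magnitude within an ROI.

    Central differences; only interior mask pixels (those whose full
    central-difference stencil stays inside the mask) contribute, so the
    summary reflects within-region homogeneity rather than ROI edges.
    """
    if img.shape != mask.shape:
        raise DimensionError(
            f"image shape {img.shape} does not match mask {mask.shape}"
        )
    sel = mask.values.astype(bool)
    interior = ndimage.binary_erosion(sel)
    # the stencil also needs in-frame neighbours
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    if not interior.any():
        raise DegenerateROIError(
            "ROI too thin for central-difference gradients (no interior pixels)"
        )
    gy, gx = np.gradient(img.values)
    mag = np.hypot(gx, gy)[interior]
    return float(mag.mean()), float(mag.std())
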