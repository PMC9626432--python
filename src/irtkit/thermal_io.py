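"""Reading/writing 2-D temperature maps and camera-geometry unit conversions.

Temperature maps are stored either as delimited text matrices of degrees
Celsius (whitespace- or comma-separated) or as single-channel 32-bit float
TIFF.  Camera geometry (instantaneous field of view and subject distance)
converts pixel counts into physical lengths.

Coordinate convention: 0-based indices, ``x`` = column (left to right),
``y`` = row (top down), origin at the top-left pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionError, ThermalIOError

__all__ = [
    "CameraGeometry",
    "ThermalImage",
    "read_thermal",
    "write_thermal",
    "pixel_size_cm",
    "frame_size_cm",
    "pixels_per_cm2",
    "DEFAULT_GEOMETRY",
]


@dataclass(frozen=True)
class CameraGeometry:
    """Thermal camera imaging geometry.

    Parameters
    ----------
    ifov_mrad : float
        Instantaneous field of view per detector pixel, in milliradian.
    distance_m : float
        Camera-to-subject distance in meters.
    width_px, height_px : int
        Frame dimensions in pixels (x and y direction respectively).
    """

    ifov_mrad: float = 1.308
    distance_m: float = 1.5
    width_px: int = 320
    height_px: int = 240

    def __post_init__(self) -> None:
        if not self.ifov_mrad > 0:
            raise ValueError(f"ifov_mrad must be > 0, got {self.ifov_mrad}")
        if not self.distance_m > 0:
            raise ValueError(f"distance_m must be > 0, got {self.distance_m}")
        if self.width_px < 2 or self.height_px < 2:
            raise ValueError(
                f"frame must be at least 2x2 px, got {self.width_px}x{self.height_px}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) array shape of a frame."""
        return (self.height_px, self.width_px)


DEFAULT_GEOMETRY = CameraGeometry()


@dataclass
class ThermalImage:
    """A 2-D temperature grid in degrees Celsius plus its camera geometry.

    ``values[y, x]`` is the temperature of the pixel in row ``y``,
    column ``x``.
    """

    values: np.ndarray
    geometry: CameraGeometry
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError(
                f"temperature grid must be 2-D, got {self.values.ndim}-D"
            )
        if self.values.shape != self.geometry.shape:
            raise DimensionError(
                f"grid shape {self.values.shape} does not match geometry "
                f"{self.geometry.shape} (height_px, width_px)"
            )
        if not np.all(np.isfinite(self.values)):
            raise ThermalIOError("temperature grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ThermalImage":
        return ThermalImage(self.values.copy(), self.geometry, self.label)


def pixel_size_cm(geometry: CameraGeometry, rounded: bool = False) -> float:
    """Physical edge length of one detector pixel in cm.

    Small-angle footprint: ``ifov [rad] * distance [m]``, converted to cm.
    With ``rounded=True`` the value is rounded to one decimal, the
    convention used for reported pixel sizes.
    """
    size = geometry.ifov_mrad * 1e-3 * geometry.distance_m * 100.0
    return round(size, 1) if rounded else size


def frame_size_cm(
    geometry: CameraGeometry, rounded: bool = False
) -> tuple[float, float]:
    """Physical (width, height) of the full frame in cm.

    ``rounded=True`` rounds each extent to the nearest whole cm.
    """
    px = pixel_size_cm(geometry)
    w, h = geometry.width_px * px, geometry.height_px * px
    if rounded:
        return (float(round(w)), float(round(h)))
    return (w, h)


def pixels_per_cm2(geometry: CameraGeometry, rounded: bool = True) -> float:
    """Number of pixels covering 1 cm^2 of target surface.

    The default (``rounded=True``) follows the reporting convention of
    deriving the count from the 1-decimal pixel size and truncating:
    ``floor(1 / 0.2)^2 = 25``.  With ``rounded=False`` the exact value
    ``(1 / pixel_size)^2`` is returned.
    """
    if rounded:
        px = pixel_size_cm(geometry, rounded=True)
        # tiny epsilon guards against 1/0.2 landing just below 5.0 in binary fp
        return float(math.floor(1.0 / px + 1e-9) ** 2)
    return (1.0 / pixel_size_cm(geometry)) ** 2


def _parse_text_matrix(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            row = []
            for colno, tok in enumerate(tokens, start=1):
                try:
                    row.append(float(tok))
                except ValueError:
                    raise ThermalIOError(
                        f"{path}: non-numeric value {tok!r} at row {lineno}, "
                        f"column {colno}"
                    ) from None
            rows.append(row)
    if not rows:
        raise ThermalIOError(f"{path}: no numeric data found")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ThermalIOError(
            f"{path}: ragged matrix, row lengths {sorted(widths)}"
        )
    return np.asarray(rows, dtype=float)


def read_thermal(
    path: str | Path,
    geometry: CameraGeometry | None = None,
    label: str = "",
) -> ThermalImage:
    """Read a temperature map (text matrix or float TIFF) in degrees C.

    No rescaling is applied: stored values are taken as Celsius.  If
    ``geometry`` is given, the file's shape must match
    ``(height_px, width_px)``; otherwise a geometry with default camera
    optics and the file's dimensions is attached.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        values = np.asarray(tifffile.imread(path), dtype=float)
        if values.ndim != 2:
            raise ThermalIOError(
                f"{path}: expected a single-channel raster, got shape {values.shape}"
            )
    else:
        values = _parse_text_matrix(path)
    if geometry is None:
        geometry = CameraGeometry(
            width_px=values.shape[1], height_px=values.shape[0]
        )
    elif values.shape != geometry.shape:
        raise DimensionError(
            f"{path}: matrix shape {values.shape} does not match declared "
            f"geometry {geometry.shape} (height_px, width_px)"
        )
    return ThermalImage(values, geometry, label)


def write_thermal(img: ThermalImage, path: str | Path) -> None:
    """Write a temperature map as delimited text or 32-bit float TIFF.

    The format is chosen from the file suffix.  Text output uses ``%.10g``
    so a write/read round-trip reproduces values to stored precision.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img.values.astype(np.float32))
    else:
        np.savetxt(path, img.values, fmt="%.10g")
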