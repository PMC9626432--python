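"""ROI polygons: validation, rasterization, serialization, and transfer
of a single reference ROI to registered follow-up images.

Pixel-inclusion rule: a pixel belongs to the mask iff its center (integer
coordinate ``(x, y)``) lies inside or on the polygon boundary, evaluated
with the even-odd rule.  This is the convention that makes overlap
statistics reproducible across implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

from .errors import DimensionError, PolygonError
from .thermal_io import ThermalImage

__all__ = [
    "ROIPolygon",
    "ROIMask",
    "polygon_to_mask",
    "transfer_reference_roi",
    "read_polygon",
    "write_polygon",
    "read_mask",
    "write_mask",
]

KNOWN_LABELS = ("supraclavicular", "deltoid", "other")


@dataclass
class ROIPolygon:
    """Ordered vertex list in pixel coordinates with an anatomical label."""

    vertices: list[tuple[float, float]]
    label: str = "other"
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise PolygonError(
                f"polygon needs >= 3 vertices, got {len(self.vertices)}"
            )
        if self.label not in KNOWN_LABELS:
            raise PolygonError(
                f"label must be one of {KNOWN_LABELS}, got {self.label!r}"
            )
        geom = shapely.Polygon(self.vertices)
        if not geom.is_valid or geom.area <= 0:
            raise PolygonError(
                "polygon is degenerate or self-intersecting "
                f"(vertices: {self.vertices})"
            )

    @property
    def shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.shapely.area


@dataclass
class ROIMask:
    """Rasterized binary ROI (1 = inside), same grid as its image."""

    values: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("ROI mask must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "ROIMask":
        return ROIMask(self.values.copy(), self.label)


def polygon_to_mask(poly: ROIPolygon, shape: tuple[int, int]) -> ROIMask:
    """Rasterize a polygon onto an image grid.

    A pixel at (row y, column x) is included iff the point (x, y) is
    covered by the polygon (interior or boundary).  Vertices must lie
    within the frame.
    """
    h, w = shape
    for vx, vy in poly.vertices:
        if not (0 <= vx <= w - 1 and 0 <= vy <= h - 1):
            raise PolygonError(
                f"vertex ({vx}, {vy}) outside frame {w}x{h}"
            )
    geom = poly.shapely
    minx, miny, maxx, maxy = geom.bounds
    x0, x1 = max(0, int(np.floor(minx))), min(w - 1, int(np.ceil(maxx)))
    y0, y1 = max(0, int(np.floor(miny))), min(h - 1, int(np.ceil(maxy)))
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    pts = shapely.points(xx.ravel().astype(float), yy.ravel().astype(float))
    inside = shapely.covers(geom, pts).reshape(yy.shape)
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside.astype(np.uint8)
    return ROIMask(mask, poly.label)


def transfer_reference_roi(
    ref_mask: ROIMask, registered_followups: list[ThermalImage]
) -> list[tuple[ThermalImage, ROIMask]]:
    """Pair the reference ROI mask with each registered follow-up.

    Registered follow-ups already live in reference space, so the
    *identical* mask object is shared across pairs (no warping, no copy):
    a single delineation serves the whole session.
    """
    for img in registered_followups:
        if img.shape != ref_mask.shape:
            raise DimensionError(
                f"follow-up shape {img.shape} does not match reference "
                f"mask {ref_mask.shape}"
            )
    return [(img, ref_mask) for img in registered_followups]


def write_polygon(poly: ROIPolygon, path: str | Path) -> None:
    """Vertex file: 'label: <label>' header then one 'x,y' pair per line."""
    lines = [f"label: {poly.label}"]
    if poly.note:
        lines.append(f"# {poly.note}")
    lines += [f"{x:.6g},{y:.6g}" for x, y in poly.vertices]
    Path(path).write_text("\n".join(lines) + "\n")


def read_polygon(path: str | Path) -> ROIPolygon:
    label, note, verts = "other", "", []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("label:"):
            label = line.split(":", 1)[1].strip()
        elif line.startswith("#"):
            note = line.lstrip("# ").strip()
        else:
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise PolygonError(f"{path}: malformed vertex line {raw!r}")
            verts.append((float(parts[0]), float(parts[1])))
    return ROIPolygon(verts, label=label, note=note)


def write_mask(mask: ROIMask, path: str | Path) -> None:
    np.savetxt(path, mask.values, fmt="%d")


def read_mask(path: str | Path, label: str = "other") -> ROIMask:
    return ROIMask(np.loadtxt(path, dtype=int), label)
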