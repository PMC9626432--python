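"""Synthetic body-shaped thermal phantoms with ground truth.

The silhouette is deliberately schematic — a head disc, a narrow neck
strip and a trapezoidal torso, all centred on one column — because the
downstream landmark logic only requires a warm foreground with a single
constriction.  Every phantom carries its ground truth (neck coordinates,
body mask, displacement field) so pre-alignment and registration can be
tested without any acquired data.

Default temperature regimes: skin around 34.3 °C (thermoneutral; roughly
29.9 °C after cooling) on a ~22 °C room-temperature background.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .thermal_io import CameraGeometry, ThermalImage, DEFAULT_GEOMETRY

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "translate_phantom",
    "deform_phantom",
    "generate_session",
    "save_truth",
    "load_truth",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic thermal phantom.

    Silhouette parameters left as ``None`` are derived from the frame
    height so the same spec scales to reduced test geometries.
    ``skin_temp_sd``/``background_temp_sd`` are subject-level spreads used
    when sampling whole sessions; ``noise_sd`` is the per-pixel noise.
    ``texture_amp`` adds a smooth deterministic within-body temperature
    pattern (0 keeps the body flat), which gives the similarity metric
    signal away from the silhouette edges.
    """

    geometry: CameraGeometry = DEFAULT_GEOMETRY
    skin_temp_mean: float = 34.3
    skin_temp_sd: float = 0.5
    background_temp_mean: float = 22.0
    background_temp_sd: float = 0.3
    noise_sd: float = 0.2
    head_radius_px: int | None = None
    neck_halfwidth_px: int | None = None
    shoulder_row_px: int | None = None
    texture_amp: float = 0.0
    texture_period_px: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.skin_temp_mean - self.background_temp_mean <= 5:
            raise ValueError(
                "skin_temp_mean must exceed background_temp_mean by more "
                "than 5 degC for detectable transitions"
            )
        for name in ("skin_temp_sd", "background_temp_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        r, hw = self.resolved_head_radius, self.resolved_neck_halfwidth
        if hw >= r:
            raise ValueError(
                f"neck_halfwidth_px ({hw}) must be < head_radius_px ({r})"
            )

    @property
    def resolved_head_radius(self) -> int:
        if self.head_radius_px is not None:
            return self.head_radius_px
        return max(6, round(0.12 * self.geometry.height_px))

    @property
    def resolved_neck_halfwidth(self) -> int:
        if self.neck_halfwidth_px is not None:
            return self.neck_halfwidth_px
        return max(2, round(0.05 * self.geometry.height_px))

    @property
    def resolved_shoulder_row(self) -> int:
        if self.shoulder_row_px is not None:
            return self.shoulder_row_px
        # head top margin + diameter + neck length
        return self._head_top + 2 * self.resolved_head_radius + round(
            0.08 * self.geometry.height_px
        )

    @property
    def _head_top(self) -> int:
        return max(3, round(0.10 * self.geometry.height_px))


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom image."""

    neck_row: int
    neck_left_x: int
    body_mask: np.ndarray  # bool, image shape
    displacement_field: np.ndarray  # (H, W, 2) float, (dx, dy) in pixels
    background_temp_mean: float = 22.0
    noise_sd: float = 0.2

    def copy(self) -> "PhantomTruth":
        return PhantomTruth(
            self.neck_row,
            self.neck_left_x,
            self.body_mask.copy(),
            self.displacement_field.copy(),
            self.background_temp_mean,
            self.noise_sd,
        )


def _silhouette_halfwidths(spec: PhantomSpec) -> tuple[np.ndarray, int, int]:
    """Per-row foreground half-width, or -1 for background rows.

    Returns (halfwidths indexed by row, neck_top_row, center_x).  Every
    non-neck body row is strictly wider than the neck strip, so the
    minimum-count row is the topmost neck row.
    """
    g = spec.geometry
    h, w = g.height_px, g.width_px
    r = spec.resolved_head_radius
    hw = spec.resolved_neck_halfwidth
    head_top = spec._head_top
    cy = head_top + r
    shoulder = spec.resolved_shoulder_row
    # generous bottom margin leaves headroom for the displacement regimes
    bottom = h - max(4, round(0.20 * h))
    cx = w // 2

    # head ends where the disc chord would narrow to the neck width
    drop = math.sqrt(max(r**2 - (hw + 2) ** 2, 0.0))
    neck_top = cy + int(math.ceil(drop))
    if not (head_top < neck_top < shoulder < bottom):
        raise GeometryError(
            f"silhouette rows out of order: head_top={head_top}, "
            f"neck_top={neck_top}, shoulder={shoulder}, bottom={bottom}, "
            f"frame height {h}"
        )

    shoulder_half = min(round(2.2 * r), (w - 4) // 2 - 1)
    max_half = min(round(3.0 * r), (w - 4) // 2)
    if shoulder_half <= hw + 2:
        raise GeometryError("frame too narrow for torso wider than the neck")

    halfs = np.full(h, -1, dtype=int)
    for y in range(head_top, neck_top):
        chord = math.sqrt(max(r**2 - (y - cy) ** 2, 0.0))
        halfs[y] = max(hw + 2, int(round(chord)))
    for y in range(neck_top, shoulder):
        halfs[y] = hw
    n_torso = bottom - shoulder
    for i, y in enumerate(range(shoulder, bottom)):
        frac = i / max(n_torso - 1, 1)
        halfs[y] = round(shoulder_half + frac * (max_half - shoulder_half))

    if cx - max_half < 1 or cx + max_half > w - 2:
        raise GeometryError("silhouette exceeds frame width")
    return halfs, neck_top, cx


def _body_mask(spec: PhantomSpec) -> tuple[np.ndarray, int, int]:
    halfs, neck_top, cx = _silhouette_halfwidths(spec)
    h, w = spec.geometry.shape
    mask = np.zeros((h, w), dtype=bool)
    for y in range(h):
        if halfs[y] >= 0:
            mask[y, cx - halfs[y] : cx + halfs[y] + 1] = True
    return mask, neck_top, cx


def _texture(spec: PhantomSpec) -> np.ndarray:
    """Smooth deterministic temperature pattern added inside the body."""
    if spec.texture_amp == 0.0:
        return np.zeros(spec.geometry.shape)
    h, w = spec.geometry.shape
    y, x = np.mgrid[0:h, 0:w].astype(float)
    p = spec.texture_period_px
    pat = 0.5 * (
        np.sin(2 * np.pi * x / p + 0.7) + np.sin(2 * np.pi * y / (1.37 * p) + 1.3)
    )
    return spec.texture_amp * pat


def generate_phantom(spec: PhantomSpec) -> tuple[ThermalImage, PhantomTruth]:
    """Generate a phantom image and its ground truth, deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    mask, neck_top, cx = _body_mask(spec)
    h, w = spec.geometry.shape

    values = np.full((h, w), spec.background_temp_mean, dtype=float)
    values[mask] = spec.skin_temp_mean
    values[mask] += _texture(spec)[mask]
    if spec.noise_sd > 0:
        # truncated at +/- 2.5 sd so the 25 degC threshold provably
        # separates body from background for any noise_sd <= 1
        noise = rng.normal(0.0, spec.noise_sd, size=(h, w))
        np.clip(noise, -2.5 * spec.noise_sd, 2.5 * spec.noise_sd, out=noise)
        values += noise

    truth = PhantomTruth(
        neck_row=neck_top,
        neck_left_x=cx - spec.resolved_neck_halfwidth,
        body_mask=mask,
        displacement_field=np.zeros((h, w, 2)),
        background_temp_mean=spec.background_temp_mean,
        noise_sd=spec.noise_sd,
    )
    img = ThermalImage(values, spec.geometry, label=f"phantom seed={spec.seed}")
    return img, truth


def translate_phantom(
    img: ThermalImage,
    truth: PhantomTruth,
    dx: int,
    dy: int,
    seed: int = 0,
) -> tuple[ThermalImage, PhantomTruth]:
    """Shift a phantom by an integer (dx, dy), filling vacated pixels.

    Vacated pixels receive fresh draws from the background model (the
    camera would see room-temperature scene sliding in at the frame edge).
    Raises :class:`GeometryError` if the silhouette would be clipped.
    """
    if dx != int(dx) or dy != int(dy):
        raise ValueError("dx and dy must be integers")
    dx, dy = int(dx), int(dy)
    h, w = img.shape

    ys, xs = np.nonzero(truth.body_mask)
    if (
        ys.min() + dy < 0
        or ys.max() + dy >= h
        or xs.min() + dx < 0
        or xs.max() + dx >= w
    ):
        raise GeometryError(
            f"translation ({dx}, {dy}) px clips the silhouette out of frame"
        )

    if dx == 0 and dy == 0:
        return img.copy(), truth.copy()

    rng = np.random.default_rng(seed)
    sd = max(truth.noise_sd, 0.0)
    out = truth.background_temp_mean + np.clip(
        rng.normal(0.0, sd, size=(h, w)) if sd > 0 else np.zeros((h, w)),
        -2.5 * sd,
        2.5 * sd,
    )
    new_mask = np.zeros((h, w), dtype=bool)
    new_field = np.zeros_like(truth.displacement_field)

    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = img.values[src_y, src_x]
    new_mask[dst_y, dst_x] = truth.body_mask[src_y, src_x]
    new_field[dst_y, dst_x] = truth.displacement_field[src_y, src_x]

    new_truth = PhantomTruth(
        neck_row=truth.neck_row + dy,
        neck_left_x=truth.neck_left_x + dx,
        body_mask=new_mask,
        displacement_field=new_field,
        background_temp_mean=truth.background_temp_mean,
        noise_sd=truth.noise_sd,
    )
    shifted = ThermalImage(out, img.geometry, label=img.label + f" shifted({dx},{dy})")
    return shifted, new_truth


def sinusoid_field(
    shape: tuple[int, int],
    amplitude_px: float,
    wavelength_px: float,
    seed: int = 0,
) -> np.ndarray:
    """Smooth separable sinusoidal displacement field, (H, W, 2) = (dx, dy).

    The wavelength is snapped to a multiple of 4 pixels and the phase
    offsets are integer pixels, so the field attains exactly
    ``amplitude_px`` at its extrema on the integer grid (provided the
    frame spans at least one wavelength).
    """
    h, w = shape
    lam = max(4, 4 * round(wavelength_px / 4))
    rng = np.random.default_rng(seed)
    x0, y0 = int(rng.integers(0, lam)), int(rng.integers(0, lam))
    x1, y1 = int(rng.integers(0, lam)), int(rng.integers(0, lam))
    y, x = np.mgrid[0:h, 0:w].astype(float)
    field = np.zeros((h, w, 2))
    field[..., 0] = amplitude_px * np.sin(2 * np.pi * (x - x0) / lam) * np.cos(
        2 * np.pi * (y - y0) / lam
    )
    field[..., 1] = amplitude_px * np.cos(2 * np.pi * (x - x1) / lam) * np.sin(
        2 * np.pi * (y - y1) / lam
    )
    return field


def deform_phantom(
    img: ThermalImage,
    truth: PhantomTruth,
    amplitude_px: float,
    wavelength_px: float,
    seed: int = 0,
) -> tuple[ThermalImage, PhantomTruth]:
    """Warp a phantom by a known smooth displacement field.

    The output image is ``out(x) = in(x + d(x))`` (backward warp, linear
    interpolation) and ``truth.displacement_field`` records ``d`` — the
    field a registration with the deformed image as *fixed* and the
    original as *moving* should recover.
    """
    if amplitude_px < 0 or amplitude_px > 5:
        raise ValueError("amplitude_px must be in [0, 5] (small smooth warps)")
    if amplitude_px > 0 and wavelength_px < 4 * amplitude_px:
        raise ValueError("wavelength_px must be >= 4 * amplitude_px")
    if amplitude_px == 0:
        out_truth = truth.copy()
        out_truth.displacement_field = np.zeros_like(truth.displacement_field)
        return img.copy(), out_truth

    h, w = img.shape
    field = sinusoid_field((h, w), amplitude_px, wavelength_px, seed)
    y, x = np.mgrid[0:h, 0:w].astype(float)
    coords = [y + field[..., 1], x + field[..., 0]]
    warped = ndimage.map_coordinates(img.values, coords, order=1, mode="nearest")
    warped_mask = (
        ndimage.map_coordinates(
            truth.body_mask.astype(np.uint8), coords, order=0, mode="nearest"
        )
        > 0
    )

    # keep truth landmark consistent with the detector definition
    counts = warped_mask.sum(axis=1)
    pos = np.nonzero(counts > 0)[0]
    neck_row = int(pos[np.argmin(counts[pos])])
    neck_left_x = int(np.argmax(warped_mask[neck_row]))

    out_truth = PhantomTruth(
        neck_row=neck_row,
        neck_left_x=neck_left_x,
        body_mask=warped_mask,
        displacement_field=field,
        background_temp_mean=truth.background_temp_mean,
        noise_sd=truth.noise_sd,
    )
    out = ThermalImage(warped, img.geometry, label=img.label + " warped")
    return out, out_truth


def generate_session(
    spec: PhantomSpec,
    seed: int,
    n_followups: int = 3,
    shift_scale_cm: tuple[float, float] = (7.5, 3.6),
    warp_amplitude_px: float = 2.0,
    warp_wavelength_px: float = 40.0,
) -> dict:
    """Generate a reference + follow-up session for one synthetic subject.

    Follow-ups mimic repeated acquisitions: same subject (same silhouette,
    subject-level temperature offsets drawn once per image), displaced by
    random integer shifts on the scale of the stated displacement regime
    (clamped so the silhouette stays in frame) and optionally warped by a
    small smooth field.

    Returns a dict with keys ``reference``, ``followups`` (lists of
    (image, truth) pairs) and ``shifts``.
    """
    from .thermal_io import pixel_size_cm

    rng = np.random.default_rng(seed)
    px_cm = pixel_size_cm(spec.geometry)

    def subject_spec(label_seed: int) -> PhantomSpec:
        skin = spec.skin_temp_mean + rng.normal(0.0, spec.skin_temp_sd)
        bg = spec.background_temp_mean + rng.normal(0.0, spec.background_temp_sd)
        return replace(
            spec,
            skin_temp_mean=skin,
            background_temp_mean=bg,
            seed=label_seed,
        )

    ref_img, ref_truth = generate_phantom(subject_spec(int(rng.integers(2**31))))
    ref_img.label = "reference"

    h, w = spec.geometry.shape

    followups, shifts = [], []
    labels = ["morning post-cooling", "evening pre-cooling", "evening post-cooling"]
    for i in range(n_followups):
        img_i, truth_i = generate_phantom(subject_spec(int(rng.integers(2**31))))
        if warp_amplitude_px > 0:
            img_i, truth_i = deform_phantom(
                img_i,
                truth_i,
                warp_amplitude_px,
                warp_wavelength_px,
                seed=int(rng.integers(2**31)),
            )
        # clamp against this follow-up's own (possibly warped) silhouette
        ys, xs = np.nonzero(truth_i.body_mask)
        dx = int(np.clip(round(rng.normal(0, shift_scale_cm[0] / px_cm)),
                         -int(xs.min()), int(w - 1 - xs.max())))
        dy = int(np.clip(round(rng.normal(0, shift_scale_cm[1] / px_cm)),
                         -int(ys.min()), int(h - 1 - ys.max())))
        img_i, truth_i = translate_phantom(
            img_i, truth_i, dx, dy, seed=int(rng.integers(2**31))
        )
        img_i.label = labels[i] if i < len(labels) else f"follow-up {i + 1}"
        followups.append((img_i, truth_i))
        shifts.append((dx, dy))

    return {"reference": (ref_img, ref_truth), "followups": followups,
            "shifts": shifts}


def save_truth(truth: PhantomTruth, path: str | Path) -> None:
    """Serialize ground truth as structured text (JSON)."""
    payload = {
        "neck_row": int(truth.neck_row),
        "neck_left_x": int(truth.neck_left_x),
        "background_temp_mean": float(truth.background_temp_mean),
        "noise_sd": float(truth.noise_sd),
        "body_mask": truth.body_mask.astype(int).tolist(),
        "displacement_field": truth.displacement_field.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_truth(path: str | Path) -> PhantomTruth:
    payload = json.loads(Path(path).read_text())
    return PhantomTruth(
        neck_row=payload["neck_row"],
        neck_left_x=payload["neck_left_x"],
        body_mask=np.asarray(payload["body_mask"], dtype=bool),
        displacement_field=np.asarray(payload["displacement_field"], dtype=float),
        background_temp_mean=payload["background_temp_mean"],
        noise_sd=payload["noise_sd"],
    )
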