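"""Non-rigid B-spline registration driven by Mattes mutual information.

The deformation is a free-form cubic B-spline: a lattice of control-point
displacement coefficients at fixed spacing, interpolated to a dense
per-pixel displacement.  Registration maximizes mutual information
between the fixed image and the warped moving image with a stochastic
gradient ascent whose gain decays as ``a0 / (k + A)^alpha`` and whose
per-coefficient step is clamped to ``max_step_length`` (interpreted in
control-coefficient units, i.e. pixels).  A coarse-to-fine Gaussian
pyramid doubles the physical control spacing at each coarser level.

Gradients use a cubic Parzen window on the moving-intensity axis (hard
binning on the fixed axis), the standard differentiable Mattes estimator.
The reported metric (:func:`mattes_mi`) uses hard binning on both axes,
which makes it exactly symmetric and makes ``MI(I, I)`` equal the binned
marginal entropy.

The returned model is the candidate (including the identity) with the
highest full-image metric, so the final MI never falls below the initial
value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import (
    DimensionError,
    DomainError,
    OptimizationDivergedError,
)
from .prealign import DEFAULT_TEMP_THRESHOLD
from .thermal_io import CameraGeometry, ThermalImage, pixel_size_cm

__all__ = [
    "RegistrationSettings",
    "DeformationModel",
    "ConvergenceTrace",
    "ConvergenceSummary",
    "mattes_mi",
    "transform_point",
    "resample_image",
    "resample_mask",
    "register",
    "check_convergence",
    "grid_spacing_px",
]

# Robbins-Monro gain decay constants (gain a_k = a0 * A^alpha / (k+A)^alpha)
_GAIN_ALPHA = 0.6
_GAIN_A = 20.0


@dataclass(frozen=True)
class RegistrationSettings:
    """Registration configuration; defaults follow the optimized protocol:
    10 mm control grid, 4 resolutions, 450 iterations per level, maximum
    step length 0.5."""

    grid_spacing_mm: float = 10.0
    n_resolutions: int = 4
    n_iterations: int = 450
    max_step_length: float = 0.5
    n_histogram_bins: int = 32
    sample_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_spacing_mm <= 0:
            raise ValueError("grid_spacing_mm must be positive")
        if self.n_resolutions < 1 or self.n_iterations < 1:
            raise ValueError("resolution and iteration counts must be positive")
        if self.max_step_length <= 0:
            raise ValueError("max_step_length must be positive")
        if self.n_histogram_bins < 4:
            raise ValueError("n_histogram_bins must be >= 4")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")


def grid_spacing_px(settings: RegistrationSettings, geometry: CameraGeometry) -> int:
    """Control-point spacing in pixels: nearest integer >= 2."""
    mm_per_px = pixel_size_cm(geometry) * 10.0
    return max(2, round(settings.grid_spacing_mm / mm_per_px))


# ---------------------------------------------------------------------------
# cubic B-spline machinery


def _bspline_weights(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Uniform cubic B-spline interpolation weights.

    For grid coordinate ``u`` returns ``(i0, w)`` where the four control
    indices ``i0-1 .. i0+2`` carry weights ``w[..., 0..3]``.
    """
    i0 = np.floor(u).astype(int)
    t = u - i0
    t2, t3 = t * t, t * t * t
    w = np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ],
        axis=-1,
    )
    return i0, w


def _grid_size(extent: int, spacing: float) -> int:
    # control indices -1 .. floor((extent-1)/spacing) + 2, stored with +1 offset
    return int(np.floor((extent - 1) / spacing)) + 4


@dataclass
class DeformationModel:
    """Free-form cubic B-spline deformation over an image domain.

    ``coeff[ky, kx]`` holds the (dx, dy) displacement coefficient of
    control point ``(kx - 1, ky - 1)`` (one-lattice border beyond the
    domain on each side); ``spacing_px`` is the lattice spacing.  The
    identity model has all-zero coefficients.
    """

    coeff: np.ndarray  # (Ky, Kx, 2) float
    spacing_px: float
    domain: tuple[int, int]  # (H, W)

    def __post_init__(self) -> None:
        self.coeff = np.asarray(self.coeff, dtype=float)
        h, w = self.domain
        expect = (_grid_size(h, self.spacing_px), _grid_size(w, self.spacing_px), 2)
        if self.coeff.shape != expect:
            raise DimensionError(
                f"coefficient lattice shape {self.coeff.shape} does not match "
                f"domain {self.domain} at spacing {self.spacing_px} "
                f"(expected {expect})"
            )

    @classmethod
    def identity(cls, domain: tuple[int, int], spacing_px: float) -> "DeformationModel":
        h, w = domain
        shape = (_grid_size(h, spacing_px), _grid_size(w, spacing_px), 2)
        return cls(np.zeros(shape), spacing_px, domain)

    def displacement(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Interpolated (dx, dy) displacement at pixel coordinates."""
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        i0x, wx = _bspline_weights(xs / self.spacing_px)
        i0y, wy = _bspline_weights(ys / self.spacing_px)
        out = np.zeros(xs.shape + (2,))
        for a in range(4):
            for b in range(4):
                wgt = (wy[..., a] * wx[..., b])[..., None]
                out += self.coeff[i0y + a, i0x + b] * wgt
        return out

    def dense_field(self) -> np.ndarray:
        """(H, W, 2) displacement field over the full domain."""
        h, w = self.domain
        y, x = np.mgrid[0:h, 0:w].astype(float)
        return self.displacement(x, y)

    def max_coefficient(self) -> float:
        return float(np.abs(self.coeff).max())

    def save(self, path: str | Path) -> None:
        payload = {
            "spacing_px": self.spacing_px,
            "domain": list(self.domain),
            "coeff": self.coeff.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "DeformationModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.asarray(payload["coeff"], dtype=float),
            payload["spacing_px"],
            tuple(payload["domain"]),
        )


def transform_point(
    model: DeformationModel, p: tuple[float, float]
) -> tuple[float, float]:
    """Map an (x, y) point through the deformation: ``p + displacement(p)``."""
    x, y = p
    h, w = model.domain
    if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
        raise DomainError(f"point {p} outside domain {w}x{h}")
    d = model.displacement(np.asarray([x]), np.asarray([y]))[0]
    return (x + float(d[0]), y + float(d[1]))


def _as_array(img) -> np.ndarray:
    return img.values if hasattr(img, "values") else np.asarray(img, dtype=float)


def _background_fill(values: np.ndarray) -> float:
    bg = values[values < DEFAULT_TEMP_THRESHOLD]
    return float(np.median(bg)) if bg.size else float(np.median(values))


def resample_image(
    moving: ThermalImage,
    model: DeformationModel,
    fill_value: float | None = None,
) -> ThermalImage:
    """Backward-warp the moving image: ``out(x) = moving(x + D(x))``.

    Bilinear interpolation; samples falling outside the domain are filled
    with the moving image's median background temperature (or
    ``fill_value``).
    """
    vals = moving.values
    if model.domain != vals.shape:
        raise DimensionError(
            f"model domain {model.domain} does not match image {vals.shape}"
        )
    if fill_value is None:
        fill_value = _background_fill(vals)
    field = model.dense_field()
    h, w = vals.shape
    y, x = np.mgrid[0:h, 0:w].astype(float)
    out = ndimage.map_coordinates(
        vals,
        [y + field[..., 1], x + field[..., 0]],
        order=1,
        mode="constant",
        cval=fill_value,
    )
    return ThermalImage(out, moving.geometry, moving.label)


def resample_mask(mask, model: DeformationModel):
    """Backward-warp a binary mask with nearest-neighbour interpolation.

    Accepts an ``ROIMask`` (returned as the same type) or a bare binary
    array.  Out-of-domain samples become 0; output is strictly binary.
    """
    values = mask.values if hasattr(mask, "values") else np.asarray(mask)
    if model.domain != values.shape:
        raise DimensionError(
            f"model domain {model.domain} does not match mask {values.shape}"
        )
    field = model.dense_field()
    h, w = values.shape
    y, x = np.mgrid[0:h, 0:w].astype(float)
    out = ndimage.map_coordinates(
        values.astype(np.uint8),
        [y + field[..., 1], x + field[..., 0]],
        order=0,
        mode="constant",
        cval=0,
    ).astype(np.uint8)
    if hasattr(mask, "values"):
        return type(mask)(values=out, label=getattr(mask, "label", "other"))
    return out


# ---------------------------------------------------------------------------
# Mattes mutual information


def mattes_mi(fixed, moving, n_bins: int = 32) -> float:
    """Mutual information (nat) from a joint intensity histogram.

    Intensities of each image are linearly rescaled onto ``n_bins`` bins.
    Hard (zero-order Parzen) binning on both axes makes the value exactly
    symmetric under argument swap; a constant image on either side yields
    0 by definition (degenerate marginal).
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    f = _as_array(fixed).ravel()
    m = _as_array(moving).ravel()
    if f.shape != m.shape:
        raise DimensionError("fixed and moving images must share a shape")

    frange = f.max() - f.min()
    mrange = m.max() - m.min()
    if frange <= 0 or mrange <= 0:
        return 0.0
    fb = np.minimum((f - f.min()) / frange * n_bins, n_bins - 1).astype(int)
    mb = np.minimum((m - m.min()) / mrange * n_bins, n_bins - 1).astype(int)
    joint = np.bincount(fb * n_bins + mb, minlength=n_bins * n_bins).astype(float)
    joint /= joint.sum()
    joint = joint.reshape(n_bins, n_bins)
    pf = joint.sum(axis=1)
    pm = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(pf, pm)[nz])))
    return max(mi, 0.0)


def _parzen_cubic(t: np.ndarray) -> np.ndarray:
    a = np.abs(t)
    out = np.zeros_like(a)
    inner = a <= 1
    outer = (a > 1) & (a < 2)
    out[inner] = 2.0 / 3.0 - a[inner] ** 2 + a[inner] ** 3 / 2.0
    out[outer] = (2.0 - a[outer]) ** 3 / 6.0
    return out


def _parzen_cubic_d(t: np.ndarray) -> np.ndarray:
    a = np.abs(t)
    out = np.zeros_like(a)
    inner = a <= 1
    outer = (a > 1) & (a < 2)
    out[inner] = -2.0 * a[inner] + 1.5 * a[inner] ** 2
    out[outer] = -0.5 * (2.0 - a[outer]) ** 2
    return out * np.sign(t)


def _smooth_mi_and_alpha(
    F: np.ndarray, M: np.ndarray, fstats, mstats, n_bins: int
) -> tuple[float, np.ndarray]:
    """Parzen-smoothed MI over samples plus dMI/dM_i per sample.

    ``fstats``/``mstats`` are (min, range) pairs fixed per pyramid level
    so the binning does not move with the warp.
    """
    n = F.size
    fmin, frange = fstats
    mmin, mrange = mstats
    fb = np.clip(((F - fmin) / frange * n_bins).astype(int), 0, n_bins - 1)
    scale = (n_bins - 3) / mrange  # d(bin coord)/d(intensity)
    cm = np.clip(1.0 + (M - mmin) * scale, 1.0, n_bins - 2.0 - 1e-9)
    base = np.floor(cm).astype(int)

    joint = np.zeros((n_bins, n_bins))
    offsets = (-1, 0, 1, 2)
    wm_list, dwm_list, mb_list = [], [], []
    for off in offsets:
        mbin = base + off
        t = mbin - cm
        wm = _parzen_cubic(t)
        np.add.at(joint, (fb, mbin), wm)
        wm_list.append(wm)
        dwm_list.append(_parzen_cubic_d(t))
        mb_list.append(mbin)
    joint /= n
    pm = joint.sum(axis=0)
    pf = joint.sum(axis=1)
    nzj = joint > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.where(nzj, np.log(joint / pm[None, :]), 0.0)
    mi = float(
        np.sum(joint[nzj] * np.log(joint[nzj] / np.outer(pf, pm)[nzj]))
    )
    alpha = np.zeros(n)
    for off_i in range(4):
        alpha -= dwm_list[off_i] * log_ratio[fb, mb_list[off_i]]
    alpha *= scale / n
    return mi, alpha


# ---------------------------------------------------------------------------
# registration driver


@dataclass
class ConvergenceTrace:
    """Per-iteration metric values (full-image MI), concatenated per level
    from coarsest to finest."""

    values: np.ndarray
    level_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("iteration,level,mi\n")
            idx, level = 0, 0
            bounds = np.cumsum(self.level_lengths) if self.level_lengths else []
            for i, v in enumerate(self.values):
                while level < len(bounds) and i >= bounds[level]:
                    level += 1
                fh.write(f"{i},{level},{v:.10g}\n")


@dataclass(frozen=True)
class ConvergenceSummary:
    converged: bool
    mean_abs_delta: float
    trace_range: float
    window_len: int


def check_convergence(
    trace: ConvergenceTrace,
    window_fraction: float = 0.1,
    tol_fraction: float = 0.01,
) -> ConvergenceSummary:
    """Stabilization check: converged iff the mean absolute successive
    change over the trailing window is below ``tol_fraction`` of the
    trace's total range."""
    v = np.asarray(trace.values if hasattr(trace, "values") else trace, float)
    if v.size == 0:
        raise ValueError("empty convergence trace")
    n = v.size
    wlen = max(2, int(np.ceil(window_fraction * n)))
    if wlen > n:
        warnings.warn(
            "trace shorter than requested window; evaluating over full trace"
        )
        wlen = n
    tail = v[-wlen:]
    mean_abs_delta = float(np.mean(np.abs(np.diff(tail)))) if wlen > 1 else 0.0
    rng = float(v.max() - v.min())
    converged = True if rng == 0.0 else mean_abs_delta < tol_fraction * rng
    return ConvergenceSummary(converged, mean_abs_delta, rng, wlen)


def _pyramid_level(values: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return values
    smoothed = ndimage.gaussian_filter(values, sigma=factor / 2.0)
    return smoothed[::factor, ::factor]


def _refine_model(
    coarse: DeformationModel, domain: tuple[int, int], spacing: float
) -> DeformationModel:
    """Initialize a finer-level model from a coarser one (2x scale jump).

    Coefficients are seeded with the coarse model's displacement sampled
    at the new control-point locations — an approximation (coefficients
    are not values) that the subsequent optimization refines.
    """
    h, w = domain
    ky = _grid_size(h, spacing)
    kx = _grid_size(w, spacing)
    xs = (np.arange(kx) - 1) * spacing
    ys = (np.arange(ky) - 1) * spacing
    gx, gy = np.meshgrid(xs, ys)
    ch, cw = coarse.domain
    cgx = np.clip(gx / 2.0, 0, cw - 1)
    cgy = np.clip(gy / 2.0, 0, ch - 1)
    disp = coarse.displacement(cgx, cgy) * 2.0
    return DeformationModel(disp, spacing, domain)


def _bilinear(values: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    h, w = values.shape
    ix = np.clip(np.floor(xs).astype(int), 0, w - 2)
    iy = np.clip(np.floor(ys).astype(int), 0, h - 2)
    tx, ty = xs - ix, ys - iy
    v00 = values[iy, ix]
    v01 = values[iy, ix + 1]
    v10 = values[iy + 1, ix]
    v11 = values[iy + 1, ix + 1]
    return (
        v00 * (1 - tx) * (1 - ty)
        + v01 * tx * (1 - ty)
        + v10 * (1 - tx) * ty
        + v11 * tx * ty
    )


def register(
    fixed: ThermalImage,
    moving: ThermalImage,
    settings: RegistrationSettings = RegistrationSettings(),
) -> tuple[DeformationModel, ConvergenceTrace]:
    """Register ``moving`` onto ``fixed`` with a multi-resolution B-spline.

    Coarse-to-fine stochastic gradient ascent on Mattes MI.  The trace
    records the full-image (level-resolution) MI after every iteration.
    Returns the deformation model for the full-resolution domain and the
    trace.  Raises :class:`OptimizationDivergedError` (with partial
    trace attached) if the metric becomes non-finite.
    """
    fvals, mvals = fixed.values, moving.values
    if fvals.shape != mvals.shape:
        raise DimensionError("fixed and moving images must share a shape")

    n_bins = settings.n_histogram_bins
    spacing = grid_spacing_px(settings, fixed.geometry)
    fill = _background_fill(mvals)

    trace_values: list[float] = []
    level_lengths: list[int] = []
    model: DeformationModel | None = None
    best: tuple[float, np.ndarray] | None = None  # finest level only

    levels = list(range(settings.n_resolutions - 1, -1, -1))
    for level in levels:
        factor = 2**level
        f_l = _pyramid_level(fvals, factor)
        m_l = _pyramid_level(mvals, factor)
        h, w = f_l.shape
        if min(h, w) < 8:
            raise ValueError(
                f"pyramid level {level} image {w}x{h} too small; "
                "reduce n_resolutions"
            )
        if model is None:
            model = DeformationModel.identity((h, w), spacing)
        else:
            model = _refine_model(model, (h, w), spacing)

        fstats = (f_l.min(), max(f_l.max() - f_l.min(), 1e-12))
        mstats = (m_l.min(), max(m_l.max() - m_l.min(), 1e-12))
        grad_y, grad_x = np.gradient(m_l)
        rng = np.random.default_rng(settings.seed * 1_000_003 + level)
        n_samples = max(100, int(round(settings.sample_fraction * h * w)))
        yy, xx = np.mgrid[0:h, 0:w].astype(float)

        a0 = None
        for k in range(settings.n_iterations):
            xs = rng.integers(0, w, n_samples)
            ys = rng.integers(0, h, n_samples)
            i0x, wx = _bspline_weights(xs / model.spacing_px)
            i0y, wy = _bspline_weights(ys / model.spacing_px)
            disp = np.zeros((n_samples, 2))
            for a in range(4):
                for b in range(4):
                    wgt = (wy[:, a] * wx[:, b])[:, None]
                    disp += model.coeff[i0y + a, i0x + b] * wgt
            px = xs + disp[:, 0]
            py = ys + disp[:, 1]
            valid = (px >= 0) & (px <= w - 1) & (py >= 0) & (py <= h - 1)
            if valid.sum() >= 16:
                v = valid
                M = _bilinear(m_l, px[v], py[v])
                F = f_l[ys[v], xs[v]]
                _, alpha = _smooth_mi_and_alpha(F, M, fstats, mstats, n_bins)
                gx_s = _bilinear(grad_x, px[v], py[v])
                gy_s = _bilinear(grad_y, px[v], py[v])
                gvec = np.stack([alpha * gx_s, alpha * gy_s], axis=-1)
                grad = np.zeros_like(model.coeff)
                wxv, wyv = wx[v], wy[v]
                i0xv, i0yv = i0x[v], i0y[v]
                for a in range(4):
                    for b in range(4):
                        wgt = (wyv[:, a] * wxv[:, b])[:, None]
                        np.add.at(grad, (i0yv + a, i0xv + b), gvec * wgt)
                gnorm = np.abs(grad).max()
                if a0 is None:
                    a0 = settings.max_step_length / (gnorm + 1e-12)
                gain = a0 * _GAIN_A**_GAIN_ALPHA / (k + _GAIN_A) ** _GAIN_ALPHA
                step = np.clip(
                    gain * grad,
                    -settings.max_step_length,
                    settings.max_step_length,
                )
                model.coeff += step

            # full-image metric for the trace (deterministic)
            fld = model.displacement(xx, yy)
            warped = ndimage.map_coordinates(
                m_l,
                [yy + fld[..., 1], xx + fld[..., 0]],
                order=1,
                mode="constant",
                cval=fill,
            )
            mi_full = mattes_mi(f_l, warped, n_bins)
            if not np.isfinite(mi_full):
                raise OptimizationDivergedError(
                    f"non-finite metric at level {level}, iteration {k}",
                    trace=ConvergenceTrace(np.asarray(trace_values), level_lengths),
                )
            trace_values.append(mi_full)
            if level == 0 and (best is None or mi_full > best[0]):
                best = (mi_full, model.coeff.copy())
        level_lengths.append(settings.n_iterations)

    assert model is not None
    # candidate set: identity, initial finest model (implicit in iterates),
    # best iterate — keep whichever maximizes the full-resolution metric
    identity = DeformationModel.identity(model.domain, spacing)
    mi_identity = mattes_mi(fvals, mvals, n_bins)
    if best is not None and best[0] > mi_identity:
        model = DeformationModel(best[1], model.spacing_px, model.domain)
    else:
        model = identity

    trace = ConvergenceTrace(np.asarray(trace_values), level_lengths)
    return model, trace
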