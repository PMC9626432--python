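"""Per-subject workflow orchestration: reference + follow-ups through
pre-alignment, registration, reference-ROI transfer and ROI statistics.

A session is one subject's image set (reference = morning pre-cooling,
follow-ups = the remaining acquisitions).  Stage order is fixed:
pre-align first, then register — the registration input is asserted to
carry the reference neck landmark.  A failing follow-up is logged and
skipped without aborting its siblings; a failing subject does not abort
the batch.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .errors import InputError, IRTError
from .prealign import (
    DEFAULT_GRAD_THRESHOLD,
    DEFAULT_TEMP_THRESHOLD,
    TranslationOffset,
    detect_neck,
    prealign,
    segment_foreground,
)
from .registration import (
    ConvergenceTrace,
    DeformationModel,
    RegistrationSettings,
    check_convergence,
    register,
    resample_image,
)
from .roi_tools import ROIMask, ROIPolygon, polygon_to_mask, transfer_reference_roi
from .thermal_io import CameraGeometry, ThermalImage, read_thermal
from .thermometry import roi_stats

__all__ = ["SessionSet", "SessionResult", "run_session", "run_batch"]


@dataclass
class SessionSet:
    """One subject's inputs: a single reference, >= 1 follow-ups, ROIs.

    Images may be given as loaded :class:`ThermalImage` objects or file
    paths; ``rois`` maps region label to an :class:`ROIPolygon` (or a
    vertex-file path) drawn on the reference image.
    """

    subject_id: str
    reference: ThermalImage | str | Path
    followups: list
    rois: dict = field(default_factory=dict)
    geometry: CameraGeometry | None = None
    settings: RegistrationSettings = field(default_factory=RegistrationSettings)
    temp_threshold: float = DEFAULT_TEMP_THRESHOLD
    grad_threshold: float = DEFAULT_GRAD_THRESHOLD

    def __post_init__(self) -> None:
        if not self.followups:
            raise InputError(f"subject {self.subject_id}: needs >= 1 follow-up")


@dataclass
class SessionResult:
    subject_id: str
    stats: pd.DataFrame
    offsets: dict[str, TranslationOffset]
    models: dict[str, DeformationModel]
    traces: dict[str, ConvergenceTrace]
    converged: dict[str, bool]
    registered: dict[str, ThermalImage]
    log: list[str]
    errors: dict[str, str]


def _load_image(src, geometry, label):
    if isinstance(src, ThermalImage):
        return src
    return read_thermal(src, geometry, label=label)


def _load_roi(src) -> ROIPolygon:
    if isinstance(src, ROIPolygon):
        return src
    from .roi_tools import read_polygon

    return read_polygon(src)


def run_session(session: SessionSet) -> SessionResult:
    """Run one subject end to end; deterministic given the settings seed.

    Produces one statistics row per (image, ROI label): the reference
    itself plus every successfully registered follow-up with the
    transferred reference ROI.
    """
    log: list[str] = []
    errors: dict[str, str] = {}

    def note(msg: str) -> None:
        log.append(msg)

    reference = _load_image(session.reference, session.geometry, "reference")
    geometry = reference.geometry
    note(f"subject {session.subject_id}: settings {session.settings}")

    ref_landmark = detect_neck(
        segment_foreground(reference, session.temp_threshold, session.grad_threshold)
    )
    note(f"reference neck landmark: {ref_landmark}")

    masks = {
        label: polygon_to_mask(_load_roi(poly), reference.shape)
        for label, poly in session.rois.items()
    }

    rows = []
    for label, mask in masks.items():
        s = roi_stats(reference, mask)
        rows.append(
            {
                "subject": session.subject_id,
                "session": "reference",
                "roi": label,
                "mean_temp": s.mean_temp,
                "max_temp": s.max_temp,
                "n_pixels": s.n_pixels,
                "area_cm2": s.area_cm2,
            }
        )

    offsets: dict[str, TranslationOffset] = {}
    models: dict[str, DeformationModel] = {}
    traces: dict[str, ConvergenceTrace] = {}
    converged: dict[str, bool] = {}
    registered_images: dict[str, ThermalImage] = {}

    for i, src in enumerate(session.followups):
        name = f"follow-up {i + 1}"  # positional: labels may collide
        t0 = time.perf_counter()
        try:
            follow = _load_image(src, geometry, name)
            shifted, offset = prealign(
                follow, reference, session.temp_threshold, session.grad_threshold
            )
            offsets[name] = offset
            note(
                f"{name}: prealign offset ({offset.dx_px}, {offset.dy_px}) px = "
                f"({offset.dx_cm:.2f}, {offset.dy_cm:.2f}) cm"
            )

            # run contract: registration input carries the reference landmark
            shifted_landmark = detect_neck(
                segment_foreground(
                    shifted, session.temp_threshold, session.grad_threshold
                )
            )
            if (shifted_landmark.row, shifted_landmark.left_x) != (
                ref_landmark.row,
                ref_landmark.left_x,
            ):
                raise IRTError(
                    f"pre-aligned landmark {shifted_landmark} does not match "
                    f"reference {ref_landmark}"
                )

            per_follow = replace(
                session.settings, seed=session.settings.seed * 101 + i
            )
            model, trace = register(reference, shifted, per_follow)
            summary = check_convergence(trace)
            models[name] = model
            traces[name] = trace
            converged[name] = summary.converged
            note(
                f"{name}: registration converged={summary.converged} "
                f"(mean |dMI| {summary.mean_abs_delta:.2e}, "
                f"range {summary.trace_range:.2e})"
            )

            reg_img = resample_image(shifted, model)
            reg_img.label = name
            registered_images[name] = reg_img

            for label, (img, mask) in zip(
                masks, transfer_reference_roi_pairs(masks, reg_img)
            ):
                s = roi_stats(img, mask)
                rows.append(
                    {
                        "subject": session.subject_id,
                        "session": name,
                        "roi": label,
                        "mean_temp": s.mean_temp,
                        "max_temp": s.max_temp,
                        "n_pixels": s.n_pixels,
                        "area_cm2": s.area_cm2,
                    }
                )
            note(f"{name}: done in {time.perf_counter() - t0:.1f} s")
        except IRTError as exc:
            errors[name] = str(exc)
            note(f"{name}: FAILED ({exc}); continuing with remaining follow-ups")

    stats = pd.DataFrame(
        rows,
        columns=[
            "subject",
            "session",
            "roi",
            "mean_temp",
            "max_temp",
            "n_pixels",
            "area_cm2",
        ],
    )
    return SessionResult(
        subject_id=session.subject_id,
        stats=stats,
        offsets=offsets,
        models=models,
        traces=traces,
        converged=converged,
        registered=registered_images,
        log=log,
        errors=errors,
    )


def transfer_reference_roi_pairs(masks: dict, reg_img: ThermalImage):
    """Transfer every reference ROI to one registered follow-up image."""
    out = []
    for label, mask in masks.items():
        pairs = transfer_reference_roi(mask, [reg_img])
        out.append(pairs[0])
    return out


def run_batch(manifest: list[SessionSet]) -> dict:
    """Run many subjects; failures are isolated per subject.

    Returns ``{"stats": DataFrame, "results": {subject: SessionResult},
    "failures": {subject: message}}``.
    """
    if not manifest:
        raise InputError("empty manifest: nothing to run")
    results: dict[str, SessionResult] = {}
    failures: dict[str, str] = {}
    frames = []
    for session in manifest:
        try:
            res = run_session(session)
            results[session.subject_id] = res
            frames.append(res.stats)
        except IRTError as exc:
            failures[session.subject_id] = str(exc)
    stats = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "subject",
                "session",
                "roi",
                "mean_temp",
                "max_temp",
                "n_pixels",
                "area_cm2",
            ]
        )
    )
    return {"stats": stats, "results": results, "failures": failures}
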