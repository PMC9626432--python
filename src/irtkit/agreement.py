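"""Spatial and temperature agreement statistics.

Dice overlap with qualitative bins — [0, 0.5) poor, [0.5, 0.7) moderate,
[0.7, 0.9) good, >= 0.9 excellent (no rounding before binning) — and a
repeated-measures Bland–Altman analysis whose total SD combines
between-subject and within-subject variance components from a one-way
random-effects decomposition, so limits of agreement remain valid with
multiple paired observations per subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError, UndefinedDiceError
from .registration import DeformationModel, resample_mask
from .roi_tools import ROIMask

__all__ = [
    "DiceResult",
    "BlandAltmanResult",
    "dice",
    "dice_bin",
    "bland_altman_rm",
    "method_comparison",
    "summarize_dice",
]

_BINS = ((0.9, "excellent"), (0.7, "good"), (0.5, "moderate"), (0.0, "poor"))


def dice_bin(value: float) -> str:
    """Qualitative bin for a Dice value (half-open at the cut-points)."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"Dice value {value} outside [0, 1]")
    for cut, label in _BINS:
        if value >= cut:
            return label
    return "poor"


@dataclass(frozen=True)
class DiceResult:
    value: float
    bin: str


def dice(a: ROIMask, b: ROIMask) -> DiceResult:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two binary masks."""
    av = a.values.astype(bool)
    bv = b.values.astype(bool)
    if av.shape != bv.shape:
        raise InputError(f"mask shapes differ: {av.shape} vs {bv.shape}")
    na, nb = int(av.sum()), int(bv.sum())
    if na + nb == 0:
        raise UndefinedDiceError("Dice undefined: both masks are empty")
    value = 2.0 * int((av & bv).sum()) / (na + nb)
    return DiceResult(value=value, bin=dice_bin(value))


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    sd_total: float
    n_subjects: int
    n_obs: int


def bland_altman_rm(diffs: Sequence[Sequence[float]]) -> BlandAltmanResult:
    """Repeated-measures Bland–Altman bias and 95% limits of agreement.

    ``diffs`` holds one list of paired differences per subject.  The bias
    is the grand mean of all differences.  The total SD combines variance
    components of a one-way random-effects decomposition:

    * within-subject variance = pooled mean square within (MSW);
    * between-subject variance = max(0, (MSB - MSW) / m0) with
      ``m0 = (sum(m_i) - sum(m_i^2)/sum(m_i)) / (n - 1)`` for unbalanced
      group sizes ``m_i``.

    LoA = bias ± 1.96 · sqrt(between + within).  With one observation per
    subject this reduces exactly to the classical bias ± 1.96 · sample SD.
    """
    groups = [np.asarray(g, dtype=float) for g in diffs]
    n = len(groups)
    if n < 2:
        raise InputError("repeated-measures Bland–Altman needs >= 2 subjects")
    sizes = np.array([g.size for g in groups])
    if (sizes == 0).any():
        raise InputError("every subject needs >= 1 difference")

    all_d = np.concatenate(groups)
    total = int(sizes.sum())
    bias = float(all_d.mean())
    means = np.array([g.mean() for g in groups])

    within_df = total - n
    if within_df > 0:
        msw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups) / within_df
    else:
        msw = 0.0
    msb = float((sizes * (means - bias) ** 2).sum()) / (n - 1)
    m0 = (total - float((sizes**2).sum()) / total) / (n - 1)
    var_between = max(0.0, (msb - msw) / m0)
    sd_total = float(np.sqrt(var_between + msw))

    return BlandAltmanResult(
        bias=bias,
        loa_lower=bias - 1.96 * sd_total,
        loa_upper=bias + 1.96 * sd_total,
        sd_total=sd_total,
        n_subjects=n,
        n_obs=total,
    )


def method_comparison(
    reference_mask: ROIMask,
    manual_followup_masks: Sequence[ROIMask],
    models: Sequence[DeformationModel],
) -> list[DiceResult]:
    """Overlap of the reference ROI with registered manual follow-up ROIs.

    Each manually drawn follow-up mask is first warped into reference
    space by its session's deformation model (nearest-neighbour, so masks
    stay binary), then compared to the reference mask with Dice.
    """
    if len(manual_followup_masks) != len(models):
        raise InputError(
            f"{len(manual_followup_masks)} masks but {len(models)} models"
        )
    out = []
    for mask, model in zip(manual_followup_masks, models):
        warped = resample_mask(mask, model)
        out.append(dice(reference_mask, warped))
    return out


def summarize_dice(results: Sequence[DiceResult]) -> dict:
    """Mean and [min, max] range summary, plus display formatting."""
    if not results:
        raise InputError("no Dice results to summarize")
    vals = np.array([r.value for r in results])
    mean, lo, hi = float(vals.mean()), float(vals.min()), float(vals.max())
    return {
        "mean": mean,
        "min": lo,
        "max": hi,
        "formatted": f"Dice = {mean:.2f}, range: [{lo:.2f}–{hi:.2f}]",
    }
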