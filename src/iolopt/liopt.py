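"""Constant optimization by linear interpolation and per-case correction.

The calibration problem: a lens formula's predicted refraction shifts
approximately linearly with its A-constant.  Measuring the cohort mean
prediction error (MPE) at two constants ``x1 < x2`` gives two points
``(x1, y1)`` and ``(x2, y2)``; the straight line through them crosses
MPE = 0 at the optimized constant

    x_opt = x2 - y2 * (x2 - x1) / (y2 - y1).

Each eye's own pair of predictions is then interpolated along the same
line to ``x_opt`` (Method-LI), which zeroes the cohort MPE while letting
the correction vary per eye.  Method-S, the classic alternative, shifts
every prediction by the cohort MPE — exact zero mean, but a single
uniform shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, EyeCase


class ZeroSlopeError(ValueError):
    """The two anchor MPEs are equal and non-zero: the line never crosses 0."""


#: Warn when the root lies further than this many anchor gaps beyond the
#: nearest anchor — almost always a sign of implausible inputs.
EXTRAPOLATION_WARN_FACTOR = 2.0


@dataclass(frozen=True)
class AnchorPair:
    """Two (constant, MPE) calibration points; order is immaterial."""

    x1: float
    x2: float
    y1: float
    y2: float

    def __post_init__(self) -> None:
        if self.x1 == self.x2:
            raise ValueError("anchor constants must differ")


@dataclass(frozen=True)
class OptimizationResult:
    """Solved constant, the fitted MPE-vs-constant slope, and diagnostics."""

    x_opt: float
    slope_d_per_unit: float
    n: int
    extrapolated: bool
    note: str | None = None


@dataclass(frozen=True, eq=False)
class CorrectionSet:
    """Per-case corrected predictions and the resulting (absolute) errors."""

    method: str  # "method_s" | "method_li" | "actual"
    corrected_pred_d: np.ndarray
    pe_d: np.ndarray
    ape_d: np.ndarray

    @classmethod
    def build(cls, method: str, postop_se_d, corrected_pred_d) -> "CorrectionSet":
        corrected = np.asarray(corrected_pred_d, dtype=float)
        postop = np.asarray(postop_se_d, dtype=float)
        if corrected.shape != postop.shape:
            raise ValueError("postop and corrected prediction series must align")
        pe = postop - corrected
        return cls(method=method, corrected_pred_d=corrected, pe_d=pe,
                   ape_d=np.abs(pe))

    def __len__(self) -> int:
        return len(self.pe_d)


def prediction_errors(cohort: Cohort, predicted) -> np.ndarray:
    """PE_i = postoperative SE minus predicted refraction, case by case."""
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != (len(cohort),):
        raise ValueError(
            f"predicted series length {predicted.shape} does not match "
            f"cohort size {len(cohort)}"
        )
    return cohort.postop_se_d - predicted


def mean_prediction_error(pe) -> float:
    pe = np.asarray(pe, dtype=float)
    if pe.size == 0:
        raise ValueError("cannot take the MPE of an empty series")
    return float(np.mean(pe))


def optimize_constant(pair: AnchorPair, n: int = 0) -> OptimizationResult:
    """Solve the two-point line for the constant at which MPE = 0.

    The root is closed-form, so no tolerance is involved; the result is
    invariant to swapping the two anchor points.  A root outside the anchor
    interval is legitimate (flagged ``extrapolated``), but a root further
    than ``EXTRAPOLATION_WARN_FACTOR`` anchor gaps beyond the nearest anchor
    triggers a warning.
    """
    x1, x2, y1, y2 = pair.x1, pair.x2, pair.y1, pair.y2
    if y1 == y2:
        if y2 == 0.0:
            warnings.warn(
                "both anchor MPEs are exactly 0; every constant on the line is "
                "a root — returning x2",
                stacklevel=2,
            )
            return OptimizationResult(
                x_opt=x2, slope_d_per_unit=0.0, n=n, extrapolated=False,
                note="degenerate: y1 = y2 = 0",
            )
        raise ZeroSlopeError(
            f"anchor MPEs are equal ({y1} D) and non-zero: the interpolated "
            "line never crosses MPE = 0"
        )
    slope = (y2 - y1) / (x2 - x1)
    x_opt = x2 - y2 / slope
    lo, hi = min(x1, x2), max(x1, x2)
    extrapolated = not lo <= x_opt <= hi
    gap = hi - lo
    overshoot = max(lo - x_opt, x_opt - hi)
    note = None
    if overshoot > EXTRAPOLATION_WARN_FACTOR * gap:
        note = (
            f"x_opt lies {overshoot / gap:.1f} anchor gaps beyond the nearest "
            "anchor; check inputs"
        )
        warnings.warn(note, stacklevel=2)
    return OptimizationResult(
        x_opt=float(x_opt), slope_d_per_unit=float(slope), n=n,
        extrapolated=extrapolated, note=note,
    )


def interpolate_predictions(pred_lo, pred_hi, x: float, x1: float, x2: float):
    """Evaluate each eye's two-point prediction line at constant ``x``.

    y' = y2' + (y2' - y1')*(x - x2)/(x2 - x1), vectorized over cases.
    """
    if x1 == x2:
        raise ValueError("anchor constants must differ")
    pred_lo = np.asarray(pred_lo, dtype=float)
    pred_hi = np.asarray(pred_hi, dtype=float)
    return pred_hi + (pred_hi - pred_lo) * (x - x2) / (x2 - x1)


def correct_case_li(case: EyeCase, x_opt: float, x1: float, x2: float) -> float:
    """One eye's predicted refraction interpolated to the optimized constant."""
    return float(
        interpolate_predictions(case.pred_lo_d, case.pred_hi_d, x_opt, x1, x2)
    )


def anchor_pair_from_cohort(cohort: Cohort) -> AnchorPair:
    """Cohort MPE at each anchor constant, packaged as calibration points."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    postop = cohort.postop_se_d
    return AnchorPair(
        x1=cohort.anchor_lo,
        x2=cohort.anchor_hi,
        y1=float(np.mean(postop - cohort.pred_lo_d)),
        y2=float(np.mean(postop - cohort.pred_hi_d)),
    )


def correct_cohort_li(cohort: Cohort) -> tuple[OptimizationResult, CorrectionSet]:
    """Optimize the constant on a cohort and apply Method-LI per case.

    Because the cohort MPE of the interpolated predictions is itself linear
    in the constant, the corrected set satisfies mean(PE) = 0 exactly (to
    float round-off), the algebraic identity Method-LI is built on.
    """
    result = optimize_constant(anchor_pair_from_cohort(cohort), n=len(cohort))
    corrected = interpolate_predictions(
        cohort.pred_lo_d, cohort.pred_hi_d, result.x_opt,
        cohort.anchor_lo, cohort.anchor_hi,
    )
    return result, CorrectionSet.build("method_li", cohort.postop_se_d, corrected)


def correct_method_s(cohort: Cohort, reference: str = "anchor_hi") -> CorrectionSet:
    """Zero the cohort MPE by one uniform shift of the reference predictions.

    ``reference`` selects which anchor's predictions are shifted
    (default the higher anchor, the convention used when the higher constant
    is the manufacturer-recommended one).  Corrected PE = PE - MPE, so the
    mean corrected PE is 0 exactly and the PE dispersion is untouched.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if reference not in ("anchor_lo", "anchor_hi"):
        raise ValueError(f"reference must be 'anchor_lo' or 'anchor_hi', got {reference!r}")
    pred = cohort.pred_lo_d if reference == "anchor_lo" else cohort.pred_hi_d
    mpe = float(np.mean(cohort.postop_se_d - pred))
    return CorrectionSet.build("method_s", cohort.postop_se_d, pred + mpe)


def actual_correction(cohort: Cohort, predicted_at_x_opt) -> CorrectionSet:
    """Wrap predictions recomputed from scratch at the optimized constant.

    These "actual values" come from re-running the formula (here, the
    pseudo-formula oracle) at x_opt; unlike the two correction methods their
    mean PE is only approximately zero.
    """
    predicted = np.asarray(predicted_at_x_opt, dtype=float)
    if predicted.shape != (len(cohort),):
        raise ValueError("predicted series must align with cohort cases")
    return CorrectionSet.build("actual", cohort.postop_se_d, predicted)
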