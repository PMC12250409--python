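"""Accuracy summaries for one (device, formula, correction-method) cell.

The outcome set is the standard refractive-accuracy panel: mean prediction
error (MPE), mean and median absolute error (MAE, MedAE), the SD and
standard error of the absolute error, a 95% normal-approximation CI for the
MAE, and the fraction of eyes with absolute prediction error under 0.25 D
and 0.50 D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .liopt import CorrectionSet

#: Normal 95% multiplier used for the MAE confidence interval.
Z_95 = 1.96


@dataclass(frozen=True)
class AccuracySummary:
    n: int
    mpe_d: float
    mae_d: float
    sd_ape_d: float
    se_ape_d: float
    medae_d: float
    ci_lo_d: float
    ci_hi_d: float
    rate_025: float
    rate_05: float


def rate_within(ape, threshold: float, inclusive: bool = False) -> float:
    """Fraction of cases with APE under ``threshold`` (strict by default)."""
    ape = np.asarray(ape, dtype=float)
    if ape.size == 0:
        raise ValueError("cannot compute a rate over an empty series")
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    hits = ape <= threshold if inclusive else ape < threshold
    return float(np.count_nonzero(hits)) / ape.size


def summarize_accuracy(
    correction: CorrectionSet,
    thresholds: tuple[float, float] = (0.25, 0.5),
    inclusive_rates: bool = False,
) -> AccuracySummary:
    """Compute the full accuracy panel for one correction set.

    SD uses the n-1 sample denominator; the even-n median is the mean of the
    two central order statistics; the CI is MAE +/- 1.96 * SD/sqrt(n).
    ``thresholds`` must be two increasing diopter cutoffs and fill the
    ``rate_025`` / ``rate_05`` slots in order.
    """
    if len(correction) == 0:
        raise ValueError("cannot summarize an empty correction set")
    t_lo, t_hi = thresholds
    if not 0 < t_lo < t_hi:
        raise ValueError(f"thresholds must be increasing and positive: {thresholds}")
    ape = correction.ape_d
    n = ape.size
    mae = float(np.mean(ape))
    sd = float(np.std(ape, ddof=1)) if n > 1 else float("nan")
    se = sd / math.sqrt(n) if n > 1 else float("nan")
    half = Z_95 * se if n > 1 else float("nan")
    return AccuracySummary(
        n=n,
        mpe_d=float(np.mean(correction.pe_d)),
        mae_d=mae,
        sd_ape_d=sd,
        se_ape_d=se,
        medae_d=float(np.median(ape)),
        ci_lo_d=mae - half,
        ci_hi_d=mae + half,
        rate_025=rate_within(ape, t_lo, inclusive_rates),
        rate_05=rate_within(ape, t_hi, inclusive_rates),
    )
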