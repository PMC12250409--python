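"""Presentation-layer rendering of constants and accuracy tables.

All arithmetic upstream is full precision; rounding happens only here, with
half-up decimal rounding (119.53989 prints as 119.540).  Constants print to
3 decimals, refraction statistics to 3, standard errors to 4, and rates as
percentages to 1.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .compare import MethodComparison
from .liopt import AnchorPair, OptimizationResult
from .metrics import AccuracySummary


def round_half_up(x: float, digits: int) -> float:
    """Decimal half-up rounding (ties away from zero on the printed digit)."""
    if digits < 0:
        raise ValueError("digits must be >= 0")
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt(x: float, digits: int) -> str:
    """Fixed-point half-up formatting with trailing zeros kept."""
    if x != x:  # NaN
        return "NaN"
    q = Decimal(1).scaleb(-digits)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def constants_frame(
    rows: Sequence[tuple[str, str, AnchorPair, OptimizationResult]],
) -> pd.DataFrame:
    """One row per (device, formula) cell, mirroring a constants summary table."""
    records = []
    for device, formula, pair, res in rows:
        records.append({
            "device": device,
            "formula": formula,
            "n": res.n,
            "anchor_lo": pair.x1,
            "anchor_hi": pair.x2,
            "mpe_lo_d": fmt(pair.y1, 4),
            "mpe_hi_d": fmt(pair.y2, 4),
            "optimized_constant": fmt(res.x_opt, 3),
            "slope_d_per_unit": fmt(res.slope_d_per_unit, 4),
            "extrapolated": res.extrapolated,
        })
    return pd.DataFrame.from_records(records)


def accuracy_frame(
    rows: Sequence[tuple[str, str, str, str, AccuracySummary]],
) -> pd.DataFrame:
    """One row per (device, formula, subgroup, method) accuracy cell."""
    records = []
    for device, formula, subgroup, method, s in rows:
        records.append({
            "device": device,
            "formula": formula,
            "subgroup": subgroup,
            "method": method,
            "n": s.n,
            "mpe_d": fmt(s.mpe_d, 4),
            "mae_d": fmt(s.mae_d, 3),
            "sd_ape_d": fmt(s.sd_ape_d, 3),
            "se_ape_d": fmt(s.se_ape_d, 4),
            "medae_d": fmt(s.medae_d, 3),
            "ci95": f"{fmt(s.ci_lo_d, 3)}-{fmt(s.ci_hi_d, 3)}",
            "rate_lt_025_pct": fmt(100.0 * s.rate_025, 1),
            "rate_lt_05_pct": fmt(100.0 * s.rate_05, 1),
        })
    return pd.DataFrame.from_records(records)


def comparison_frame(
    rows: Sequence[tuple[str, str, str, MethodComparison]],
) -> pd.DataFrame:
    """Machine-readable comparison report: gate, omnibus, post hoc triples."""
    records = []
    for device, formula, subgroup, comp in rows:
        blocks = [("mae", comp.mae)] + [
            (f"rate_lt_{thr}", res) for thr, res in comp.rates.items()
        ]
        for outcome, res in blocks:
            posthoc = "; ".join(
                f"{a} vs {b}: p={fmt(pr.p_raw, 4)} adj={fmt(pr.p_adjusted, 4)}"
                for (a, b), pr in ((p.pair, p) for p in res.posthoc)
            )
            records.append({
                "device": device,
                "formula": formula,
                "subgroup": subgroup,
                "outcome": outcome,
                "all_normal": comp.all_normal,
                "test": res.test,
                "statistic": fmt(res.statistic, 4) if res.statistic == res.statistic else "NaN",
                "df": "x".join(str(d) for d in res.df),
                "p_value": fmt(res.p_value, 4),
                "posthoc": posthoc,
            })
    return pd.DataFrame.from_records(records)


def frame_to_markdown(df: pd.DataFrame) -> str:
    """Render a DataFrame as a GitHub-style pipe table (values pre-formatted)."""
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"
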