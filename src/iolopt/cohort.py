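"""Cohort data model, CSV I/O, eligibility filtering and axial-length strata.

A :class:`Cohort` is an ordered collection of :class:`EyeCase` records, one
per eye, together with the pair of anchor A-constants at which predicted
refractions were computed.  The long CSV format (one row per
eye x device x formula) lets a single file drive every device-formula cell
of a constant-optimization study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import pandas as pd


class CohortSchemaError(ValueError):
    """The CSV header does not name a required column."""


class CohortRowError(ValueError):
    """A row holds a value that cannot be parsed for its column."""


_NUMERIC_COLUMNS = ("al_mm", "cva_logmar", "postop_se_d", "pred_lo_d", "pred_hi_d")

#: Canonical CSV header.  Extra columns are ignored on read but preserved.
REQUIRED_COLUMNS = ("patient_id", "eye", "device", "formula") + _NUMERIC_COLUMNS

_EYE_ALIASES = {"right": "right", "left": "left", "od": "right", "os": "left",
                "r": "right", "l": "left"}


@dataclass(frozen=True)
class EyeCase:
    """One eye's postoperative outcome and its paired predictions.

    ``pred_lo_d`` / ``pred_hi_d`` are the predicted spherical-equivalent
    refractions (D) produced by the formula at the lower / higher anchor
    constant.  ``postop_se_d`` is the measured postoperative spherical
    equivalent.  ``cva_logmar`` is corrected visual acuity in logMAR
    (20/40 = 0.30).
    """

    patient_id: str
    eye: str  # "right" | "left"
    device: str
    formula: str
    al_mm: float
    cva_logmar: float
    postop_se_d: float
    pred_lo_d: float
    pred_hi_d: float
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.eye not in ("right", "left"):
            raise ValueError(f"eye must be 'right' or 'left', got {self.eye!r}")
        if not 15.0 < self.al_mm < 40.0:
            raise ValueError(f"al_mm out of plausible range (15, 40): {self.al_mm}")
        if not -0.5 <= self.cva_logmar <= 4.0:
            raise ValueError(f"cva_logmar out of range [-0.5, 4]: {self.cva_logmar}")
        for name in ("postop_se_d", "pred_lo_d", "pred_hi_d"):
            v = getattr(self, name)
            if not -30.0 < v < 30.0:
                raise ValueError(f"{name} out of range (-30, 30) D: {v}")


@dataclass(frozen=True)
class Cohort:
    """Ordered eye cases sharing one (anchor_lo, anchor_hi) constant pair."""

    cases: tuple[EyeCase, ...]
    anchor_lo: float
    anchor_hi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "cases", tuple(self.cases))
        if not self.anchor_lo < self.anchor_hi:
            raise ValueError(
                f"anchor_lo must be < anchor_hi, got {self.anchor_lo} >= {self.anchor_hi}"
            )

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self) -> Iterator[EyeCase]:
        return iter(self.cases)

    def column(self, name: str):
        """Return one numeric field across cases as a numpy array."""
        import numpy as np

        return np.array([getattr(c, name) for c in self.cases], dtype=float)

    @property
    def postop_se_d(self):
        return self.column("postop_se_d")

    @property
    def pred_lo_d(self):
        return self.column("pred_lo_d")

    @property
    def pred_hi_d(self):
        return self.column("pred_hi_d")

    @property
    def al_mm(self):
        return self.column("al_mm")

    def with_cases(self, cases) -> "Cohort":
        return replace(self, cases=tuple(cases))

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with the canonical columns, extras appended."""
        rows = []
        extra_order: list[str] = []
        for c in self.cases:
            row = {k: getattr(c, k) for k in REQUIRED_COLUMNS}
            for k, v in c.extra:
                row[k] = v
                if k not in extra_order:
                    extra_order.append(k)
            rows.append(row)
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + extra_order)


@dataclass(frozen=True)
class StudyFilters:
    """Eligibility filters and axial-length subgroup cutoffs.

    cva_logmar_max: worst admissible corrected visual acuity (0.30 = 20/40),
        inclusive.
    one_eye_per_patient: keep only the better-seeing eligible eye per patient
        (fellow eyes are correlated and must not be treated as independent).
    al_short_max_mm / al_long_min_mm: strict cutoffs for the short
        (AL < 22.5 mm) and long (AL > 25.5 mm) subgroups.
    """

    cva_logmar_max: float = 0.30
    one_eye_per_patient: bool = True
    al_short_max_mm: float = 22.5
    al_long_min_mm: float = 25.5

    def __post_init__(self) -> None:
        if not self.al_short_max_mm < self.al_long_min_mm:
            raise ValueError("al_short_max_mm must be < al_long_min_mm")


def _normalize_eye(raw: object, row: int) -> str:
    key = str(raw).strip().lower()
    if key not in _EYE_ALIASES:
        raise CohortRowError(f"row {row}: unrecognized eye label {raw!r}")
    return _EYE_ALIASES[key]


def read_cohort_csv(path, anchor_lo: float, anchor_hi: float) -> Cohort:
    """Read a long-format cohort CSV (UTF-8, comma separated, dot decimals).

    Lines starting with ``#`` are treated as comments.  Extra columns are
    carried through unchanged and re-emitted by :func:`write_cohort_csv`.
    """
    if anchor_lo >= anchor_hi:
        raise ValueError(f"anchor_lo must be < anchor_hi, got {anchor_lo}, {anchor_hi}")
    df = pd.read_csv(path, dtype=str, comment="#", skipinitialspace=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError("missing required column(s): " + ", ".join(missing))
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]

    cases = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        numeric = {}
        for col in _NUMERIC_COLUMNS:
            raw = rec[col]
            if raw is None or pd.isna(raw):
                raise CohortRowError(f"row {i}: column {col!r} is missing")
            try:
                numeric[col] = float(raw)
            except ValueError:
                raise CohortRowError(
                    f"row {i}: column {col!r} is not numeric: {raw!r}"
                ) from None
        try:
            case = EyeCase(
                patient_id=str(rec["patient_id"]),
                eye=_normalize_eye(rec["eye"], i),
                device=str(rec["device"]),
                formula=str(rec["formula"]),
                extra=tuple(
                    (c, "" if pd.isna(rec[c]) else str(rec[c])) for c in extra_cols
                ),
                **numeric,
            )
        except ValueError as exc:
            if isinstance(exc, CohortRowError):
                raise
            raise CohortRowError(f"row {i}: {exc}") from None
        cases.append(case)
    return Cohort(tuple(cases), anchor_lo, anchor_hi)


def write_cohort_csv(cohort: Cohort, path, header_comment: str | None = None) -> None:
    """Write the cohort back to CSV; floats keep full precision (round-trip safe)."""
    df = cohort.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def _eye_rank(case: EyeCase) -> tuple[float, int]:
    # better (lower) CVA first; on an exact tie the right eye wins
    return (case.cva_logmar, 0 if case.eye == "right" else 1)


def select_study_eyes(cohort: Cohort, filters: StudyFilters | None = None) -> Cohort:
    """Apply the eligibility protocol: CVA cutoff, then one eye per patient.

    When both of a patient's eyes qualify, the eye with the better (lower)
    logMAR CVA is retained; an exact tie retains the right eye.  Idempotent.
    """
    filters = filters or StudyFilters()
    eligible = [
        (i, c) for i, c in enumerate(cohort.cases)
        if c.cva_logmar <= filters.cva_logmar_max
    ]
    if filters.one_eye_per_patient:
        best: dict[str, tuple[int, EyeCase]] = {}
        for i, c in eligible:
            cur = best.get(c.patient_id)
            if cur is None or _eye_rank(c) < _eye_rank(cur[1]):
                best[c.patient_id] = (i, c)
        eligible = sorted(best.values())
    return cohort.with_cases(c for _, c in eligible)


def stratify_by_al(
    cohort: Cohort, filters: StudyFilters | None = None
) -> Mapping[str, Cohort]:
    """Split into short / all / long axial-length strata (strict cutoffs).

    An eye with AL exactly at a cutoff belongs to neither extreme stratum;
    ``all`` is the unmodified input.
    """
    filters = filters or StudyFilters()
    short = cohort.with_cases(
        c for c in cohort.cases if c.al_mm < filters.al_short_max_mm
    )
    long = cohort.with_cases(
        c for c in cohort.cases if c.al_mm > filters.al_long_min_mm
    )
    return {"short": short, "all": cohort, "long": long}
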