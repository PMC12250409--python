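"""Repeated-measures comparison of correction methods and formulas.

Each eye contributes one value (its absolute prediction error, or a 0/1
success indicator) under each of k conditions — the classic complete-case
repeated-measures layout.  The analysis plan is normality-gated: Shapiro-Wilk
per condition; if every condition looks normal the MAE is compared by
one-way repeated-measures ANOVA with paired-t post hoc, otherwise by the
Friedman test with Durbin-Conover post hoc.  Binary success rates are
compared by Cochran's Q with McNemar post hoc.  Post hoc p-values are
Bonferroni-adjusted over the pairs actually tested.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .liopt import CorrectionSet

_EPS = 1e-12


@dataclass(frozen=True, eq=False)
class PairedMatrix:
    """n subjects x k conditions, complete cases only."""

    values: np.ndarray
    subject_ids: tuple = ()
    condition_labels: tuple = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (subjects x conditions) array")
        if np.isnan(values).any():
            raise ValueError("repeated-measures matrix must be complete (no NaN)")
        object.__setattr__(self, "values", values)
        n, k = values.shape
        if not self.subject_ids:
            object.__setattr__(self, "subject_ids", tuple(range(n)))
        if not self.condition_labels:
            object.__setattr__(self, "condition_labels",
                               tuple(f"cond{j}" for j in range(k)))
        if len(self.subject_ids) != n or len(self.condition_labels) != k:
            raise ValueError("identifier lengths must match the matrix shape")

    @classmethod
    def from_columns(cls, columns: Mapping[str, Sequence[float]],
                     subject_ids: Sequence | None = None) -> "PairedMatrix":
        labels = tuple(columns)
        values = np.column_stack([np.asarray(columns[c], dtype=float) for c in labels])
        return cls(values, tuple(subject_ids or ()), labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())


@dataclass(frozen=True)
class PairwiseResult:
    """One post hoc pair: raw and Bonferroni-adjusted two-sided p."""

    pair: tuple[str, str]
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    posthoc: tuple[PairwiseResult, ...] = ()
    note: str | None = None


@dataclass(frozen=True)
class NormalityGate:
    normal: bool
    w: float
    p: float


@dataclass(frozen=True)
class MethodComparison:
    """Full per-cell comparison: gate outcomes, MAE omnibus, rate omnibuses."""

    condition_labels: tuple[str, ...]
    normality: Mapping[str, NormalityGate]
    all_normal: bool
    mae: ComparisonResult
    rates: Mapping[float, ComparisonResult]


def bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def shapiro_wilk_gate(values, alpha: float = 0.05) -> NormalityGate:
    """Shapiro-Wilk normality check; ``normal`` means p >= alpha.

    Delegates the W statistic and p-value to the standard routine; a
    constant series has no defined W and raises.
    """
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={values.size}")
    if np.ptp(values) == 0:
        raise ValueError("Shapiro-Wilk W is undefined for a constant series")
    w, p = stats.shapiro(values)
    return NormalityGate(normal=bool(p >= alpha), w=float(w), p=float(p))


def _row_ranks(values: np.ndarray) -> np.ndarray:
    # midranks within each subject's row
    return np.apply_along_axis(stats.rankdata, 1, values)


def friedman_test(m: PairedMatrix) -> ComparisonResult:
    """Friedman rank test across k conditions, midranks with tie correction.

    Uses the tie-corrected form Q = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (A - C)
    with A the sum of squared ranks and C = n k (k+1)^2 / 4; referred to a
    chi-square with k-1 df.  Rows that are entirely tied contribute nothing;
    if every row is fully tied, Q = 0 and p = 1.
    """
    if m.k < 2 or m.n < 2:
        raise ValueError("Friedman test needs at least 2 subjects and 2 conditions")
    ranks = _row_ranks(m.values)
    n, k = m.n, m.k
    rj = ranks.sum(axis=0)
    a = float((ranks ** 2).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    if a - c <= _EPS:
        return ComparisonResult("friedman", 0.0, (k - 1,), 1.0,
                                note="all rows fully tied")
    q = (k - 1) * float(((rj - n * (k + 1) / 2.0) ** 2).sum()) / (a - c)
    p = float(stats.chi2.sf(q, k - 1))
    return ComparisonResult("friedman", q, (k - 1,), p)


def rm_anova(m: PairedMatrix) -> ComparisonResult:
    """One-way within-subject ANOVA: F = MS_condition / MS_error.

    Sums of squares decompose total variation into condition, subject and
    error parts; df = (k-1, (n-1)(k-1)).  Zero error variance with a real
    condition effect is flagged as an infinite F with p = 0.
    """
    if m.k < 2 or m.n < 2:
        raise ValueError("RM-ANOVA needs at least 2 subjects and 2 conditions")
    x = m.values
    n, k = m.n, m.k
    grand = x.mean()
    ss_cond = n * float(((x.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((x.mean(axis=1) - grand) ** 2).sum())
    ss_tot = float(((x - grand) ** 2).sum())
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    scale = max(ss_tot, 1.0)
    if ss_err <= _EPS * scale:
        if ss_cond <= _EPS * scale:
            return ComparisonResult("rm_anova", 0.0, (df1, df2), 1.0,
                                    note="no variation beyond subjects")
        return ComparisonResult("rm_anova", float("inf"), (df1, df2), 0.0,
                                note="zero error variance: infinite F")
    f = (ss_cond / df1) / (ss_err / df2)
    return ComparisonResult("rm_anova", float(f), (df1, df2),
                            float(stats.f.sf(f, df1, df2)))


def cochran_q_test(m: PairedMatrix) -> ComparisonResult:
    """Cochran's Q for k paired binary outcomes, chi-square with k-1 df.

    Q = (k-1) [k * sum C_j^2 - N^2] / (k N - sum R_i^2) with column totals
    C_j, row totals R_i and grand total N.  Rows with all-equal values are
    retained (they cancel); if every row is constant the statistic is
    degenerate and reported as Q = 0, p = 1.
    """
    if m.k < 2:
        raise ValueError("Cochran's Q needs at least 2 conditions")
    if not m.is_binary():
        raise ValueError("Cochran's Q requires a 0/1 success matrix")
    x = m.values
    k = m.k
    cj = x.sum(axis=0)
    ri = x.sum(axis=1)
    n_total = float(x.sum())
    denom = k * n_total - float((ri ** 2).sum())
    if denom <= _EPS:
        return ComparisonResult("cochran_q", 0.0, (k - 1,), 1.0,
                                note="every row constant: Q degenerate")
    q = (k - 1) * (k * float((cj ** 2).sum()) - n_total ** 2) / denom
    return ComparisonResult("cochran_q", float(q), (k - 1,),
                            float(stats.chi2.sf(q, k - 1)))


def mcnemar_test(x, y, method: str = "chi2") -> ComparisonResult:
    """McNemar's test on two aligned 0/1 series.

    ``chi2`` (default): the uncorrected statistic (b-c)^2/(b+c) on one df.
    ``exact``: two-sided binomial, p = min(1, 2 P(X <= min(b,c) | b+c, 1/2)) —
    preferable when the discordant count b+c is small (< ~25).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("series must be aligned and non-empty")
    if not (np.isin(x, (0.0, 1.0)).all() and np.isin(y, (0.0, 1.0)).all()):
        raise ValueError("McNemar requires 0/1 series")
    b = int(np.count_nonzero((x == 1) & (y == 0)))
    c = int(np.count_nonzero((x == 0) & (y == 1)))
    if b + c == 0:
        return ComparisonResult("mcnemar", 0.0, (1,), 1.0,
                                note="no discordant pairs")
    stat = (b - c) ** 2 / (b + c)
    if method == "chi2":
        p = float(stats.chi2.sf(stat, 1))
    elif method == "exact":
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), b + c, 0.5)))
    else:
        raise ValueError(f"method must be 'chi2' or 'exact', got {method!r}")
    return ComparisonResult("mcnemar", float(stat), (1,), p,
                            note=f"b={b}, c={c}, method={method}")


def durbin_conover_posthoc(
    m: PairedMatrix, adjust_m: int | None = None
) -> list[PairwiseResult]:
    """All-pairs rank comparison following a Friedman test.

    With within-row rank sums R_j, A the sum of all squared ranks and
    B = (1/n) sum_j R_j^2, the pairwise statistic is

        t = (R_j - R_l) / sqrt(2 n (A - B) / ((n-1)(k-1)))

    on (n-1)(k-1) df, two-sided, Bonferroni-adjusted over the k(k-1)/2
    pairs.  A = B happens both when every row is fully tied (all pairs
    p = 1) and when rankings are perfectly consistent across subjects, in
    which case any pair with unequal rank sums is maximally separated
    (p = 0).
    """
    ranks = _row_ranks(m.values)
    n, k = m.n, m.k
    if n < 2 or k < 2:
        raise ValueError("post hoc needs at least 2 subjects and 2 conditions")
    rj = ranks.sum(axis=0)
    a = float((ranks ** 2).sum())
    b = float((rj ** 2).sum()) / n
    df = (n - 1) * (k - 1)
    pairs = list(itertools.combinations(range(k), 2))
    m_adj = adjust_m if adjust_m is not None else len(pairs)
    var2 = 2.0 * n * (a - b) / df
    out = []
    for j, l in pairs:
        diff = float(rj[j] - rj[l])
        label = (m.condition_labels[j], m.condition_labels[l])
        if var2 <= _EPS:
            if abs(diff) <= _EPS:
                t, p = 0.0, 1.0
            else:  # perfectly consistent rankings: separation is maximal
                t, p = math.copysign(float("inf"), diff), 0.0
        else:
            t = diff / math.sqrt(var2)
            p = float(2.0 * stats.t.sf(abs(t), df))
        out.append(PairwiseResult(label, t, df, p, bonferroni(p, m_adj)))
    return out


def _paired_t_posthoc(m: PairedMatrix, adjust_m: int) -> list[PairwiseResult]:
    out = []
    df = m.n - 1
    for j, l in itertools.combinations(range(m.k), 2):
        d = m.values[:, j] - m.values[:, l]
        if np.ptp(d) == 0 and abs(d.mean()) <= _EPS:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(m.values[:, j], m.values[:, l])
            t, p = float(t), float(p)
        out.append(PairwiseResult(
            (m.condition_labels[j], m.condition_labels[l]), t, df, p,
            bonferroni(p, adjust_m),
        ))
    return out


def _mcnemar_posthoc(m: PairedMatrix, adjust_m: int,
                     method: str = "chi2") -> list[PairwiseResult]:
    out = []
    for j, l in itertools.combinations(range(m.k), 2):
        r = mcnemar_test(m.values[:, j], m.values[:, l], method=method)
        out.append(PairwiseResult(
            (m.condition_labels[j], m.condition_labels[l]),
            r.statistic, r.df[0], r.p_value, bonferroni(r.p_value, adjust_m),
        ))
    return out


def compare_methods(
    cells: Mapping[str, CorrectionSet],
    alpha: float = 0.05,
    thresholds: tuple[float, float] = (0.25, 0.5),
    inclusive_rates: bool = False,
    decimals: int | None = 9,
) -> MethodComparison:
    """Run the full normality-gated comparison across aligned correction sets.

    ``cells`` maps a condition label (a correction method, or a formula) to
    its CorrectionSet over the same eyes in the same order.  MAE is compared
    by RM-ANOVA (all cells normal per Shapiro-Wilk at ``alpha``) or the
    Friedman test otherwise; the APE-threshold success rates by Cochran's Q.
    Post hoc pairs run only when the omnibus p < alpha.

    APE values are rounded to ``decimals`` places (default 9, far below
    clinical resolution) before testing, so corrections that agree up to
    float round-off are ranked as exact ties rather than spurious wins;
    pass ``None`` to disable.
    """
    if len(cells) < 2:
        raise ValueError("need at least two correction sets to compare")
    labels = tuple(cells)
    sizes = {len(cells[lab]) for lab in labels}
    if len(sizes) != 1:
        raise ValueError("correction sets are misaligned (different case counts)")
    columns = {lab: cells[lab].ape_d for lab in labels}
    if decimals is not None:
        columns = {lab: np.round(v, decimals) for lab, v in columns.items()}
    ape = PairedMatrix.from_columns(columns)

    gates: dict[str, NormalityGate] = {}
    for j, lab in enumerate(labels):
        try:
            gates[lab] = shapiro_wilk_gate(ape.values[:, j], alpha=alpha)
        except ValueError:
            # constant APE column: treat as non-normal and fall through to ranks
            gates[lab] = NormalityGate(normal=False, w=float("nan"), p=float("nan"))
    all_normal = all(g.normal for g in gates.values())

    n_pairs = len(labels) * (len(labels) - 1) // 2
    if all_normal:
        omnibus = rm_anova(ape)
        if omnibus.p_value < alpha:
            omnibus = ComparisonResult(
                omnibus.test, omnibus.statistic, omnibus.df, omnibus.p_value,
                tuple(_paired_t_posthoc(ape, n_pairs)), omnibus.note,
            )
    else:
        omnibus = friedman_test(ape)
        if omnibus.p_value < alpha:
            omnibus = ComparisonResult(
                omnibus.test, omnibus.statistic, omnibus.df, omnibus.p_value,
                tuple(durbin_conover_posthoc(ape, n_pairs)), omnibus.note,
            )

    rates: dict[float, ComparisonResult] = {}
    for thr in thresholds:
        hits = (ape.values <= thr) if inclusive_rates else (ape.values < thr)
        binary = PairedMatrix(hits.astype(float), ape.subject_ids, labels)
        res = cochran_q_test(binary)
        if res.p_value < alpha:
            res = ComparisonResult(
                res.test, res.statistic, res.df, res.p_value,
                tuple(_mcnemar_posthoc(binary, n_pairs)), res.note,
            )
        rates[thr] = res

    return MethodComparison(
        condition_labels=labels, normality=gates, all_normal=all_normal,
        mae=omnibus, rates=rates,
    )
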