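"""Synthetic refraction cohorts with a known per-eye prediction law.

Real constant-optimization studies rely on proprietary formulas served
through web calculators, so no ground truth is available.  This module
replaces the formula with a transparent pseudo-formula: each eye's
predicted refraction is affine (optionally mildly quadratic) in the lens
constant,

    f_i(x) = b_i + s_i (x - x_ref) + c_i (x - x_ref)^2,

with negative per-eye slopes s_i (raising the constant makes the predicted
refraction more myopic).  The postoperative refraction is f_i(x_true) plus
Gaussian noise, so the constant x_true is the exact calibration target and
``f_i`` evaluated at any constant is the "actual value" oracle.  Optional
2-decimal quantization of emitted predictions emulates web-calculator
output precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .cohort import Cohort, EyeCase
from .liopt import correct_cohort_li


@dataclass(frozen=True, eq=False)
class PseudoFormula:
    """Per-eye affine/quadratic prediction law and the 2-dp emission flag."""

    x_ref: float
    intercept_d: np.ndarray
    slope_d_per_unit: np.ndarray
    curvature_d_per_unit2: np.ndarray | None = None
    quantize_2dp: bool = False

    def __post_init__(self) -> None:
        b = np.asarray(self.intercept_d, dtype=float)
        s = np.asarray(self.slope_d_per_unit, dtype=float)
        c = (np.zeros_like(b) if self.curvature_d_per_unit2 is None
             else np.asarray(self.curvature_d_per_unit2, dtype=float))
        if not (b.shape == s.shape == c.shape):
            raise ValueError("intercept, slope and curvature arrays must align")
        if not (s < 0).all():
            raise ValueError("per-eye slopes must be negative "
                             "(higher constant => more myopic prediction)")
        object.__setattr__(self, "intercept_d", b)
        object.__setattr__(self, "slope_d_per_unit", s)
        object.__setattr__(self, "curvature_d_per_unit2", c)

    @property
    def n_eyes(self) -> int:
        return self.intercept_d.size

    def evaluate(self, x: float, quantize: bool | None = None) -> np.ndarray:
        """All eyes' predictions at constant ``x`` (2-dp rounded if flagged)."""
        dx = x - self.x_ref
        out = (self.intercept_d + self.slope_d_per_unit * dx
               + self.curvature_d_per_unit2 * dx * dx)
        q = self.quantize_2dp if quantize is None else quantize
        return np.round(out, 2) if q else out


def evaluate_formula_at(formula: PseudoFormula, index: int, x: float) -> float:
    """One eye's prediction at constant ``x`` — the "actual value" for that eye."""
    if not 0 <= index < formula.n_eyes:
        raise IndexError(f"eye index {index} out of range [0, {formula.n_eyes})")
    return float(formula.evaluate(x)[index])


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults emulate a 188-eye biometry cohort.

    Axial length is truncated-normal 23.8 +/- 1.35 mm on [20, 30]; per-eye
    slopes are uniform on [-0.85, -0.65] D per constant unit; postoperative
    noise SD is 0.30 D; anchors are 119.1 and 119.33 and the true zero-MPE
    constant is 119.5.  ``curvature_d_per_unit2`` > 0 bends the prediction
    law for eyes outside the [22.5, 25.5] mm AL band, mimicking the way
    uniform-shift corrections fail in short and long eyes.
    """

    n_eyes: int = 188
    x_true: float = 119.5
    anchor_lo: float = 119.1
    anchor_hi: float = 119.33
    al_mean_mm: float = 23.8
    al_sd_mm: float = 1.35
    al_min_mm: float = 20.0
    al_max_mm: float = 30.0
    slope_lo: float = -0.85
    slope_hi: float = -0.65
    curvature_d_per_unit2: float = 0.0
    noise_sd_d: float = 0.30
    quantize_2dp: bool = False
    seed: int = 0
    device: str = "SIM-DEV"
    formula: str = "pseudo"

    def __post_init__(self) -> None:
        if self.n_eyes < 2:
            raise ValueError("n_eyes must be >= 2")
        if self.noise_sd_d < 0:
            raise ValueError("noise_sd_d must be >= 0")
        if not self.anchor_lo < self.anchor_hi:
            raise ValueError("anchor_lo must be < anchor_hi")
        if not self.slope_lo <= self.slope_hi < 0:
            raise ValueError("slope range must satisfy slope_lo <= slope_hi < 0")
        if not self.al_min_mm < self.al_mean_mm < self.al_max_mm:
            raise ValueError("AL truncation bounds must bracket the mean")


def simulate_cohort(config: SyntheticConfig) -> tuple[Cohort, PseudoFormula]:
    """Draw a cohort and return it with its generating pseudo-formula.

    Deterministic for a given seed.  Intercepts are set so each eye's
    prediction at ``x_true`` sits in a realistic refraction band
    (target ~ N(-0.25, 0.25) D clipped to [-1.8, 0.8]); the postoperative
    SE is the exact (unquantized) prediction at ``x_true`` plus noise.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_eyes
    a = (config.al_min_mm - config.al_mean_mm) / config.al_sd_mm
    b = (config.al_max_mm - config.al_mean_mm) / config.al_sd_mm
    al = stats.truncnorm.rvs(a, b, loc=config.al_mean_mm, scale=config.al_sd_mm,
                             size=n, random_state=rng)
    slopes = rng.uniform(config.slope_lo, config.slope_hi, size=n)
    extreme = (al < 22.5) | (al > 25.5)
    curv = np.where(extreme, config.curvature_d_per_unit2, 0.0)

    x_ref = config.anchor_lo
    dx_true = config.x_true - x_ref
    target = np.clip(rng.normal(-0.25, 0.25, size=n), -1.8, 0.8)
    intercept = target - slopes * dx_true - curv * dx_true * dx_true
    formula = PseudoFormula(x_ref=x_ref, intercept_d=intercept,
                            slope_d_per_unit=slopes,
                            curvature_d_per_unit2=curv,
                            quantize_2dp=config.quantize_2dp)

    pred_lo = formula.evaluate(config.anchor_lo)
    pred_hi = formula.evaluate(config.anchor_hi)
    postop = formula.evaluate(config.x_true, quantize=False) \
        + rng.normal(0.0, config.noise_sd_d, size=n)
    cva = np.round(rng.uniform(0.0, 0.2, size=n), 2)
    eyes = np.where(rng.random(n) < 0.5, "right", "left")

    cases = tuple(
        EyeCase(
            patient_id=f"P{i:04d}", eye=str(eyes[i]), device=config.device,
            formula=config.formula, al_mm=float(al[i]),
            cva_logmar=float(cva[i]), postop_se_d=float(postop[i]),
            pred_lo_d=float(pred_lo[i]), pred_hi_d=float(pred_hi[i]),
        )
        for i in range(n)
    )
    return Cohort(cases, config.anchor_lo, config.anchor_hi), formula


@dataclass(frozen=True)
class RecoveryResult:
    """Monte-Carlo summary of how well the calibration recovers x_true."""

    bias_x_opt: float
    sd_x_opt: float
    mean_abs_li_minus_actual_d: float
    x_opts: tuple[float, ...]
    actual_mpes_d: tuple[float, ...]
    n_eyes: int
    replicates: int


def recovery_experiment(config: SyntheticConfig, replicates: int) -> RecoveryResult:
    """Repeatedly simulate, calibrate, and score against the formula oracle.

    Per replicate: draw a cohort, solve for the optimized constant, apply the
    per-case interpolation correction, then re-evaluate the pseudo-formula at
    the optimized constant ("actual values").  Reports the bias and SD of the
    recovered constant, the mean per-case |corrected - actual| discrepancy,
    and each replicate's actual-value MPE.  Child seeds are spawned
    deterministically from ``config.seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(replicates)
    x_opts, discrepancies, actual_mpes = [], [], []
    for child in children:
        seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        cohort, formula = simulate_cohort(replace(config, seed=seed))
        result, li = correct_cohort_li(cohort)
        actual = formula.evaluate(result.x_opt)
        x_opts.append(result.x_opt)
        discrepancies.append(float(np.mean(np.abs(li.corrected_pred_d - actual))))
        actual_mpes.append(float(np.mean(cohort.postop_se_d - actual)))
    x_arr = np.asarray(x_opts)
    return RecoveryResult(
        bias_x_opt=float(np.mean(x_arr) - config.x_true),
        sd_x_opt=float(np.std(x_arr, ddof=1)) if replicates > 1 else 0.0,
        mean_abs_li_minus_actual_d=float(np.mean(discrepancies)),
        x_opts=tuple(x_opts),
        actual_mpes_d=tuple(actual_mpes),
        n_eyes=config.n_eyes,
        replicates=replicates,
    )
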