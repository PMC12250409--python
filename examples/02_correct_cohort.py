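"""Calibrate a cohort and compare the two per-case correction methods.

A synthetic 188-eye cohort is drawn (predictions affine in the constant,
postoperative noise SD 0.30 D), the constant is optimized by linear
interpolation, and each eye's prediction is corrected two ways:

* Method-S  — one uniform shift by the cohort MPE;
* Method-LI — each eye's own two predictions interpolated to the
  optimized constant.

Because the generator exposes its prediction law, we can also recompute
"actual values" at the optimized constant and score all three.
"""

from iolopt import (SyntheticConfig, actual_correction, correct_cohort_li,
                    correct_method_s, simulate_cohort, summarize_accuracy)
from iolopt.report import fmt

cohort, formula = simulate_cohort(SyntheticConfig(seed=20250922))
result, li = correct_cohort_li(cohort)
print(f"n = {len(cohort)} eyes; optimized constant = {fmt(result.x_opt, 3)} "
      f"(true value 119.5), slope = {fmt(result.slope_d_per_unit, 3)} D/unit\n")

corrections = {
    "Method-S": correct_method_s(cohort),
    "Method-LI": li,
    "Actual": actual_correction(cohort, formula.evaluate(result.x_opt)),
}

print(f"{'method':<10}{'MPE':>9}{'MAE':>8}{'MedAE':>8}{'SE':>8}"
      f"{'<0.25D%':>9}{'<0.5D%':>8}")
for name, corr in corrections.items():
    s = summarize_accuracy(corr)
    print(f"{name:<10}{fmt(s.mpe_d, 4):>9}{fmt(s.mae_d, 3):>8}"
          f"{fmt(s.medae_d, 3):>8}{fmt(s.se_ape_d, 4):>8}"
          f"{fmt(100 * s.rate_025, 1):>9}{fmt(100 * s.rate_05, 1):>8}")

print("\nBoth correction methods zero the mean error by construction; with an "
      "exactly linear prediction law Method-LI reproduces the recomputed "
      "actual values case by case, so their accuracy rows coincide.")
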