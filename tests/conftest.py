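import numpy as np
import pytest

from iolopt import Cohort, EyeCase

ANCHORS = (119.1, 119.33)


def _case(patient="P1", eye="right", al=23.8, cva=0.1, postop=-0.3,
          pred_lo=-0.1, pred_hi=-0.25, device="DEV", formula="F"):
    return EyeCase(patient_id=patient, eye=eye, device=device, formula=formula,
                   al_mm=al, cva_logmar=cva, postop_se_d=postop,
                   pred_lo_d=pred_lo, pred_hi_d=pred_hi)


@pytest.fixture
def make_case():
    return _case


@pytest.fixture
def make_cohort():
    """Build a cohort from keyword-dict case specs (defaults filled in)."""

    def build(*case_specs, anchors=ANCHORS):
        cases = [_case(**spec) for spec in case_specs]
        return Cohort(tuple(cases), *anchors)

    return build


@pytest.fixture
def linear_cohort(make_cohort):
    """A 6-eye cohort whose predictions are exactly affine in the constant.

    Eye i has slope s_i and prediction s_i*(x - 119.5) + t_i, so the true
    zero-MPE constant is 119.5 when postop equals the prediction there plus
    a mean-zero disturbance.
    """
    rng = np.random.default_rng(42)
    slopes = rng.uniform(-0.85, -0.65, 6)
    targets = rng.normal(-0.25, 0.2, 6)
    noise = rng.normal(0, 0.3, 6)
    noise -= noise.mean()  # exact zero-MPE constant stays at 119.5
    specs = []
    for i in range(6):
        f = lambda x, i=i: targets[i] + slopes[i] * (x - 119.5)
        specs.append(dict(patient=f"P{i}", postop=float(targets[i] + noise[i]),
                          pred_lo=float(f(ANCHORS[0])), pred_hi=float(f(ANCHORS[1]))))
    return make_cohort(*specs)
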