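"""10-year Framingham risk from continuous covariates.

Uses the sex-specific Cox formulation of the Framingham general
cardiovascular risk profile (D'Agostino et al., Circulation 2008), which
takes age, total cholesterol, HDL cholesterol and systolic blood pressure as
continuous (log-transformed) variables and diabetes and current smoking as
indicators:

    risk = 1 - S0(10) ** exp(sum_i beta_i x_i - m)

where ``S0(10)`` is the sex-specific 10-year baseline survival and ``m`` the
mean linear predictor in the derivation cohort.  Cholesterol enters in mg/dL;
inputs in mmol/l are converted with 1 mmol/l = 38.67 mg/dL.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["framingham_risk", "MissingCovariateError", "MGDL_PER_MMOL"]

MGDL_PER_MMOL = 38.67

# D'Agostino 2008, Table: Cox model coefficients (lipids in mg/dL).
_COEFFS = {
    "male": {
        "ln_age": 3.06117,
        "ln_tc": 1.12370,
        "ln_hdl": -0.93263,
        "ln_sbp_untreated": 1.93303,
        "ln_sbp_treated": 1.99881,
        "smoker": 0.65451,
        "diabetes": 0.57367,
        "mean_lp": 23.9802,
        "s0_10": 0.88936,
    },
    "female": {
        "ln_age": 2.32888,
        "ln_tc": 1.20904,
        "ln_hdl": -0.70833,
        "ln_sbp_untreated": 2.76157,
        "ln_sbp_treated": 2.82263,
        "smoker": 0.52873,
        "diabetes": 0.69154,
        "mean_lp": 26.1931,
        "s0_10": 0.95012,
    },
}


class MissingCovariateError(ValueError):
    """A required risk covariate is absent or non-finite."""


def framingham_risk(
    age: float,
    male: bool,
    total_chol_mmol: float,
    hdl_mmol: float,
    sbp_mmhg: float,
    smoker: bool,
    diabetes: bool,
    treated_bp: bool = False,
) -> float:
    """10-year risk of a cardiovascular event, in percent (0-100)."""
    for name, value in (
        ("age", age),
        ("total_chol_mmol", total_chol_mmol),
        ("hdl_mmol", hdl_mmol),
        ("sbp_mmhg", sbp_mmhg),
    ):
        if value is None or not np.isfinite(value) or value <= 0:
            raise MissingCovariateError(f"covariate {name!r} is missing or invalid: {value!r}")
    c = _COEFFS["male" if male else "female"]
    lp = (
        c["ln_age"] * math.log(age)
        + c["ln_tc"] * math.log(total_chol_mmol * MGDL_PER_MMOL)
        + c["ln_hdl"] * math.log(hdl_mmol * MGDL_PER_MMOL)
        + (c["ln_sbp_treated"] if treated_bp else c["ln_sbp_untreated"]) * math.log(sbp_mmhg)
        + c["smoker"] * bool(smoker)
        + c["diabetes"] * bool(diabetes)
    )
    risk = 1.0 - c["s0_10"] ** math.exp(lp - c["mean_lp"])
    return 100.0 * min(max(risk, 0.0), 1.0)
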