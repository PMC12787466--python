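"""Deterministic clinical derivations: HOMA-IR and BMI classification."""

from __future__ import annotations

import numpy as np

#: Standard HOMA-IR denominator for insulin in uIU/mL and glucose in mg/dL.
HOMA_DENOMINATOR = 405.0

#: BMI class labels, in increasing severity.
BMI_OUT_OF_RANGE = "out_of_range"
BMI_OVERWEIGHT = "overweight"
BMI_OBESITY = "obesity"


def homa_ir(insulin, glucose):
    """Homeostasis-model insulin-resistance index.

    HOMA-IR = insulin (uIU/mL) x glucose (mg/dL) / 405. Accepts scalars or
    arrays (broadcast elementwise).

    Raises
    ------
    ValueError
        If any insulin or glucose value is negative.
    """
    ins = np.asarray(insulin, dtype=float)
    glu = np.asarray(glucose, dtype=float)
    if np.any(ins < 0):
        raise ValueError("insulin must be non-negative")
    if np.any(glu < 0):
        raise ValueError("glucose must be non-negative")
    out = ins * glu / HOMA_DENOMINATOR
    return float(out) if out.ndim == 0 else out


def bmi_class(bmi: float) -> str:
    """Classify BMI (kg/m2) against the cohort inclusion bands.

    ``[25, 30)`` is overweight, ``>= 30`` obesity, ``< 25`` out of range
    (below the study's inclusion threshold). The boundary values 25 and 30
    follow the WHO convention (25 -> overweight, 30 -> obesity).

    Raises
    ------
    ValueError
        If ``bmi`` is not strictly positive.
    """
    if not bmi > 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi >= 30:
        return BMI_OBESITY
    if bmi >= 25:
        return BMI_OVERWEIGHT
    return BMI_OUT_OF_RANGE
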