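"""Reported characteristics of the development cohort for half-body conversion.

The half-to-full conversion implemented in :mod:`hemivol.stats` was
characterised on a cohort of 26 adults with obesity (13 females, 13 males,
BMI 30.8-41.2 kg/m^2) imaged with fat-selective abdominal MRI at 1.5 T.
This module collects the published summary quantities of that cohort; they
serve as inputs for worked examples and as the population the synthetic
cohorts emulate.  All volumes are in cm^3.
"""

from __future__ import annotations

#: Conversion parameter sets {(compartment, side): (slope f, intercept b)}
#: of the linear fit  side_volume = f * reference_total + b.
CONVERSION_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("asat", "left"): (0.5253, -211.1),
    ("asat", "right"): (0.4747, 211.1),
    ("vat", "left"): (0.5207, 154.1),
    ("vat", "right"): (0.4793, -154.1),
}

#: Cohort-mean half-body volumes (cm^3).
MEAN_SIDE_VOLUMES: dict[tuple[str, str], float] = {
    ("asat", "left"): 6605.0,
    ("asat", "right"): 6370.0,
    ("vat", "left"): 2272.0,
    ("vat", "right"): 1795.0,
}

#: Cohort-mean reference (whole-body) volumes (cm^3).
MEAN_REFERENCE: dict[str, float] = {"asat": 12976.0, "vat": 4068.0}

#: Cohort-mean estimated totals obtained from each half (cm^3).
MEAN_ESTIMATES: dict[tuple[str, str], float] = {
    ("asat", "left"): 12976.4,
    ("asat", "right"): 12976.2,
    ("vat", "left"): 4069.2,
    ("vat", "right"): 4068.4,
}

#: Reported min-max of reference volumes over the cohort (cm^3).
REFERENCE_RANGES: dict[str, tuple[float, float]] = {
    "asat": (7812.0, 24161.0),
    "vat": (1137.0, 7518.0),
}

#: Per-gender cohort means (each group n = 13).
GROUP_MEANS: dict[str, dict[str, float]] = {
    "female": {"asat": 15020.0, "vat": 2786.0, "bmi": 34.9, "age": 49.0},
    "male": {"asat": 10932.0, "vat": 5350.0, "bmi": 33.7, "age": 50.9},
}

#: Overall cohort means of BMI (kg/m^2) and age (years).
MEAN_BMI = 34.3
MEAN_AGE = 50.0

#: Left-side volume fractions (dimensionless): (mean, sd, lower, upper).
#: Mean and truncation bounds are the reported cohort mean and min-max;
#: the dispersion is chosen so the truncated normal matches that spread.
ASAT_LEFT_FRACTION: tuple[float, float, float, float] = (0.508, 0.012, 0.482, 0.537)
VAT_LEFT_FRACTION: tuple[float, float, float, float] = (0.564, 0.025, 0.514, 0.659)

#: Headline agreement of half-body with whole-body volumes (R^2 lower bounds).
R2_BOUNDS: dict[str, float] = {"asat": 0.99, "vat": 0.97}
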