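"""Half-to-full volume conversion and agreement statistics.

The conversion parameters are the slope ``f`` and intercept ``b`` of the
ordinary least-squares fit of a half-body volume against the whole-body
reference volume,

    side = f * REF + b,

so the whole-body estimate from a measured half is the inverse prediction

    EST = (side - b) / f.

For any cohort in which left + right = reference exactly, the two sides'
parameters satisfy f_L + f_R = 1 and b_L + b_R = 0, and in-sample estimation
preserves the cohort mean (mean(EST) = mean(REF)).

Agreement between measured and estimated totals is summarised Bland-Altman
style (mean difference, SD of differences with n-1 denominator, limits of
agreement at mean +/- 1.96 SD) with a Shapiro-Wilk normality check of the
differences.  Group contrasts use a two-sided two-sample t-test
(equal-variance by default, Welch optional).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConversionFit", "AgreementStats", "GroupComparison",
    "validate_cohort_table", "fit_conversion", "estimate_full",
    "r_squared", "bland_altman", "group_compare", "run_validation",
]

VOLUME_COLUMNS = ["asat_total", "asat_left", "asat_right",
                  "vat_total", "vat_left", "vat_right"]
COMPARTMENTS = ("asat", "vat")
SIDES = ("left", "right")


@dataclass(frozen=True)
class ConversionFit:
    """Slope f, intercept b (cm^3) and R^2 of a side-vs-reference fit."""

    compartment: str
    side: str
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a conversion fit needs at least 3 subjects")
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"R^2 {self.r_squared} outside [0, 1]")


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of measured - estimated differences (cm^3)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    shapiro_w: float | None
    shapiro_p: float | None
    n: int


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    means: dict[str, float]
    t: float
    p: float
    equal_var: bool


def validate_cohort_table(table: pd.DataFrame) -> None:
    missing = [c for c in VOLUME_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    if "subject_id" in table.columns and table["subject_id"].duplicated().any():
        raise ValueError("cohort table has duplicated subject ids")
    vols = table[VOLUME_COLUMNS].to_numpy(dtype=float)
    if np.any(vols < 0):
        raise ValueError("cohort table contains negative volumes")


def fit_conversion(table: pd.DataFrame, compartment: str, side: str) -> ConversionFit:
    """OLS of the half-body volume (response) on the reference total."""
    if compartment not in COMPARTMENTS or side not in SIDES:
        raise ValueError(f"unknown compartment/side {compartment!r}/{side!r}")
    x = table[f"{compartment}_total"].to_numpy(dtype=float)
    y = table[f"{compartment}_{side}"].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 subjects to fit, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: reference volumes are all equal")
    res = sps.linregress(x, y)
    return ConversionFit(compartment=compartment, side=side,
                         slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2), n=int(n))


def estimate_full(side_volume, fit: ConversionFit, as_printed: bool = False):
    """Whole-body volume estimated from one half.

    Default is the inverse prediction ``(side - b) / f`` of the
    side-vs-reference fit.  ``as_printed=True`` instead evaluates the
    literal published form ``side / f + b``, provided for comparison; it is
    algebraically inconsistent with the published parameter sets (see the
    methods note) and not used anywhere by default.
    """
    if fit.slope == 0:
        raise ValueError("conversion slope f is zero; estimate undefined")
    side_volume = np.asarray(side_volume, dtype=float)
    if as_printed:
        out = side_volume / fit.slope + fit.intercept
    else:
        out = (side_volume - fit.intercept) / fit.slope
    return float(out) if out.ndim == 0 else out


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination as the squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = sps.pearsonr(x, y).statistic
    return float(r * r)


def bland_altman(measured: Sequence[float], estimated: Sequence[float]) -> AgreementStats:
    """Agreement between measured and estimated volumes.

    Differences are measured - estimated; the SD uses the n-1 denominator
    and the limits of agreement are mean +/- 1.96 SD.  The Shapiro-Wilk
    normality fields are None when fewer than 3 pairs are available or the
    differences are constant.
    """
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.size != e.size:
        raise ValueError("measured and estimated must have equal length")
    if m.size < 2:
        raise ValueError("need at least 2 pairs")
    d = m - e
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    w = p = None
    if d.size >= 3 and np.ptp(d) > 0:
        sw = sps.shapiro(d)
        w, p = float(sw.statistic), float(sw.pvalue)
    return AgreementStats(mean_diff=mean, sd_diff=sd,
                          loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd,
                          shapiro_w=w, shapiro_p=p, n=int(d.size))


def group_compare(values_by_group: Mapping[str, Sequence[float]],
                  variable: str = "", equal_var: bool = True) -> GroupComparison:
    """Two-sided two-sample t-test between exactly two groups."""
    if len(values_by_group) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(values_by_group)}")
    arrays = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    (ka, a), (kb, b) = arrays.items()
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(variable=variable,
                           means={ka: float(a.mean()), kb: float(b.mean())},
                           t=float(res.statistic), p=float(res.pvalue),
                           equal_var=equal_var)


def _summary(values: np.ndarray) -> dict[str, float]:
    return {"mean": float(np.mean(values)), "min": float(np.min(values)),
            "max": float(np.max(values))}


def run_validation(table: pd.DataFrame, equal_var: bool = True,
                   as_printed: bool = False) -> tuple[dict, pd.DataFrame]:
    """Full half-to-full validation of a cohort volumes table.

    For each compartment x side: conversion fit, in-sample estimates,
    Bland-Altman agreement with the reference totals; plus cohort summaries
    (means, ranges, mean per-subject side fractions in percent) and, when a
    group column with two groups is present, group comparisons of the
    reference volumes.

    Returns the structured report and the per-subject table of measured
    volumes, estimates and differences.
    """
    validate_cohort_table(table)
    per_subject = pd.DataFrame({"subject_id": table.get("subject_id", table.index)})
    if "group" in table.columns:
        per_subject["group"] = table["group"].to_numpy()
    for c in VOLUME_COLUMNS:
        per_subject[c] = table[c].to_numpy(dtype=float)

    fits: dict[str, dict] = {}
    agreement: dict[str, dict] = {}
    for comp in COMPARTMENTS:
        ref = table[f"{comp}_total"].to_numpy(dtype=float)
        for side in SIDES:
            fit = fit_conversion(table, comp, side)
            est = estimate_full(table[f"{comp}_{side}"].to_numpy(dtype=float),
                                fit, as_printed=as_printed)
            key = f"{comp}_{side}"
            fits[key] = asdict(fit)
            agreement[key] = asdict(bland_altman(ref, est))
            per_subject[f"{comp}_est_{side}"] = est
            per_subject[f"{comp}_diff_{side}"] = ref - est

    cohort: dict[str, dict] = {}
    for c in VOLUME_COLUMNS:
        cohort[c] = _summary(table[c].to_numpy(dtype=float))
    for comp in COMPARTMENTS:
        tot = table[f"{comp}_total"].to_numpy(dtype=float)
        left = table[f"{comp}_left"].to_numpy(dtype=float)
        ok = tot > 0
        # mean of per-subject ratios, in percent
        if ok.any():
            cohort[f"{comp}_left_frac_pct"] = _summary(100.0 * left[ok] / tot[ok])

    groups = None
    if "group" in table.columns:
        labels = [g for g in pd.unique(table["group"]) if str(g)]
        if len(labels) == 2:
            groups = {}
            for c in ("asat_total", "vat_total"):
                by = {g: table.loc[table["group"] == g, c].to_numpy(dtype=float)
                      for g in labels}
                if all(v.size >= 2 for v in by.values()):
                    groups[c] = asdict(group_compare(by, variable=c,
                                                     equal_var=equal_var))

    report = {
        "n": int(len(table)),
        "fits": fits,
        "agreement": agreement,
        "cohort": cohort,
        "groups": groups,
        "settings": {"equal_var": equal_var, "as_printed": as_printed},
    }
    return report, per_subject
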