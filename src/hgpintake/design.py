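"""Demographic groupings and fixed-effect design matrices.

The population is analysed in two cohorts fitted separately: children
(ages 1-19) and adults (20+).  Reporting groups cross gender with five
life-stage age bands: early childhood (1-5), middle childhood (6-9),
adolescence (10-19), young-to-middle adulthood (20-54), and 55+
(postmenopausal for females, late adulthood for males).

The fixed-effect basis is identical for the probability and amount parts of
the two-part model: gender, continuous age, a linear age spline (knot at 11
years for children; 29, 39, 49, 59, 69 for adults), age x gender and
spline x gender cross-products, an end-of-week indicator (Friday, Saturday
or Sunday) and a recall-sequence indicator (second, by-phone recall = 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CHILD_KNOTS",
    "ADULT_KNOTS",
    "AGE_GROUPS",
    "age_group",
    "cohort_of_age",
    "design_columns",
    "build_design_matrix",
]

CHILD_KNOTS = (11.0,)
ADULT_KNOTS = (29.0, 39.0, 49.0, 59.0, 69.0)

#: reporting age bands (label, inclusive lower, inclusive upper)
AGE_GROUPS = (
    ("1-5", 1.0, 5.0),
    ("6-9", 6.0, 9.0),
    ("10-19", 10.0, 19.0),
    ("20-54", 20.0, 54.0),
    ("55+", 55.0, np.inf),
)


def age_group(age: float) -> str:
    """Life-stage band label for a single age in years."""
    for label, lo, hi in AGE_GROUPS:
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age!r} outside the supported range (>= 1)")


def cohort_of_age(age) -> np.ndarray:
    """'child' for ages 1-19, 'adult' for 20+ (vectorized)."""
    a = np.asarray(age, dtype=float)
    if np.any(a < 1):
        raise ValueError("ages below 1 year are not supported")
    return np.where(a < 20, "child", "adult")


def _knots(cohort: str):
    if cohort == "child":
        return CHILD_KNOTS
    if cohort == "adult":
        return ADULT_KNOTS
    raise ValueError(f"unknown cohort {cohort!r}")


def design_columns(cohort: str) -> list[str]:
    """Ordered fixed-effect column names for a cohort."""
    knots = _knots(cohort)
    cols = ["const", "male", "age"]
    cols += [f"age_sp{int(k)}" for k in knots]
    cols += ["male_age"]
    cols += [f"male_age_sp{int(k)}" for k in knots]
    cols += ["end_of_week", "second_recall"]
    return cols


def build_design_matrix(df: pd.DataFrame, cohort: str) -> pd.DataFrame:
    """Expand person-day attributes into the fixed-effect basis.

    ``df`` needs columns ``gender`` ('M'/'F'), ``age`` (years), and the
    day-level indicators ``end_of_week`` and ``second_recall`` (0/1 or
    bool; fractional values are allowed so a weekday/weekend mixture can be
    encoded for usual-day prediction).

    Raises if any age falls outside the cohort (children 1-19, adults 20+).
    """
    age = np.asarray(df["age"], dtype=float)
    if cohort == "child":
        if np.any((age < 1) | (age >= 20)):
            raise ValueError("child cohort requires ages in [1, 20)")
    else:
        if np.any(age < 20):
            raise ValueError("adult cohort requires ages >= 20")
    gender = np.asarray(df["gender"]).astype(str)
    bad = ~np.isin(gender, ["M", "F"])
    if bad.any():
        raise ValueError(f"unknown gender codes: {sorted(set(gender[bad]))}")
    male = (gender == "M").astype(float)

    out = pd.DataFrame(index=df.index)
    out["const"] = 1.0
    out["male"] = male
    out["age"] = age
    for k in _knots(cohort):
        out[f"age_sp{int(k)}"] = np.maximum(age - k, 0.0)
    out["male_age"] = male * age
    for k in _knots(cohort):
        out[f"male_age_sp{int(k)}"] = male * out[f"age_sp{int(k)}"]
    out["end_of_week"] = np.asarray(df["end_of_week"], dtype=float)
    out["second_recall"] = np.asarray(df["second_recall"], dtype=float)
    return out[design_columns(cohort)]
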