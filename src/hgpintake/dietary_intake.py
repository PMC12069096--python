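"""Recipe disaggregation and single-day per-bodyweight intake arithmetic.

A consumed food is split into its recipe ingredients; ingredients whose
description contains "beef" (case-insensitive substring, no exclusion list)
are beef.  Cooked ingredient grams convert to raw grams through a single
moisture adjustment factor of 0.75 (25% water loss in cooking), raw grams
split into fat and non-fat mass via the ingredient's nutrient-label fat
proportion, and each mass picks up the scenario concentration of its tissue
class.  Daily intake for person *i* under scenario *s* is

    intake_is = sum_j [ raw_ij * fat_j * C_fat,s + raw_ij * (1-fat_j) * C_nonfat,s ]
                / (1000 * bodyweight_kg)

in ug/kg/day (g x pg/mg / 1000 = ug).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .concentrations import SCENARIOS

__all__ = [
    "MOISTURE_FACTOR",
    "is_beef_description",
    "find_beef_ingredients",
    "cooked_to_raw",
    "raw_beef_from_food",
    "daily_hgp_intake",
    "person_day_beef_grams",
    "compute_daily_intakes",
]

log = logging.getLogger("hgpintake.intake")

MOISTURE_FACTOR = 0.75


def is_beef_description(description: str) -> bool:
    """Case-insensitive substring match on the token 'beef'."""
    return "beef" in str(description).lower()


def find_beef_ingredients(recipe: pd.DataFrame) -> pd.DataFrame:
    """Beef-ingredient rows of one food's recipe."""
    if len(recipe) == 0:
        raise ValueError("recipe has no ingredients")
    return recipe[recipe["description"].map(is_beef_description)]


def cooked_to_raw(cooked_g):
    """Raw-equivalent grams: cooked grams / 0.75."""
    g = np.asarray(cooked_g, dtype=float)
    if np.any(g < 0):
        raise ValueError("cooked grams must be >= 0")
    out = g / MOISTURE_FACTOR
    return float(out) if out.ndim == 0 else out


def raw_beef_from_food(grams_consumed, beef_fraction):
    """Raw beef grams from a consumed food and its summed beef fraction."""
    g = np.asarray(grams_consumed, dtype=float)
    f = np.asarray(beef_fraction, dtype=float)
    if np.any(g < 0) or np.any(f < 0):
        raise ValueError("inputs must be >= 0")
    if np.any(f > 1):
        raise ValueError("beef fraction cannot exceed 1")
    out = g * f / MOISTURE_FACTOR
    return float(out) if out.ndim == 0 else out


def _scenario_lookup(scenario_table: pd.DataFrame, analyte: str,
                     scenario: str):
    sel = scenario_table[(scenario_table["analyte"] == analyte)
                         & (scenario_table["scenario"] == scenario)]
    conc = dict(zip(sel["tissue_class"], sel["pg_per_mg"]))
    if "fat" not in conc or "non-fat" not in conc:
        raise ValueError(
            f"scenario table lacks fat and/or non-fat concentration for "
            f"{analyte}/{scenario}")
    return conc["fat"], conc["non-fat"]


def daily_hgp_intake(items: pd.DataFrame, recipes: pd.DataFrame,
                     scenario_table: pd.DataFrame, analyte: str,
                     scenario: str, bodyweight_kg: float):
    """Intake (ug/kg/day) for one person-day's recall items.

    ``items`` has columns ``food_code`` and ``grams_consumed``.  Returns
    ``(intake, fat_g, nonfat_g)`` where the gram components are the raw
    beef fat / non-fat masses summed over all beef ingredients.
    """
    if not bodyweight_kg > 0:
        raise ValueError("bodyweight must be > 0")
    c_fat, c_nonfat = _scenario_lookup(scenario_table, analyte, scenario)
    fat_g = 0.0
    nonfat_g = 0.0
    pg = 0.0
    for _, item in items.iterrows():
        recipe = recipes[recipes["food_code"] == item["food_code"]]
        if len(recipe) == 0:
            continue
        beef = find_beef_ingredients(recipe)
        for _, ing in beef.iterrows():
            raw = raw_beef_from_food(item["grams_consumed"],
                                     ing["recipe_fraction"])
            f = float(ing["fat_proportion"])
            fat_g += raw * f
            nonfat_g += raw * (1 - f)
            pg += raw * f * c_fat + raw * (1 - f) * c_nonfat
    return pg / (1000.0 * bodyweight_kg), fat_g, nonfat_g


def person_day_beef_grams(recalls: pd.DataFrame,
                          recipes: pd.DataFrame) -> pd.DataFrame:
    """Raw beef fat/non-fat grams per person-day (vectorized).

    Returns one row per person x recall day (including zero rows for days
    with no beef) with columns ``raw_fat_g``, ``raw_nonfat_g``,
    ``raw_beef_g``, plus the day attributes ``end_of_week`` and
    ``second_recall``.
    """
    merged = recalls.merge(recipes, on="food_code", how="left")
    beef = merged["description"].map(is_beef_description).fillna(False)
    m = merged[beef].copy()
    raw = (m["grams_consumed"] * m["recipe_fraction"]) / MOISTURE_FACTOR
    m["raw_fat_g"] = raw * m["fat_proportion"]
    m["raw_nonfat_g"] = raw * (1 - m["fat_proportion"])
    grams = (m.groupby(["person_id", "recall_day"])[
        ["raw_fat_g", "raw_nonfat_g"]].sum())

    day_attrs = (recalls.groupby(["person_id", "recall_day"])[
        ["end_of_week", "second_recall"]].first())
    out = day_attrs.join(grams, how="left").fillna(
        {"raw_fat_g": 0.0, "raw_nonfat_g": 0.0})
    out["raw_beef_g"] = out["raw_fat_g"] + out["raw_nonfat_g"]
    return out.reset_index()


def compute_daily_intakes(recalls: pd.DataFrame, recipes: pd.DataFrame,
                          persons: pd.DataFrame,
                          scenario_table: pd.DataFrame,
                          analytes=None, scenarios=SCENARIOS) -> pd.DataFrame:
    """Dense person-day x analyte x scenario intake table (ug/kg/day).

    Person-days whose person lacks a bodyweight are skipped and logged (not
    imputed).  Columns: person_id, recall_day, analyte, scenario,
    ug_per_kg_day, fat_g, nonfat_g.
    """
    grams = person_day_beef_grams(recalls, recipes)
    pw = persons.set_index("person_id")["bodyweight_kg"]
    grams = grams.merge(pw.rename("bodyweight_kg"), left_on="person_id",
                        right_index=True, how="left")
    missing = grams["bodyweight_kg"].isna() | (grams["bodyweight_kg"] <= 0)
    if missing.any():
        log.warning("skipping %d person-days with missing bodyweight",
                    int(missing.sum()))
        grams = grams[~missing]

    if analytes is None:
        analytes = sorted(scenario_table["analyte"].unique())
    frames = []
    for analyte in analytes:
        for scenario in scenarios:
            c_fat, c_nonfat = _scenario_lookup(scenario_table, analyte,
                                               scenario)
            pg = grams["raw_fat_g"] * c_fat + grams["raw_nonfat_g"] * c_nonfat
            frames.append(pd.DataFrame({
                "person_id": grams["person_id"],
                "recall_day": grams["recall_day"],
                "analyte": analyte,
                "scenario": scenario,
                "ug_per_kg_day": pg / (1000.0 * grams["bodyweight_kg"]),
                "fat_g": grams["raw_fat_g"],
                "nonfat_g": grams["raw_nonfat_g"],
            }))
    return pd.concat(frames, ignore_index=True)
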