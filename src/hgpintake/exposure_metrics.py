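"""Hazard-quotient screening and short-term (two-day-average) intake.

The hazard quotient (HQ) is estimated intake divided by the analyte's
acceptable daily intake (ADI, ug/kg/day); HQ > 1 means the intake estimate
exceeds the ADI.  Testosterone intake is screened as the sum of T and
epitestosterone intakes against the T ADI.  The hazard index (HI) is the
sum of HQs for agents with related critical effects.  Short-term intake is
the empirical two-day average over both recalls for persons completing
both, summarized with the shared weighted-percentile convention.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design import age_group
from .quantiles import weighted_quantile

__all__ = [
    "AdiRegistry",
    "DEFAULT_ADIS",
    "hazard_quotient",
    "hazard_index",
    "format_hq",
    "combined_testosterone",
    "two_day_average",
    "summarize_two_day",
]

log = logging.getLogger("hgpintake.exposure")

#: JECFA acceptable daily intakes, ug/kg bodyweight/day
DEFAULT_ADIS = {
    "MGA": (0.03, "JECFA ADI for melengestrol acetate, 0-0.03 ug/kg/day"),
    "P": (30.0, "JECFA ADI for progesterone, 0-30 ug/kg/day"),
    "T": (2.0, "JECFA ADI for testosterone, 2 ug/kg/day"),
    "T+EpiT": (2.0, "T plus epitestosterone screened against the T ADI"),
}


class AdiRegistry:
    """Editable analyte -> ADI mapping with provenance notes."""

    def __init__(self, entries=None):
        self._entries = dict(DEFAULT_ADIS if entries is None else entries)
        for analyte, (adi, _) in self._entries.items():
            if not adi > 0:
                raise ValueError(f"ADI for {analyte} must be > 0")

    def __contains__(self, analyte):
        return analyte in self._entries

    def adi(self, analyte) -> float:
        if analyte not in self._entries:
            raise KeyError(f"no ADI registered for analyte {analyte!r}")
        return self._entries[analyte][0]

    def provenance(self, analyte) -> str:
        return self._entries[analyte][1]

    def add(self, analyte, adi, note=""):
        if not adi > 0:
            raise ValueError("ADI must be > 0")
        self._entries[analyte] = (float(adi), note)

    def to_dict(self):
        return {a: {"adi_ug_per_kg_day": v, "provenance": n}
                for a, (v, n) in self._entries.items()}

    @classmethod
    def from_dict(cls, d):
        return cls({a: (e["adi_ug_per_kg_day"], e.get("provenance", ""))
                    for a, e in d.items()})


def hazard_quotient(intake, analyte, registry: AdiRegistry | None = None):
    """HQ = intake / ADI (dimensionless, unrounded)."""
    registry = registry or AdiRegistry()
    if np.any(np.asarray(intake, dtype=float) < 0):
        raise ValueError("intake must be >= 0")
    out = np.asarray(intake, dtype=float) / registry.adi(analyte)
    return float(out) if out.ndim == 0 else out


def format_hq(hq) -> str:
    """Report rendering: two decimals, '<0.01' below 0.005."""
    hq = float(hq)
    if hq < 0:
        raise ValueError("HQ must be >= 0")
    if 0 < hq < 0.005:
        return "<0.01"
    return f"{hq:.2f}"


def hazard_index(hqs) -> float:
    """Sum of hazard quotients (agents with related critical effects)."""
    hqs = np.asarray(list(hqs), dtype=float)
    if np.any(hqs < 0):
        raise ValueError("HQs must be >= 0")
    return float(hqs.sum())


def combined_testosterone(intake_t, intake_epit):
    """Summed T + EpiT intake, screened against the testosterone ADI."""
    t = np.asarray(intake_t, dtype=float)
    e = np.asarray(intake_epit, dtype=float)
    if np.any(t < 0) or np.any(e < 0):
        raise ValueError("intakes must be >= 0")
    out = t + e
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Short-term (two-day-average) intake
# ---------------------------------------------------------------------------

def two_day_average(daily_intakes: pd.DataFrame) -> pd.DataFrame:
    """Per-person two-day mean intake, per analyte x scenario.

    Persons contributing only one recall day are excluded (counted in the
    log).  ``daily_intakes`` is the dense table from
    :func:`hgpintake.dietary_intake.compute_daily_intakes`.
    """
    days_per = daily_intakes.groupby("person_id")["recall_day"].nunique()
    complete = days_per[days_per >= 2].index
    n_dropped = int((days_per < 2).sum())
    if n_dropped:
        log.info("two-day average: excluded %d persons with a single recall",
                 n_dropped)
    df = daily_intakes[daily_intakes["person_id"].isin(complete)]
    out = (df.groupby(["person_id", "analyte", "scenario"], sort=True)
           ["ug_per_kg_day"].mean().rename("two_day_avg_ug_per_kg_day")
           .reset_index())
    out.attrs["n_excluded_single_recall"] = n_dropped
    return out


def summarize_two_day(two_day: pd.DataFrame,
                      persons: pd.DataFrame) -> pd.DataFrame:
    """Weighted group summaries of the two-day-average distribution.

    Flagged ``acute_vs_chronic_adi`` because short-term intakes compared to
    chronic ADIs are not strictly comparable.
    """
    p = persons.set_index("person_id")
    merged = two_day.merge(
        p[["gender", "age", "weight"]], left_on="person_id",
        right_index=True, how="inner")
    merged["age_group"] = merged["age"].map(age_group)
    rows = []
    for (analyte, scen, gender, band), grp in merged.groupby(
            ["analyte", "scenario", "gender", "age_group"], sort=True):
        v = grp["two_day_avg_ug_per_kg_day"].to_numpy()
        w = grp["weight"].to_numpy()
        med, p95, p99 = weighted_quantile(v, [0.5, 0.95, 0.99], w)
        rows.append({
            "analyte": analyte, "scenario": scen,
            "gender": gender, "age_group": band,
            "n": len(grp),
            "mean": float(np.average(v, weights=w)),
            "median": float(med), "p95": float(p95), "p99": float(p99),
            "acute_vs_chronic_adi": "not strictly comparable",
        })
    return pd.DataFrame(rows)


def hq_report(summaries: pd.DataFrame, registry: AdiRegistry | None = None,
              kind="usual") -> pd.DataFrame:
    """HQ table for group summaries (statistics: mean/median/p95/p99).

    Analytes without a registered ADI are passed through with empty HQ
    cells.  Underlying unrounded HQs are stored alongside the display
    rendering.
    """
    registry = registry or AdiRegistry()
    rows = []
    for _, r in summaries.iterrows():
        for statistic in ("mean", "median", "p95", "p99"):
            row = {
                "kind": kind,
                "analyte": r["analyte"], "scenario": r["scenario"],
                "gender": r["gender"], "age_group": r["age_group"],
                "statistic": statistic,
                "intake_ug_per_kg_day": float(r[statistic]),
            }
            if r["analyte"] in registry:
                hq = hazard_quotient(r[statistic], r["analyte"], registry)
                row["adi_ug_per_kg_day"] = registry.adi(r["analyte"])
                row["hq"] = hq
                row["hq_display"] = format_hq(hq)
            else:
                row["adi_ug_per_kg_day"] = np.nan
                row["hq"] = np.nan
                row["hq_display"] = ""
            if kind == "shortterm":
                row["note"] = "acute intake vs chronic ADI: not strictly comparable"
            rows.append(row)
    return pd.DataFrame(rows)
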