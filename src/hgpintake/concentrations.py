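"""Assay records -> analyte inclusion, imputation, summaries, scenario tables.

Non-detects are left-censored at the assay LOD and imputed as LOD/sqrt(2)
before any distribution statistic is computed.  Analytes enter the intake
assessment only if detected in at least ten samples overall.  Per analyte
and tissue class (separated subcutaneous fat vs everything else) the mean,
95th percentile and maximum of the detected-plus-imputed sample define the
three concentration scenarios: typical (mean), high (P95) and max.
Fat/non-fat concentration differences in paired subsamples are screened
with a Wilcoxon matched-pairs signed-rank test (exact by sign enumeration
for up to 12 non-zero differences).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .quantiles import weighted_quantile

__all__ = [
    "impute_nondetect",
    "select_analytes",
    "summarize_by_tissue",
    "build_scenario_tables",
    "paired_fat_meat_test",
    "paired_values",
    "SCENARIOS",
]

SCENARIOS = ("typical", "high", "max")
MIN_DETECTIONS = 10
EXACT_WILCOXON_MAX_N = 12


def impute_nondetect(lod):
    """Imputed value for a non-detect: LOD / sqrt(2)."""
    lod = np.asarray(lod, dtype=float)
    if np.any(lod < 0):
        raise ValueError("LOD must be >= 0")
    out = lod / np.sqrt(2.0)
    return float(out) if out.ndim == 0 else out


def _imputed_concentrations(assays: pd.DataFrame) -> np.ndarray:
    conc = assays["concentration_pg_mg"].to_numpy(dtype=float)
    det = assays["detected"].astype(bool).to_numpy()
    lod = assays["lod_pg_mg"].to_numpy(dtype=float)
    return np.where(det, conc, impute_nondetect(lod))


def select_analytes(assays: pd.DataFrame, min_detections=MIN_DETECTIONS,
                    return_counts=False):
    """Analytes detected in at least ``min_detections`` samples overall."""
    if len(assays) == 0:
        raise ValueError("assay table is empty")
    counts = (assays.groupby("analyte")["detected"].sum()
              .astype(int).sort_index())
    keep = counts[counts >= min_detections].index.tolist()
    if return_counts:
        return keep, counts
    return keep


def summarize_by_tissue(assays: pd.DataFrame, analytes=None) -> pd.DataFrame:
    """Mean/P95/max per analyte x tissue class over detected + imputed values.

    ``analytes`` defaults to the full table (callers normally pass the
    output of :func:`select_analytes`).  Empty analyte-tissue cells are
    omitted with a warning.
    """
    df = assays
    if analytes is not None:
        df = df[df["analyte"].isin(analytes)]
    rows = []
    for (analyte, tissue), grp in df.groupby(["analyte", "tissue_class"],
                                             sort=True):
        if len(grp) == 0:     # pragma: no cover - groupby drops empty
            continue
        vals = _imputed_concentrations(grp)
        rows.append({
            "analyte": analyte,
            "tissue_class": tissue,
            "n": len(grp),
            "n_detected": int(grp["detected"].sum()),
            "mean_pg_mg": float(vals.mean()),
            "p95_pg_mg": float(weighted_quantile(vals, 0.95)),
            "max_pg_mg": float(vals.max()),
        })
    out = pd.DataFrame(rows)
    if analytes is not None:
        seen = set(map(tuple, out[["analyte", "tissue_class"]].to_numpy())) \
            if len(out) else set()
        for a in analytes:
            for t in ("fat", "non-fat"):
                if (a, t) not in seen:
                    warnings.warn(f"no assay records for {a}/{t}; "
                                  "summary omitted", UserWarning, stacklevel=2)
    return out


def build_scenario_tables(summaries: pd.DataFrame) -> pd.DataFrame:
    """Long-format scenario concentration table from tissue summaries.

    typical <- mean, high <- P95, max <- maximum, per analyte and tissue
    class.  Every analyte must have both tissue classes (the per-ingredient
    intake formula needs both); otherwise a hard error is raised.
    """
    have = summaries.groupby("analyte")["tissue_class"].apply(set)
    missing = {a: {"fat", "non-fat"} - s for a, s in have.items()
               if {"fat", "non-fat"} - s}
    if missing:
        raise ValueError(f"missing tissue classes for analytes: {missing}")
    rows = []
    col = {"typical": "mean_pg_mg", "high": "p95_pg_mg", "max": "max_pg_mg"}
    for _, r in summaries.iterrows():
        for scen in SCENARIOS:
            rows.append({
                "scenario": scen,
                "analyte": r["analyte"],
                "tissue_class": r["tissue_class"],
                "pg_per_mg": float(r[col[scen]]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Paired fat vs meat comparison
# ---------------------------------------------------------------------------

def paired_values(assays: pd.DataFrame, analyte: str):
    """(fat, non-fat) imputed concentration pairs for one analyte.

    Fat subsamples are matched to their parent product via
    ``paired_parent_id``; both members are imputed at LOD/sqrt(2) when
    censored.
    """
    df = assays[assays["analyte"] == analyte].copy()
    df["value"] = _imputed_concentrations(df)
    fat = df[(df["tissue_class"] == "fat")
             & (df["paired_parent_id"].astype(str) != "")]
    nonfat = df[df["tissue_class"] == "non-fat"].set_index("sample_id")
    pairs = []
    for _, r in fat.iterrows():
        pid = r["paired_parent_id"]
        if pid in nonfat.index:
            pairs.append((float(r["value"]), float(nonfat.loc[pid, "value"])))
    return pairs


def paired_fat_meat_test(pairs):
    """Wilcoxon matched-pairs signed-rank test, two-sided.

    Zero differences are dropped before ranking.  With at most
    ``EXACT_WILCOXON_MAX_N`` non-zero differences the null distribution of
    the positive-rank sum W+ is enumerated over all sign assignments
    (ties in |d| get midranks and the enumeration uses those midranks);
    otherwise a normal approximation with continuity and tie correction is
    used.  Returns ``(w_plus, p_two_sided)``.
    """
    pairs = list(pairs)
    if len(pairs) < 1:
        raise ValueError("need at least one pair")
    d = np.array([f - m for f, m in pairs], dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; no signal",
                      UserWarning, stacklevel=2)
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        # enumerate all 2^n sign assignments of the midranks
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        center = ranks.sum() / 2.0
        dev = abs(w_plus - center)
        p = float(np.mean(np.abs(sums - center) >= dev - 1e-12))
        return w_plus, min(1.0, p)
    # normal approximation with continuity and tie correction
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = (n * (n + 1) * (2 * n + 1)
           - 0.5 * np.sum(tie_counts**3 - tie_counts)) / 24.0
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if var > 0 else 0.0
    p = 2 * stats.norm.sf(abs(z))
    return w_plus, float(min(1.0, p))


def exact_signed_rank_reference(diffs):
    """Brute-force two-sided exact p by itertools sign enumeration.

    Independent oracle for :func:`paired_fat_meat_test` (n <= 12): loops
    over every sign vector explicitly rather than convolving rank sums.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    center = ranks.sum() / 2.0
    count = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if abs(w - center) >= abs(w_obs - center) - 1e-12:
            count += 1
    return min(1.0, count / total)
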