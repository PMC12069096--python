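"""Sociodemographic intake ratios with Fay-BRR confidence intervals.

Subgroup contrasts are ratios of the weighted median usual intake in a
subgroup (race/ethnicity, income vs the federal poverty line, education) to
the weighted median of the *overall* reference population — the subgroup is
part of the reference, exactly as the comparisons are defined.  Sampling
variability under a two-units-per-stratum survey design is estimated by
balanced repeated replication with Fay's method: replicate r multiplies one
half-sample of each pseudo-stratum by (2 - F) and the other by F following
a Hadamard-balanced pattern, and

    var(theta_hat) = 1 / (R (1-F)^2) * sum_r (theta_r - theta_hat)^2 .

Confidence intervals and two-sided p-values are formed on the log-ratio
scale with a normal reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import hadamard

from .quantiles import weighted_median

__all__ = [
    "BrrDesign",
    "build_replicate_weights",
    "median_intake_ratio",
    "fay_variance",
    "brr_ci",
    "BrrEstimate",
    "intake_ratio_table",
    "plot_intake_ratios",
]

log = logging.getLogger("hgpintake.disparities")


@dataclass
class BrrDesign:
    """Balanced-repeated-replication design (Fay's method)."""

    n_replicates: int = 32
    fay_factor: float = 0.3
    max_failed_fraction: float = 0.25

    def __post_init__(self):
        if not 0 <= self.fay_factor <= 1:
            raise ValueError("Fay factor must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def build_replicate_weights(persons: pd.DataFrame,
                            design: BrrDesign | None = None) -> np.ndarray:
    """Replicate weight matrix (n_persons, R) from paired pseudo-strata.

    ``persons`` needs ``weight``, ``pseudo_stratum`` and ``half_sample``
    (exactly two units per stratum).  Half-sample selection follows the
    first ``n_strata`` columns of a Hadamard matrix of order >= R; each
    replicate is rescaled so its weight total matches the full-sample total
    (median- and ratio-type estimators are invariant to this rescaling).
    With F = 1 every replicate reproduces the base weights.
    """
    design = design or BrrDesign()
    w = persons["weight"].to_numpy(dtype=float)
    strata = persons["pseudo_stratum"].to_numpy()
    half = persons["half_sample"].to_numpy()
    uniq = np.unique(strata)
    for s in uniq:
        units = np.unique(half[strata == s])
        if len(units) != 2:
            raise ValueError(
                f"pseudo-stratum {s!r} has {len(units)} half-sample units "
                "(need exactly 2)")
    n_strata = len(uniq)
    R = design.n_replicates
    if R < n_strata:
        raise ValueError(f"need at least {n_strata} replicates for "
                         f"{n_strata} pseudo-strata (got {R})")
    order = 1
    while order < max(R, n_strata + 1):
        order *= 2
    # drop the all-ones first column so every stratum's selection is balanced
    H = hadamard(order)[:R, 1:n_strata + 1]

    F = design.fay_factor
    stratum_idx = np.searchsorted(uniq, strata)
    first_half = half == half.min()
    # factor per person per replicate: (2-F) where selected, F otherwise
    sel = H[:, stratum_idx].T == 1          # (n, R): is this person's
    sel = np.where(first_half[:, None], sel, ~sel)
    factors = np.where(sel, 2.0 - F, F)
    reps = w[:, None] * factors
    totals = reps.sum(axis=0)
    reps *= w.sum() / totals                # replicate totals match full total
    return reps


def median_intake_ratio(values, subgroup_mask, weights) -> float:
    """Weighted median of subgroup / weighted median of overall population.

    ``values`` may be per-person scalars (n,) or a pooled draw matrix
    (n, n_sim) whose rows are a person's simulated usual intakes; pooled
    draws each carry the person's weight divided by the draw count.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(subgroup_mask, dtype=bool)
    weights = np.asarray(weights, dtype=float)
    if mask.sum() == 0:
        raise ValueError("subgroup is empty")
    if values.ndim == 2:
        k = values.shape[1]
        flat = values.ravel()
        wflat = np.repeat(weights / k, k)
        mflat = np.repeat(mask, k)
        values, weights, mask = flat, wflat, mflat
    overall = weighted_median(values, weights)
    if overall == 0:
        raise ZeroDivisionError("overall median intake is zero; "
                                "ratio undefined")
    return float(weighted_median(values[mask], weights[mask]) / overall)


@dataclass
class BrrEstimate:
    """Point estimate with Fay-BRR variance, CI and two-sided p."""

    estimate: float
    variance: float
    ci_low: float
    ci_high: float
    p_value: float
    n_replicates_used: int
    n_replicates_failed: int


def fay_variance(replicate_estimates, full_estimate, fay_factor) -> float:
    """Fay-BRR variance: ``sum_r (theta_r - theta)^2 / (R (1-F)^2)``."""
    reps = np.asarray(replicate_estimates, dtype=float)
    if fay_factor == 1.0:
        return 0.0
    return float(((reps - full_estimate) ** 2).sum()
                 / (reps.size * (1 - fay_factor) ** 2))


def brr_ci(estimator, replicate_weights: np.ndarray,
           design: BrrDesign | None = None, full_estimate=None,
           base_weights=None, log_scale=True, null_value=1.0,
           alpha=0.05) -> BrrEstimate:
    """Fay-BRR variance, CI and test for a weight-indexed estimator.

    ``estimator(weights) -> float`` is re-evaluated under every replicate
    weight column; failed replicates (exceptions or non-finite results) are
    dropped with a count, aborting above the design's failure cap.  The CI
    and p-value are normal-reference on the log scale (for positive ratio
    estimands; ``log_scale=False`` uses the natural scale with
    ``null_value`` as the test null).
    """
    design = design or BrrDesign()
    if full_estimate is None:
        if base_weights is None:
            # balanced replicate factors average to one, so the mean
            # replicate weight recovers the (rescaled) base weight
            base_weights = replicate_weights.mean(axis=1)
        full_estimate = estimator(np.asarray(base_weights, dtype=float))
    theta = float(full_estimate)
    reps = []
    failed = 0
    for r in range(replicate_weights.shape[1]):
        try:
            val = float(estimator(replicate_weights[:, r]))
            if not np.isfinite(val):
                raise FloatingPointError("non-finite replicate estimate")
            reps.append(val)
        except Exception as exc:  # noqa: BLE001 - replicate-level guard
            failed += 1
            log.warning("replicate %d failed: %s", r + 1, exc)
    R_total = replicate_weights.shape[1]
    if failed > design.max_failed_fraction * R_total:
        raise RuntimeError(
            f"{failed}/{R_total} BRR replicates failed "
            f"(> {design.max_failed_fraction:.0%} cap)")
    variance = fay_variance(reps, theta, design.fay_factor)
    se = np.sqrt(variance)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    if log_scale:
        if theta <= 0:
            raise ValueError("log-scale CI requires a positive estimate")
        se_log = se / theta if theta > 0 else np.inf   # delta method
        lo = theta * np.exp(-zcrit * se_log)
        hi = theta * np.exp(zcrit * se_log)
        z = ((np.log(theta) - np.log(null_value)) / se_log
             if se_log > 0 else np.inf * np.sign(np.log(theta / null_value))
             if theta != null_value else 0.0)
    else:
        lo = theta - zcrit * se
        hi = theta + zcrit * se
        z = (theta - null_value) / se if se > 0 else (
            0.0 if theta == null_value else np.inf)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if se == 0:
        p = 1.0 if theta == null_value else 0.0
    return BrrEstimate(estimate=theta, variance=variance,
                       ci_low=float(lo), ci_high=float(hi), p_value=p,
                       n_replicates_used=len(reps),
                       n_replicates_failed=failed)


# ---------------------------------------------------------------------------
# End-to-end subgroup analysis
# ---------------------------------------------------------------------------

_DIMENSIONS = {
    "children": ("race_ethnicity", "income_cat"),
    "women": ("race_ethnicity", "income_cat", "education"),
}


def _cohort_masks(persons: pd.DataFrame):
    age = persons["age"].to_numpy(dtype=float)
    return {
        "children": age < 20,
        "women": (age >= 20) & (persons["gender"].to_numpy() == "F"),
    }


def intake_ratio_table(per_person_intake, persons: pd.DataFrame,
                       design: BrrDesign | None = None,
                       replicate_estimator=None) -> pd.DataFrame:
    """Median intake ratios for every subgroup vs its reference population.

    ``per_person_intake`` is a per-person usual-intake summary (one value
    per row of ``persons``; typically the person's median simulated usual
    intake).  By default each replicate re-evaluates the weighted-median
    ratio under the replicate weights (summary-level replication);
    ``replicate_estimator(weights, mask) -> float`` may be supplied to
    perform heavier per-replicate computation (e.g. refitting the usual-
    intake model under replicate weights).
    """
    design = design or BrrDesign()
    values = np.asarray(per_person_intake, dtype=float)
    if len(values) != len(persons):
        raise ValueError("per_person_intake must align with persons")
    rows = []
    masks = _cohort_masks(persons)
    # replicate weights are built on the full sample and then subset:
    # a half-sample may be empty within a subpopulation
    reps_full = build_replicate_weights(persons.reset_index(drop=True),
                                        design)
    for cohort, dims in _DIMENSIONS.items():
        base = masks[cohort]
        if base.sum() == 0:
            continue
        sub_p = persons[base].reset_index(drop=True)
        sub_v = values[base]
        reps = reps_full[base]
        base_w = sub_p["weight"].to_numpy(dtype=float)
        for dim in dims:
            for cat in sorted(sub_p[dim].unique()):
                mask = (sub_p[dim] == cat).to_numpy()
                if mask.sum() == 0:
                    continue
                if replicate_estimator is None:
                    def est(w, _m=mask):
                        return median_intake_ratio(sub_v, _m, w)
                else:
                    def est(w, _m=mask):
                        return replicate_estimator(w, _m)
                point = est(base_w)
                res = brr_ci(est, reps, design, full_estimate=point)
                rows.append({
                    "cohort": cohort, "dimension": dim, "subgroup": cat,
                    "ratio": res.estimate,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "p_value": res.p_value,
                    "n_replicates_used": res.n_replicates_used,
                    "n_replicates_failed": res.n_replicates_failed,
                    "n_subgroup": int(mask.sum()),
                })
    return pd.DataFrame(rows)


def plot_intake_ratios(table: pd.DataFrame, ax=None):
    """Forest plot of subgroup median-intake ratios with 95% CIs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * max(len(table), 4) + 1.5))
    ypos = np.arange(len(table))[::-1]
    ax.errorbar(table["ratio"], ypos,
                xerr=[table["ratio"] - table["ci_low"],
                      table["ci_high"] - table["ratio"]],
                fmt="o", color="k", ecolor="gray", capsize=3)
    labels = [f"{r.cohort}: {r.subgroup}" for r in table.itertuples()]
    ax.set_yticks(ypos)
    ax.set_yticklabels(labels)
    ax.axvline(1.0, color="firebrick", lw=1, ls="--")
    ax.set_xlabel("median usual-intake ratio (subgroup / overall)")
    ax.figure.tight_layout()
    return ax
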