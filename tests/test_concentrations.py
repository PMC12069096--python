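"""Imputation, inclusion rule, tissue summaries, scenarios, signed-rank test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hgpintake.concentrations import (impute_nondetect, select_analytes,
                                      summarize_by_tissue,
                                      build_scenario_tables,
                                      paired_fat_meat_test,
                                      exact_signed_rank_reference)


def make_assay_table(rows):
    return pd.DataFrame(rows, columns=[
        "sample_id", "analyte", "tissue_class", "detected",
        "concentration_pg_mg", "lod_pg_mg", "paired_parent_id"])


def _rows(analyte, tissue, values, lod, detected=None):
    out = []
    for i, v in enumerate(values):
        det = (v >= lod) if detected is None else detected[i]
        out.append((f"{analyte}{tissue}{i}", analyte, tissue, int(det),
                    v if det else np.nan, lod, ""))
    return out


def test_impute_nondetect_values():
    assert impute_nondetect(0.1) == pytest.approx(0.1 / np.sqrt(2))
    assert round(impute_nondetect(0.1), 2) == 0.07
    assert impute_nondetect(0.0) == 0.0
    assert impute_nondetect(0.5) == pytest.approx(0.35355339, abs=1e-7)
    with pytest.raises(ValueError):
        impute_nondetect(-0.1)


@pytest.mark.parametrize("n_det,included", [(78, True), (1, False),
                                            (10, True), (9, False)])
def test_select_analytes_detection_rule(n_det, included):
    rows = _rows("X", "non-fat", [1.0] * n_det + [np.nan] * (100 - n_det),
                 0.1, detected=[True] * n_det + [False] * (100 - n_det))
    table = make_assay_table(rows)
    got = select_analytes(table)
    assert ("X" in got) == included


def test_select_analytes_empty_table_error():
    with pytest.raises(ValueError):
        select_analytes(make_assay_table([]))


def test_summary_all_censored_collapses_to_imputed_lod():
    # all 321 non-fat records censored at LOD 0.1 -> every statistic 0.0707
    rows = _rows("TB", "non-fat", [np.nan] * 321, 0.1,
                 detected=[False] * 321)
    summ = summarize_by_tissue(make_assay_table(rows))
    r = summ.iloc[0]
    for col in ("mean_pg_mg", "p95_pg_mg", "max_pg_mg"):
        assert r[col] == pytest.approx(0.1 / np.sqrt(2))
        assert round(r[col], 2) == 0.07


def test_summary_mean_with_single_detection():
    # 99 imputed at LOD/sqrt(2) plus one detection at 7.07
    imp = 0.1 / np.sqrt(2)
    rows = _rows("X", "fat", [np.nan] * 99 + [7.07], 0.1,
                 detected=[False] * 99 + [True])
    summ = summarize_by_tissue(make_assay_table(rows))
    r = summ.iloc[0]
    assert r["mean_pg_mg"] == pytest.approx((99 * imp + 7.07) / 100)
    assert r["max_pg_mg"] == pytest.approx(7.07)
    assert r["n_detected"] == 1


def test_summary_matches_brute_force_loop(rng):
    """Vectorized summaries equal an explicit per-record loop oracle."""
    rows = []
    for analyte in ("A", "B"):
        for tissue in ("fat", "non-fat"):
            n = int(rng.integers(5, 50))
            vals = rng.lognormal(-2, 1.5, n)
            lod = 0.1
            rows += _rows(analyte, tissue, vals, lod)
    table = make_assay_table(rows)
    summ = summarize_by_tissue(table).set_index(["analyte", "tissue_class"])
    from test_quantiles import brute_force_weighted_quantile
    for (analyte, tissue), grp in table.groupby(["analyte", "tissue_class"]):
        values = []
        for _, rec in grp.iterrows():
            if rec["detected"]:
                values.append(rec["concentration_pg_mg"])
            else:
                values.append(rec["lod_pg_mg"] / np.sqrt(2))
        r = summ.loc[(analyte, tissue)]
        assert r["mean_pg_mg"] == pytest.approx(sum(values) / len(values))
        assert r["max_pg_mg"] == pytest.approx(max(values))
        assert r["p95_pg_mg"] == pytest.approx(
            brute_force_weighted_quantile(values, 0.95, [1.0] * len(values)))


def test_scenario_tables_mapping_and_monotonicity():
    summaries = pd.DataFrame([
        {"analyte": "MGA", "tissue_class": "fat", "n": 76, "n_detected": 19,
         "mean_pg_mg": 0.65, "p95_pg_mg": 3.25, "max_pg_mg": 4.07},
        {"analyte": "MGA", "tissue_class": "non-fat", "n": 321,
         "n_detected": 59, "mean_pg_mg": 0.13, "p95_pg_mg": 0.40,
         "max_pg_mg": 2.38},
    ])
    scen = build_scenario_tables(summaries).set_index(
        ["scenario", "tissue_class"])
    assert scen.loc[("typical", "fat"), "pg_per_mg"] == 0.65
    assert scen.loc[("high", "fat"), "pg_per_mg"] == 3.25
    assert scen.loc[("max", "fat"), "pg_per_mg"] == 4.07
    for tissue in ("fat", "non-fat"):
        t, h, m = (scen.loc[(s, tissue), "pg_per_mg"]
                   for s in ("typical", "high", "max"))
        assert t <= h <= m


def test_scenario_tables_all_censored_degenerate():
    v = 0.1 / np.sqrt(2)
    summaries = pd.DataFrame([
        {"analyte": "TB", "tissue_class": tc, "n": 10, "n_detected": 0,
         "mean_pg_mg": v, "p95_pg_mg": v, "max_pg_mg": v}
        for tc in ("fat", "non-fat")])
    scen = build_scenario_tables(summaries)
    assert np.allclose(scen["pg_per_mg"], v)


def test_scenario_tables_missing_tissue_hard_error():
    summaries = pd.DataFrame([{
        "analyte": "MGA", "tissue_class": "fat", "n": 5, "n_detected": 2,
        "mean_pg_mg": 0.2, "p95_pg_mg": 0.3, "max_pg_mg": 0.4}])
    with pytest.raises(ValueError, match="missing tissue"):
        build_scenario_tables(summaries)


def test_scenario_monotonicity_on_random_summaries(rng):
    rows = []
    for a in "ABCDE":
        for tc in ("fat", "non-fat"):
            vals = np.sort(rng.lognormal(0, 1, 3))
            rows.append({"analyte": a, "tissue_class": tc, "n": 3,
                         "n_detected": 3, "mean_pg_mg": vals[0],
                         "p95_pg_mg": vals[1], "max_pg_mg": vals[2]})
    scen = build_scenario_tables(pd.DataFrame(rows))
    wide = scen.pivot_table(index=["analyte", "tissue_class"],
                            columns="scenario", values="pg_per_mg")
    assert (wide["typical"] <= wide["high"]).all()
    assert (wide["high"] <= wide["max"]).all()


# -- Wilcoxon matched-pairs signed-rank --------------------------------------

def test_six_concordant_pairs_exact_p():
    pairs = [(i + 1.0, 0.5) for i in range(6)]
    w, p = paired_fat_meat_test(pairs)
    assert w == 21.0
    assert p == pytest.approx(0.03125)


def test_all_equal_pairs_no_signal():
    with pytest.warns(UserWarning, match="zero"):
        w, p = paired_fat_meat_test([(1.0, 1.0)] * 5)
    assert p == 1.0


def test_antisymmetric_pairs_centered():
    w, p = paired_fat_meat_test([(1, 0), (-1.0, 0), (0.5, 0), (-0.5, 0)])
    assert p == 1.0


@pytest.mark.parametrize("seed", range(6))
def test_exact_p_matches_enumeration_and_scipy(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    d = rng.normal(0.4, 1.0, n)
    d = d[d != 0]
    _, p = paired_fat_meat_test([(x, 0.0) for x in d])
    assert p == pytest.approx(exact_signed_rank_reference(d), abs=1e-12)
    if len(np.unique(np.abs(d))) == len(d):   # scipy exact needs no ties
        sp = stats.wilcoxon(d, mode="exact")
        assert p == pytest.approx(sp.pvalue, abs=1e-12)


def test_large_sample_normal_approximation():
    rng = np.random.default_rng(3)
    d = rng.normal(0.25, 1.0, 80)
    _, p = paired_fat_meat_test([(x, 0.0) for x in d])
    sp = stats.wilcoxon(d, correction=True, mode="approx")
    assert p == pytest.approx(sp.pvalue, rel=1e-6)
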