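"""Fay-BRR replication, median-intake ratios, and subgroup-effect recovery."""

import numpy as np
import pandas as pd
import pytest

from hgpintake.disparities import (BrrDesign, build_replicate_weights,
                                   median_intake_ratio, fay_variance,
                                   brr_ci, intake_ratio_table)
from hgpintake.quantiles import weighted_median
from hgpintake.synthdata import TruthConfig, generate_all
from hgpintake.design import cohort_of_age


def _persons(n, n_strata, weights=None, seed=0):
    rng = np.random.default_rng(seed)
    slot = rng.permutation(n) % (2 * n_strata)
    return pd.DataFrame({
        "weight": np.ones(n) if weights is None else weights,
        "pseudo_stratum": slot // 2 + 1,
        "half_sample": slot % 2 + 1,
    })


def test_fay_factor_one_reproduces_base_weights():
    persons = _persons(40, 4, weights=np.linspace(1, 5, 40))
    reps = build_replicate_weights(persons, BrrDesign(8, fay_factor=1.0))
    assert np.allclose(reps, persons["weight"].to_numpy()[:, None])


def test_hand_built_two_strata_four_replicates():
    """2 strata x 2 units, 4 replicates, F=0.3: factors follow the
    Hadamard(4) pattern (all-ones column dropped) with (2-F)=1.7 / F=0.3."""
    persons = pd.DataFrame({
        "weight": [1.0, 1.0, 1.0, 1.0],
        "pseudo_stratum": [1, 1, 2, 2],
        "half_sample": [1, 2, 1, 2],
    })
    reps = build_replicate_weights(persons, BrrDesign(4, fay_factor=0.3))
    # Hadamard(4) columns 1 and 2: stratum 1 -> [+,-,+,-], stratum 2 -> [+,+,-,-]
    expected = np.array([
        [1.7, 0.3, 1.7, 0.3],     # stratum 1, unit 1
        [0.3, 1.7, 0.3, 1.7],     # stratum 1, unit 2
        [1.7, 1.7, 0.3, 0.3],     # stratum 2, unit 1
        [0.3, 0.3, 1.7, 1.7],     # stratum 2, unit 2
    ])
    assert np.allclose(reps, expected)


def test_replicate_totals_match_full_sample():
    rng = np.random.default_rng(5)
    persons = _persons(120, 8, weights=rng.lognormal(0, 0.5, 120), seed=5)
    reps = build_replicate_weights(persons, BrrDesign(16, 0.3))
    assert np.allclose(reps.sum(axis=0), persons["weight"].sum(), rtol=1e-9)


def test_stratum_with_wrong_unit_count_rejected():
    persons = pd.DataFrame({
        "weight": [1.0, 1.0, 1.0],
        "pseudo_stratum": [1, 1, 2],
        "half_sample": [1, 2, 1],
    })
    with pytest.raises(ValueError, match="half-sample"):
        build_replicate_weights(persons, BrrDesign(4, 0.3))


def test_fay_variance_hand_example():
    # R=4, F=0.3, estimates {1.0, 1.2, 0.8, 1.0} around 1.0:
    # (0 + 0.04 + 0.04 + 0) / (4 * 0.49) = 0.040816...
    assert fay_variance([1.0, 1.2, 0.8, 1.0], 1.0, 0.3) \
        == pytest.approx(0.04081632653, abs=1e-9)


def test_zero_dispersion_collapses_ci():
    persons = _persons(60, 4, seed=1)
    reps = build_replicate_weights(persons, BrrDesign(8, 0.3))
    res = brr_ci(lambda w: 2.5, reps, BrrDesign(8, 0.3), full_estimate=2.5)
    assert res.variance == 0.0
    assert res.ci_low == res.ci_high == 2.5


def test_subgroup_to_itself_ratio_one():
    rng = np.random.default_rng(7)
    vals = rng.lognormal(0, 1, 200)
    w = rng.uniform(0.5, 2, 200)
    mask = np.ones(200, dtype=bool)
    assert median_intake_ratio(vals, mask, w) == 1.0
    persons = _persons(200, 8, weights=w, seed=7)
    reps = build_replicate_weights(persons, BrrDesign(16, 0.3))
    res = brr_ci(lambda wt: median_intake_ratio(vals, mask, wt), reps,
                 BrrDesign(16, 0.3), full_estimate=1.0)
    assert res.ci_low <= 1.0 <= res.ci_high


def test_two_point_population_ratio_half():
    # small subgroup at exactly half everyone else's intake
    vals = np.array([1.0] * 90 + [0.5] * 10)
    mask = np.array([False] * 90 + [True] * 10)
    w = np.ones(100)
    assert median_intake_ratio(vals, mask, w) == pytest.approx(0.5)


def test_scale_invariance():
    rng = np.random.default_rng(9)
    vals = rng.lognormal(0, 1, 150)
    mask = rng.random(150) < 0.3
    w = rng.uniform(0.5, 2, 150)
    persons = _persons(150, 8, weights=w, seed=9)
    reps = build_replicate_weights(persons, BrrDesign(16, 0.3))

    def run(scale):
        return brr_ci(lambda wt: median_intake_ratio(scale * vals, mask, wt),
                      reps, BrrDesign(16, 0.3),
                      full_estimate=median_intake_ratio(scale * vals, mask,
                                                        w))
    a, b = run(1.0), run(1000.0)
    assert a.estimate == pytest.approx(b.estimate)
    assert a.ci_low == pytest.approx(b.ci_low)
    assert a.p_value == pytest.approx(b.p_value)


def test_zero_overall_median_rejected():
    vals = np.zeros(50)
    with pytest.raises(ZeroDivisionError):
        median_intake_ratio(vals, np.ones(50, bool), np.ones(50))


def test_failed_replicates_dropped_and_capped():
    persons = _persons(80, 8, seed=11)
    reps = build_replicate_weights(persons, BrrDesign(16, 0.3))
    calls = {"n": 0}

    def flaky(w):
        calls["n"] += 1
        if calls["n"] % 8 == 0:
            raise RuntimeError("no convergence")
        return 1.0 + 0.01 * calls["n"]

    res = brr_ci(flaky, reps, BrrDesign(16, 0.3), full_estimate=1.0)
    assert res.n_replicates_failed == 2
    assert res.n_replicates_used == 14

    def always_fail(w):
        raise RuntimeError("boom")

    with pytest.raises(RuntimeError, match="failed"):
        brr_ci(always_fail, reps, BrrDesign(16, 0.3), full_estimate=1.0)


def test_known_subgroup_effect_recovered():
    """A built-in 0.52x amount multiplier for one subgroup is recovered by
    the median intake ratio within its BRR confidence interval."""
    cfg = TruthConfig(
        n_persons=2500, seed=33,
        amount_multipliers=(("race_ethnicity", "NH-Asian", 0.52),))
    data = generate_all(cfg)
    persons = data.persons
    child = cohort_of_age(persons["age"].to_numpy()) == "child"
    sub_p = persons[child].reset_index(drop=True)
    per_kg = (data.truth.true_usual_g[child].to_numpy()
              / sub_p["bodyweight_kg"].to_numpy())
    mask = (sub_p["race_ethnicity"] == "NH-Asian").to_numpy()
    w = sub_p["weight"].to_numpy()
    ratio = median_intake_ratio(per_kg, mask, w)
    reps = build_replicate_weights(sub_p, BrrDesign(32, 0.3))
    res = brr_ci(lambda wt: median_intake_ratio(per_kg, mask, wt), reps,
                 BrrDesign(32, 0.3), full_estimate=ratio)
    assert 0.3 < ratio < 0.8
    assert res.ci_low <= 0.52 <= res.ci_high
    # truth bookkeeping agrees
    truth_ratio = data.truth.subgroup_median_ratios[
        ("children", "race_ethnicity", "NH-Asian")]
    assert ratio == pytest.approx(truth_ratio)


def test_intake_ratio_table_smoke(synth_data):
    persons = synth_data.persons
    per_kg = (synth_data.truth.true_usual_g.to_numpy()
              / persons["bodyweight_kg"].to_numpy())
    table = intake_ratio_table(per_kg, persons, BrrDesign(32, 0.3))
    assert {"children", "women"} == set(table["cohort"])
    assert (table["ratio"] > 0).all()
    assert (table["ci_low"] <= table["ratio"]).all()
    assert (table["ratio"] <= table["ci_high"]).all()
    women_dims = set(table.loc[table.cohort == "women", "dimension"])
    assert "education" in women_dims
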