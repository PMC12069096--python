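"""Two-part mixed model: transform, likelihood, fit, simulation, summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from hgpintake.design import build_design_matrix, design_columns
from hgpintake.quantiles import weighted_quantile
from hgpintake.synthdata import (TruthConfig, generate_population,
                                 simulate_person_days)
from hgpintake.twopart import (TwoPartMixedModel, TwoPartParams,
                               UsualIntakeDraws, boxcox, inv_boxcox,
                               simulate_usual_intake, summarize_groups)

from conftest import CHILD_COLS, recovery_truth


# -- Box-Cox -----------------------------------------------------------------

def test_boxcox_lambda_one_is_shift():
    x = np.array([0.5, 1.0, 7.3])
    assert np.allclose(boxcox(x, 1.0), x - 1.0)


def test_boxcox_small_lambda_approaches_log():
    assert boxcox(np.e, 1e-8) == pytest.approx(1.0, abs=1e-6)
    assert boxcox(np.e, 0.0) == pytest.approx(1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0.01, 1.0), st.floats(0.01, 1000.0))
def test_boxcox_round_trip(lam, x):
    assert inv_boxcox(boxcox(x, lam), lam) == pytest.approx(x, rel=1e-9)


def test_boxcox_domain_errors():
    with pytest.raises(ValueError):
        boxcox(-1.0, 0.5)
    with pytest.raises(ValueError):
        inv_boxcox(-10.0, 0.5)     # 1 + lam*y < 0


# -- design vectors ----------------------------------------------------------

def test_child_spline_zero_at_knot():
    df = pd.DataFrame({"gender": ["F"], "age": [11.0],
                       "end_of_week": [0], "second_recall": [0]})
    X = build_design_matrix(df, "child")
    assert X.loc[0, "age_sp11"] == 0.0


def test_day_attribute_indicators():
    df = pd.DataFrame({"gender": ["M"], "age": [30.0],
                       "end_of_week": [1], "second_recall": [1]})
    X = build_design_matrix(df, "adult")
    assert X.loc[0, "end_of_week"] == 1.0
    assert X.loc[0, "second_recall"] == 1.0
    assert X.loc[0, "age_sp29"] == 1.0          # max(30-29, 0)


def test_cohort_age_bounds_enforced():
    child = pd.DataFrame({"gender": ["F"], "age": [25.0],
                          "end_of_week": [0], "second_recall": [0]})
    with pytest.raises(ValueError):
        build_design_matrix(child, "child")
    adult = pd.DataFrame({"gender": ["F"], "age": [12.0],
                          "end_of_week": [0], "second_recall": [0]})
    with pytest.raises(ValueError):
        build_design_matrix(adult, "adult")


# -- likelihood --------------------------------------------------------------

def _small_model(n=60, seed=0, **kw):
    rng = np.random.default_rng(seed)
    persons = pd.DataFrame({
        "person_id": [f"P{i:04d}" for i in range(n)],
        "gender": rng.choice(["F", "M"], n),
        "age": rng.integers(1, 20, n).astype(float),
        "weight": np.exp(rng.normal(0, 0.4, n)),
    })
    frame = simulate_person_days(persons, {"child": recovery_truth()}, seed)
    return TwoPartMixedModel.from_dataframe(frame, "child", **kw)


def test_analytic_gradient_matches_finite_differences():
    model = _small_model(n=50, seed=1, n_quad=9)
    theta = model._start_params(np.random.default_rng(0))
    _, grad, _ = model.loglike_components(theta)
    num = np.empty_like(theta)
    for j in range(theta.size):
        e = 1e-6
        tp, tm = theta.copy(), theta.copy()
        tp[j] += e
        tm[j] -= e
        num[j] = (model.loglike(tp) - model.loglike(tm)) / (2 * e)
    assert np.allclose(grad, num, rtol=1e-5, atol=1e-6)


def test_loglik_highest_near_truth():
    """Consistency smoke: truth beats perturbed parameter sets."""
    cfg = TruthConfig(n_persons=1200, age_range=(1, 19), seed=13)
    persons = generate_population(cfg)
    truth = recovery_truth()
    frame = simulate_person_days(persons, {"child": truth}, 77)
    model = TwoPartMixedModel.from_dataframe(frame, "child")
    theta_true = model._pack_natural(truth)
    ll_true = model.loglike(theta_true)
    rng = np.random.default_rng(0)
    for _ in range(5):
        ll_pert = model.loglike(theta_true + rng.normal(0, 0.25,
                                                        theta_true.shape))
        assert ll_true > ll_pert


def test_degenerate_outcomes_rejected():
    p = len(design_columns("child"))
    X = np.ones((20, p))
    idx = np.repeat(np.arange(10), 2)
    w = np.ones(20)
    with pytest.raises(ValueError, match="degenerate"):
        TwoPartMixedModel(idx, X, np.zeros(20), w, "child")
    with pytest.raises(ValueError, match="degenerate"):
        TwoPartMixedModel(idx, X, np.ones(20), w, "child")


def test_reduces_to_weighted_lmm_when_always_consuming():
    """With P(consumption) ~ 1, negligible probability random effect and
    lambda pinned at 1, the amount part must match an independent
    closed-form Gaussian ML oracle (2x2 marginal covariance per person)."""
    cfg = TruthConfig(n_persons=600, age_range=(1, 19), seed=14)
    persons = generate_population(cfg)
    truth = TwoPartParams(
        beta_prob=pd.Series([3.5, 0, 0, 0, 0, 0, 0, 0], index=CHILD_COLS),
        beta_amount=pd.Series([50.0, 1.0, 0.3, 0, 0, 0, 0.5, -0.3],
                              index=CHILD_COLS),
        var_u1=1e-4, var_u2=4.0, rho=0.0, var_eps=3.0, lam=1.0,
        cohort="child")
    frame = simulate_person_days(persons, {"child": truth}, 1234)
    assert 0.9 < (frame["amount"] > 0).mean() < 1.0
    model = TwoPartMixedModel.from_dataframe(
        frame, "child", lam_bounds=(1 - 1e-9, 1.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(seed=0)
    p = res.params

    # oracle: weighted Gaussian ML on positive amounts, beta profiled by GLS
    pos = frame[frame["amount"] > 0]
    X = build_design_matrix(pos, "child").to_numpy()
    z = pos["amount"].to_numpy() - 1.0            # g(R; 1) = R - 1
    pid, _ = pd.factorize(pos["person_id"])
    w = pos.groupby("person_id")["weight"].first()
    w = (w / w.mean()).to_numpy()

    def neg_ll(par):
        vu, ve = np.exp(par)
        XtVX = 0.0
        XtVz = 0.0
        pieces = []
        for i in np.unique(pid):
            idx = pid == i
            k = idx.sum()
            V = vu * np.ones((k, k)) + ve * np.eye(k)
            Vi = np.linalg.inv(V)
            Xi, zi = X[idx], z[idx]
            XtVX = XtVX + w[i] * Xi.T @ Vi @ Xi
            XtVz = XtVz + w[i] * Xi.T @ Vi @ zi
            pieces.append((i, Xi, zi, Vi, np.linalg.slogdet(V)[1], k))
        beta = np.linalg.solve(XtVX, XtVz)
        ll = 0.0
        for i, Xi, zi, Vi, ld, k in pieces:
            r = zi - Xi @ beta
            ll += w[i] * (-0.5 * (ld + r @ Vi @ r + k * np.log(2 * np.pi)))
        return -ll, beta

    opt = minimize(lambda t: neg_ll(t)[0], np.log([2.0, 2.0]),
                   method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10})
    vu, ve = np.exp(opt.x)
    beta_oracle = neg_ll(opt.x)[1]

    assert p.var_u2 == pytest.approx(vu, rel=0.02)
    assert p.var_eps == pytest.approx(ve, rel=0.02)
    assert np.allclose(p.beta_amount.to_numpy(), beta_oracle,
                       rtol=0.02, atol=0.05)


def test_quadrature_doubling_leaves_fit_unchanged():
    cfg = TruthConfig(n_persons=500, age_range=(1, 19), seed=15)
    persons = generate_population(cfg)
    frame = simulate_person_days(persons, {"child": recovery_truth()}, 31)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m15 = TwoPartMixedModel.from_dataframe(frame, "child", n_quad=15)
        r15 = m15.fit(seed=0)
        m30 = TwoPartMixedModel.from_dataframe(frame, "child", n_quad=30)
        r30 = m30.fit(start_params=r15.params, seed=0)
    v15 = r15.param_table["estimate"].to_numpy()
    v30 = r30.param_table["estimate"].to_numpy()
    assert np.linalg.norm(v30 - v15) / np.linalg.norm(v15) < 1e-3


def test_single_fit_parameter_recovery_smoke():
    cfg = TruthConfig(n_persons=1000, age_range=(1, 19), seed=16)
    persons = generate_population(cfg)
    truth = recovery_truth()
    frame = simulate_person_days(persons, {"child": truth}, 321)
    model = TwoPartMixedModel.from_dataframe(frame, "child")
    res = model.fit(seed=0)
    assert res.converged
    fe_true = np.r_[truth.beta_prob.to_numpy(),
                    truth.beta_amount.to_numpy()]
    fe = res.fixed_effects
    z = (fe["estimate"].to_numpy() - fe_true) / fe["se"].to_numpy()
    assert np.abs(z).max() < 4.0
    p = res.params
    assert p.lam == pytest.approx(truth.lam, abs=0.08)
    for name in ("var_u1", "var_u2", "var_eps"):
        assert getattr(p, name) == pytest.approx(getattr(truth, name),
                                                 rel=0.4)
    assert "converged: True" in res.summary()


def test_small_sample_warning():
    model = _small_model(n=60, seed=3)
    assert model.n_both_day_consumers < 50
    with pytest.warns(UserWarning, match="both"):
        try:
            model.fit(seed=0, max_starts=1, maxiter=5)
        except Exception:
            pass


# -- usual-intake simulation -------------------------------------------------

def _persons_frame(n=50, seed=0):
    cfg = TruthConfig(n_persons=max(n, 200), age_range=(1, 19), n_strata=4,
                      seed=seed)
    return generate_population(cfg).head(n).reset_index(drop=True)


def test_zero_probability_gives_zero_draws():
    truth = recovery_truth()
    truth.beta_prob = truth.beta_prob.copy()
    truth.beta_prob["const"] = -60.0
    persons = _persons_frame(30)
    draws = simulate_usual_intake(truth, persons, n_sim=20, seed=1)
    assert np.allclose(draws.draws, 0.0, atol=1e-12)


def test_degenerate_randomness_gives_identical_draws():
    truth = TwoPartParams(
        beta_prob=pd.Series([0.5, 0, 0, 0, 0, 0, 0, 0], index=CHILD_COLS),
        beta_amount=pd.Series([9.0, 0, 0, 0, 0, 0, 0, 0], index=CHILD_COLS),
        var_u1=0.0, var_u2=0.0, rho=0.0, var_eps=0.0, lam=0.4,
        cohort="child")
    persons = _persons_frame(20)
    draws = simulate_usual_intake(truth, persons, n_sim=10, seed=2)
    # all covariate effects are zero -> every person identical, every draw
    assert np.allclose(draws.draws, draws.draws[0, 0])


def test_usual_intake_monotone_in_probability_intercept():
    persons = _persons_frame(40)
    lo = recovery_truth()
    hi = recovery_truth()
    hi.beta_prob = hi.beta_prob.copy()
    hi.beta_prob["const"] += 1.0
    d_lo = simulate_usual_intake(lo, persons, n_sim=30, seed=3)
    d_hi = simulate_usual_intake(hi, persons, n_sim=30, seed=3)
    assert np.all(d_hi.draws >= d_lo.draws - 1e-12)


def test_simulation_seeded_determinism():
    persons = _persons_frame(25)
    a = simulate_usual_intake(recovery_truth(), persons, n_sim=15, seed=9)
    b = simulate_usual_intake(recovery_truth(), persons, n_sim=15, seed=9)
    assert np.array_equal(a.draws, b.draws)


# -- group summaries ---------------------------------------------------------

def _draws_fixture(n_persons=6, values=None):
    persons = pd.DataFrame({
        "person_id": [f"P{i}" for i in range(n_persons)],
        "gender": ["F", "M"] * (n_persons // 2),
        "age": [3.0, 7.0, 12.0] * (n_persons // 3),
        "weight": np.ones(n_persons),
    })
    if values is None:
        values = np.tile(np.arange(1.0, 101.0), (n_persons, 1))
    return persons, UsualIntakeDraws(
        person_id=persons["person_id"].to_numpy(), draws=values,
        weights=persons["weight"].to_numpy())


def test_group_median_of_uniform_grid():
    persons, draws = _draws_fixture()
    out = summarize_groups(draws, persons)
    assert np.allclose(out["median"], 50.5)
    assert np.allclose(out["p95"], weighted_quantile(
        np.arange(1.0, 101.0), 0.95))


def test_group_weight_domination():
    persons, draws = _draws_fixture()
    persons = persons.assign(weight=[1e6, 1, 1e6, 1, 1e6, 1])
    big = np.tile(np.arange(1.0, 101.0), (6, 1))
    big[1::2] += 1000.0      # dominated persons pushed far away
    draws = UsualIntakeDraws(person_id=persons["person_id"].to_numpy(),
                             draws=big,
                             weights=persons["weight"].to_numpy())
    out = summarize_groups(draws, persons)
    # female groups contain one dominating person each with draws 1..100
    f15 = out[(out.gender == "F") & (out.age_group == "1-5")].iloc[0]
    assert f15["median"] == pytest.approx(50.5, rel=1e-3)


def test_group_summary_matches_weighted_oracle(rng):
    persons, _ = _draws_fixture()
    vals = rng.lognormal(0, 1, (6, 40))
    w = rng.uniform(0.5, 3.0, 6)
    persons = persons.assign(weight=w)
    draws = UsualIntakeDraws(person_id=persons["person_id"].to_numpy(),
                             draws=vals, weights=w)
    out = summarize_groups(draws, persons).set_index(["gender", "age_group"])
    from test_quantiles import brute_force_weighted_quantile
    for (gender, band), idx in persons.groupby(
            [persons["gender"],
             persons["age"].map({3.0: "1-5", 7.0: "6-9",
                                 12.0: "10-19"})]).groups.items():
        sub = vals[np.asarray(idx)].ravel().tolist()
        ws = np.repeat(w[np.asarray(idx)] / 40, 40).tolist()
        want = brute_force_weighted_quantile(sub, 0.95, ws)
        assert out.loc[(gender, band), "p95"] == pytest.approx(want)
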