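import numpy as np
import pandas as pd
import pytest

from coralct.driver_stats import (ModelSpec, aicc, default_models,
                                  inverse_transform_response, model_selection,
                                  ols_fit, prepare_predictors, residualize,
                                  simulate_block_environment, simulate_rates,
                                  standardized_coefficients, transform_response,
                                  validate_volumes)


# ------------------------------------------------------------- residualize

def test_residualize_linear_signal_vanishes(rng):
    depth = rng.uniform(0.5, 4.5, 20)
    dist = rng.uniform(0, 32, 20)
    vals = 2.0 + 3.0 * depth
    r = residualize(vals, depth, dist)
    assert np.abs(r).max() < 1e-10


def test_residualize_orthogonality(rng):
    depth = rng.uniform(0.5, 4.5, 20)
    dist = rng.uniform(0, 32, 20)
    r = residualize(rng.normal(size=20), depth, dist)
    assert abs(np.corrcoef(r, depth)[0, 1]) < 1e-10
    assert abs(np.corrcoef(r, dist)[0, 1]) < 1e-10


def test_residualize_matches_normal_equations(rng):
    depth = rng.uniform(0.5, 4.5, 15)
    dist = rng.uniform(0, 32, 15)
    y = rng.normal(size=15)
    X = np.column_stack([np.ones(15), depth, dist])
    beta = np.linalg.solve(X.T @ X, X.T @ y)  # brute-force normal equations
    np.testing.assert_allclose(residualize(y, depth, dist), y - X @ beta, atol=1e-10)


def test_residualize_collinear_rejected():
    d = np.linspace(0, 10, 10)
    with pytest.raises(ValueError, match="collinear"):
        residualize(np.ones(10), d, 2 * d)


# ------------------------------------------------------------- transforms

def test_sqrt_transform():
    np.testing.assert_array_equal(transform_response([0, 1, 4]), [0, 1, 2])
    x = np.array([0.3, 1.7, 0.02])
    np.testing.assert_allclose(
        inverse_transform_response(transform_response(x)), x, rtol=1e-12)
    with pytest.raises(ValueError, match="signed_sqrt"):
        transform_response([-1.0, 2.0])


def test_signed_sqrt_for_net_change():
    x = np.array([-4.0, 0.0, 9.0])
    t = transform_response(x, "signed_sqrt")
    np.testing.assert_allclose(t, [-2.0, 0.0, 3.0])
    np.testing.assert_allclose(inverse_transform_response(t, "signed_sqrt"), x)


# ------------------------------------------------------------- ols / aicc

def test_ols_logL_closed_form(rng):
    n, sigma = 50, 0.7
    x = rng.normal(size=n)
    y = 1.0 + 2.0 * x + rng.normal(0, sigma, n)
    X = np.column_stack([np.ones(n), x])
    fit = ols_fit(X, y)
    expect = -(n / 2) * (np.log(2 * np.pi * fit["rss"] / n) + 1)
    assert np.isclose(fit["logL"], expect, rtol=1e-12)


def test_ols_constant_response_r2_zero():
    X = np.ones((10, 1))
    fit = ols_fit(X, np.full(10, 3.3))
    assert fit["r_squared"] == 0.0
    assert np.isclose(fit["coefficients"][0], 3.3)


def test_ols_matches_normal_equations_oracle(rng):
    n = 25
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    y = rng.normal(size=n)
    fit = ols_fit(X, y)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(fit["coefficients"], beta, atol=1e-9)
    rss = float(((y - X @ beta) ** 2).sum())
    logL = -(n / 2) * (np.log(2 * np.pi * rss / n) + 1)
    assert np.isclose(fit["logL"], logL, rtol=1e-9)


def test_ols_rank_deficient_rejected(rng):
    x = rng.normal(size=12)
    X = np.column_stack([np.ones(12), x, 2 * x])
    with pytest.raises(ValueError, match="rank"):
        ols_fit(X, rng.normal(size=12))


def test_aicc_correction_vanishes_large_n():
    logL, m = -10.0, 3
    plain_aic = -2 * logL + 2 * m
    assert abs(aicc(logL, m, 10 ** 7) - plain_aic) < 1e-4


def test_aicc_denominator_guard():
    with pytest.raises(ValueError):
        aicc(0.0, 19, 20)


# ------------------------------------------------------------- selection

def _env_and_rates(seed=0):
    env = simulate_block_environment(20, seed=seed)
    y = simulate_rates(env, seed=seed + 1)
    return env, y


def test_single_model_ranks_first():
    env, y = _env_and_rates()
    table = model_selection([ModelSpec("pH", ("pH_mean", "pH_var"))], env, y)
    assert table.iloc[0]["Rank"] == 1
    assert table.iloc[0]["dAICc"] == 0.0


def test_penalty_prefers_smaller_of_equal_models():
    env, y = _env_and_rates(3)
    # nested models where the extra predictor adds (almost) nothing:
    # duplicate information via a noise column unrelated to y
    table = model_selection([
        ModelSpec("small", ("depth",)),
        ModelSpec("large", ("depth", "temp_covar")),
    ], env, y)
    small = table[table.Model == "small"].iloc[0]
    large = table[table.Model == "large"].iloc[0]
    assert large["-log(L)"] <= small["-log(L)"]  # logL monotone in predictors
    assert small["R2"] <= large["R2"]            # R2 monotone too
    assert small["AICc"] < large["AICc"] or large["R2"] - small["R2"] > 0.15


def test_failed_model_flagged_not_fatal():
    env, y = _env_and_rates(5)
    table = model_selection([
        ModelSpec("ok", ("depth",)),
        ModelSpec("missing", ("no_such_column",)),
    ], env, y)
    assert bool(table[table.Model == "missing"].iloc[0]["failed"])
    assert table[table.Model == "ok"].iloc[0]["Rank"] == 1


def test_selection_recovers_generative_driver_often():
    # smoke-scale version of the full 200-replicate acceptance check
    wins = 0
    for i in range(25):
        env = simulate_block_environment(20, seed=300 + i)
        y = simulate_rates(env, seed=800 + i)
        t = model_selection(default_models(), env, y)
        wins += t.iloc[0]["Model"] == "pH"
    assert wins >= 20


def test_table_has_expected_columns():
    env, y = _env_and_rates(9)
    t = model_selection(default_models(), env, y)
    assert list(t.columns[:7]) == ["Model", "k", "-log(L)", "AICc", "dAICc", "R2", "Rank"]
    # printed k = coefficients + residual variance
    assert t[t.Model == "pH"].iloc[0]["k"] == 4
    assert t[t.Model == "Full"].iloc[0]["k"] == 12
    d = t["dAICc"].to_numpy()
    assert np.isclose(np.nanmin(d), 0.0)


# ------------------------------------------------------------- std coefs

def test_single_predictor_equals_pearson_r(rng):
    env = simulate_block_environment(20, seed=12)
    y = simulate_rates(env, seed=13)
    res = standardized_coefficients(ModelSpec("Depth", ("depth",)), env, y)
    x = prepare_predictors(env)["depth"].to_numpy()
    r = np.corrcoef(x, transform_response(y))[0, 1]
    assert abs(res["abs_std_coef"].iloc[0] - abs(r)) < 1e-12


def test_scale_invariance(rng):
    env = simulate_block_environment(20, seed=14)
    y = simulate_rates(env, seed=15)
    spec = ModelSpec("pH", ("pH_mean", "pH_var"))
    a = standardized_coefficients(spec, env, y)
    b = standardized_coefficients(spec, env, 7.3 * y, response_transform="none")
    c = standardized_coefficients(spec, env, y, response_transform="none")
    np.testing.assert_allclose(b["abs_std_coef"], c["abs_std_coef"], rtol=1e-10)
    assert a.shape == (2, 3)


def test_two_predictor_matches_zscore_oracle(rng):
    env = simulate_block_environment(20, seed=16)
    y = simulate_rates(env, seed=17)
    spec = ModelSpec("pH", ("pH_mean", "pH_var"))
    res = standardized_coefficients(spec, env, y)
    # oracle: explicit z-score + normal equations
    X_all = prepare_predictors(env)
    yz = transform_response(y)
    yz = (yz - yz.mean()) / yz.std(ddof=1)
    cols = []
    for c in spec.predictors:
        v = X_all[c].to_numpy()
        cols.append((v - v.mean()) / v.std(ddof=1))
    X = np.column_stack([np.ones(20)] + cols)
    beta = np.linalg.solve(X.T @ X, X.T @ yz)
    np.testing.assert_allclose(res["abs_std_coef"], np.abs(beta[1:]), atol=1e-10)


def test_zero_variance_predictor_rejected():
    env = simulate_block_environment(20, seed=18)
    env["temp_covar"] = 0.0
    y = simulate_rates(env, seed=19)
    with pytest.raises(ValueError, match="zero-variance"):
        standardized_coefficients(ModelSpec("T", ("temp_covar",)), env, y)


# ------------------------------------------------------------- validation

def test_validate_volumes_identity():
    v = np.linspace(40, 60, 10)
    fit = validate_volumes(v, v)
    assert np.isclose(fit["slope"], 1.0, atol=1e-12)
    assert np.isclose(fit["intercept"], 0.0, atol=1e-9)
    assert np.isclose(fit["r_squared"], 1.0, atol=1e-12)


def test_validate_volumes_recovers_generating_line():
    # slope/intercept within 2 SE of truth in most seeded replicates
    hits = 0
    n_rep = 200
    for i in range(n_rep):
        rng = np.random.default_rng(4000 + i)
        buoyant = rng.uniform(40, 60, 21)
        ct = 0.96 * buoyant + 1.9 + rng.normal(0, 1.0, 21)
        fit = validate_volumes(buoyant, ct)
        import statsmodels.api as sm
        res = sm.OLS(ct, sm.add_constant(buoyant)).fit()
        ok = (abs(fit["slope"] - 0.96) <= 2 * res.bse[1]
              and abs(fit["intercept"] - 1.9) <= 2 * res.bse[0])
        hits += ok
    assert hits / n_rep >= 0.93


def test_validate_volumes_needs_three():
    with pytest.raises(ValueError):
        validate_volumes([1.0, 2.0], [1.0, 2.0])


def test_prepare_predictors_log_and_residualize():
    env = simulate_block_environment(20, seed=20)
    out = prepare_predictors(env)
    # depth/distance untouched
    np.testing.assert_array_equal(out["depth"], env["depth"])
    # residualized columns are orthogonal to the confounders
    assert abs(np.corrcoef(out["pH_mean"], env["depth"])[0, 1]) < 1e-10
    with pytest.raises(ValueError, match="log-transform"):
        bad = env.copy()
        bad.loc[bad.index[0], "chl_mean"] = -1.0
        prepare_predictors(bad)
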