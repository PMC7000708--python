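"""ML path-model estimation: discrepancy, indices, MIs, robust errors."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from zoosem.exceptions import DataError, DegenerateInputError
from zoosem.fitting import (
    cluster_robust_se,
    fit_baseline_model,
    fit_indices,
    fit_path_model,
    modification_indices,
    standardize,
)
from zoosem.model import PathModelSpec, parse_model_spec


def saturated_spec(variables):
    """Complete DAG over the variables: reproduces S exactly, df = 0."""
    edges = tuple(
        (variables[j], variables[i])
        for j in range(len(variables))
        for i in range(j)
    )
    return PathModelSpec(tuple(variables), edges)


def random_recursive_spec(variables, rng, p_edge=0.5):
    edges = [
        (variables[j], variables[i])
        for j in range(len(variables))
        for i in range(j)
        if rng.random() < p_edge
    ]
    if not edges:
        edges = [(variables[1], variables[0])]
    return PathModelSpec(tuple(variables), tuple(edges))


def random_data(variables, n, rng):
    X = rng.standard_normal((n, len(variables)))
    mix = rng.standard_normal((len(variables), len(variables))) * 0.3
    np.fill_diagonal(mix, 1.0)
    return pd.DataFrame(X @ mix, columns=variables)


# ---------------------------------------------------------------------------
# standardize
# ---------------------------------------------------------------------------


def test_standardize_simple_column():
    out = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
    assert np.allclose(out.data["x"], [-1.0, 0.0, 1.0])


def test_standardize_idempotent():
    df = pd.DataFrame({"x": np.random.default_rng(0).normal(3.0, 2.0, 50)})
    once = standardize(df).data
    twice = standardize(once).data
    assert np.allclose(once, twice, atol=1e-9)
    assert once["x"].mean() == pytest.approx(0.0, abs=1e-9)
    assert once["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_standardize_constant_column_named():
    with pytest.raises(DegenerateInputError, match="flat"):
        standardize(pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]}))


def test_standardize_missing_values_rejected():
    with pytest.raises(DataError):
        standardize(pd.DataFrame({"x": [1.0, np.nan]}))


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def test_saturated_model_reproduces_sample_covariance(rng):
    data = random_data(["a", "b", "c"], 60, rng)
    fit = fit_path_model(saturated_spec(["a", "b", "c"]), data)
    assert fit.df == 0
    assert fit.fml == pytest.approx(0.0, abs=1e-10)
    assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(fit.sigma, fit.sample_cov, atol=1e-10)
    assert fit.srmr == pytest.approx(0.0, abs=1e-8)
    assert fit.cfi == pytest.approx(1.0)


def test_chain_coefficients_recovered_at_large_n(rng):
    n = 100_000
    x = rng.standard_normal(n)
    y = 0.5 * x + rng.normal(0, np.sqrt(1 - 0.25), n)
    z = 0.4 * y + rng.normal(0, np.sqrt(1 - 0.16), n)
    data = standardize(pd.DataFrame({"x": x, "y": y, "z": z}))
    fit = fit_path_model(parse_model_spec("y ~ x\nz ~ y"), data, se=False)
    assert fit.A.loc["y", "x"] == pytest.approx(0.5, abs=0.02)
    assert fit.A.loc["z", "y"] == pytest.approx(0.4, abs=0.02)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_ml_equals_per_equation_least_squares(seed):
    """The stated oracle: ML coefficients coincide with per-equation OLS."""
    rng = np.random.default_rng(seed)
    variables = ["v1", "v2", "v3", "v4", "v5"]
    spec = random_recursive_spec(variables, rng)
    data = random_data(variables, 80, rng)
    fit = fit_path_model(spec, data, se=False)
    for y in spec.endogenous:
        pa = list(spec.parents(y))
        ols = sm.OLS(data[y], sm.add_constant(data[pa])).fit()
        assert np.allclose(
            fit.A.loc[y, pa].to_numpy(), ols.params[pa].to_numpy(), atol=1e-6
        )


def test_residual_covariance_model_uses_optimizer(rng):
    """Declared residual covariances are recovered by the numeric ML path."""
    n = 5000
    x = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2 = 0.5 * e1 + np.sqrt(1 - 0.25) * rng.standard_normal(n)
    y1 = 0.6 * x + e1
    y2 = -0.4 * x + e2
    data = pd.DataFrame({"x": x, "y1": y1, "y2": y2})
    spec = parse_model_spec("y1 ~ x\ny2 ~ x\ny1 ~~ y2")
    fit = fit_path_model(spec, data)
    assert fit.converged
    assert fit.psi.loc["y1", "y2"] == pytest.approx(0.5, abs=0.08)
    assert fit.A.loc["y1", "x"] == pytest.approx(0.6, abs=0.05)
    # frees the only constrained moment -> saturated
    assert fit.df == 0
    assert fit.chi2 == pytest.approx(0.0, abs=1e-6)


def test_standardized_coefficients_match_prestandardized_fit(rng):
    """Fitting raw data then standardizing coefficients agrees with fitting
    z-scored data (recursive-model identity)."""
    variables = ["a", "b", "c", "d"]
    raw = random_data(variables, 300, rng) * np.array([2.0, 0.5, 7.0, 1.3]) + 5.0
    spec = random_recursive_spec(variables, rng)
    fit_raw = fit_path_model(spec, raw, se=False)
    fit_std = fit_path_model(spec, standardize(raw), se=False)
    assert np.allclose(fit_raw.A_std, fit_std.A_std, atol=1e-8)
    assert fit_raw.chi2 == pytest.approx(fit_std.chi2, abs=1e-8)


def test_r2_bounds_and_aicc_exceeds_aic(rng):
    variables = ["a", "b", "c", "d"]
    data = random_data(variables, 120, rng)
    fit = fit_path_model(random_recursive_spec(variables, rng), data, se=False)
    for r in fit.r2.values():
        assert 0.0 <= r <= 1.0
    assert fit.aicc > fit.aic
    k, n = fit.n_free, fit.n
    assert fit.aicc - fit.aic == pytest.approx(2 * k * (k + 1) / (n - k - 1))


def test_small_sample_aicc_correction_arithmetic():
    # closed-form check of the correction term: k=2, n=10 -> 12/7
    k, n = 2, 10
    assert 2 * k * (k + 1) / (n - k - 1) == pytest.approx(12 / 7)


def test_n_not_exceeding_k_rejected(rng):
    variables = ["a", "b", "c", "d", "e"]
    data = random_data(variables, 12, rng)
    with pytest.raises(DataError):
        fit_path_model(saturated_spec(variables), data)  # k = 15 >= n - 1


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------


def test_cfi_zero_when_model_is_its_own_baseline(rng):
    x = rng.standard_normal(400)
    y = 0.8 * x + 0.6 * rng.standard_normal(400)
    z = 0.8 * y + 0.6 * rng.standard_normal(400)
    data = pd.DataFrame({"x": x, "y": y, "z": z})
    fit = fit_path_model(parse_model_spec("y ~ x\nz ~ x"), data, se=False)
    assert fit.chi2 > fit.df  # clearly misspecified (misses y -> z)
    self_baseline = {"chi2": fit.chi2, "df": fit.df}
    assert fit_indices(fit, self_baseline)["cfi"] == pytest.approx(0.0)


def test_fit_indices_against_explicit_baseline(rng):
    variables = ["a", "b", "c"]
    data = random_data(variables, 150, rng)
    fit = fit_path_model(parse_model_spec("b ~ a\nc ~ a"), data, se=False)
    base = fit_baseline_model(data, variables)
    out = fit_indices(fit, base)
    assert out["cfi"] == pytest.approx(fit.cfi)
    assert 0.0 <= out["cfi"] <= 1.0
    assert out["srmr"] >= 0.0


# ---------------------------------------------------------------------------
# modification indices
# ---------------------------------------------------------------------------


def test_dropped_edge_has_maximal_mi(rng):
    n = 3000
    x = rng.standard_normal(n)
    w = rng.standard_normal(n)
    y = 0.5 * x + 0.4 * w + rng.standard_normal(n) * 0.7
    z = 0.6 * y + rng.standard_normal(n) * 0.8
    data = pd.DataFrame({"x": x, "w": w, "y": y, "z": z})
    # missing y ~ w; w sits in the model as an isolated exogenous variable
    spec = PathModelSpec(("x", "w", "y", "z"), (("y", "x"), ("z", "y")))
    table = modification_indices(
        spec, data, [("y", "w"), ("z", "x"), ("z", "w"), ("x", "z")]
    )
    admissible = table[table["admissible"]]
    assert admissible.iloc[0][["lhs", "rhs"]].tolist() == ["y", "w"]
    assert (admissible["mi"] >= 0).all()
    cyclic = table[~table["admissible"]]
    assert cyclic[["lhs", "rhs"]].values.tolist() == [["x", "z"]]
    assert "cycle" in cyclic.iloc[0]["reason"]


def test_saturated_model_has_no_candidates(rng):
    variables = ["a", "b", "c"]
    data = random_data(variables, 60, rng)
    spec = saturated_spec(variables)
    absent = [
        (o, p)
        for o in variables
        for p in variables
        if o != p and (o, p) not in spec.edges
    ]
    table = modification_indices(spec, data, absent)
    # every absent edge would reverse an existing one -> cycle -> inadmissible
    assert not table["admissible"].any()


# ---------------------------------------------------------------------------
# cluster-robust standard errors
# ---------------------------------------------------------------------------


def _small_fit(rng, n=200):
    x = rng.standard_normal(n)
    y = 0.5 * x + rng.standard_normal(n) * 0.8
    data = pd.DataFrame({"x": x, "y": y})
    return fit_path_model(parse_model_spec("y ~ x"), data)


def test_cluster_se_preserves_estimates(rng):
    fit = _small_fit(rng)
    clusters = pd.Series(np.arange(fit.n) % 10)
    robust = cluster_robust_se(fit, clusters)
    assert np.allclose(robust["estimate"], fit.params["estimate"])
    assert not np.allclose(robust["se"], fit.params["se"])  # genuinely adjusted


def test_duplicated_rows_do_not_shrink_clustered_se(rng):
    fit = _small_fit(rng, n=150)
    singleton = cluster_robust_se(fit, pd.Series(np.arange(fit.n)))
    doubled = pd.concat([fit.data, fit.data], ignore_index=True)
    fit2 = fit_path_model(fit.spec, doubled)
    pair_clusters = pd.Series(np.tile(np.arange(fit.n), 2))
    paired = cluster_robust_se(fit2, pair_clusters)
    naive_ratio = fit2.params["se"].iloc[0] / fit.params["se"].iloc[0]
    robust_ratio = paired["se"].iloc[0] / singleton["se"].iloc[0]
    assert naive_ratio == pytest.approx(1 / np.sqrt(2), abs=0.03)
    assert robust_ratio == pytest.approx(1.0, abs=0.05)  # duplication adds no info


def test_single_cluster_rejected(rng):
    fit = _small_fit(rng)
    with pytest.raises(DataError):
        cluster_robust_se(fit, pd.Series(np.zeros(fit.n)))
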