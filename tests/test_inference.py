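"""Design construction, OLS/PGLS fits, and ensemble summaries."""

import numpy as np
import pandas as pd
import pytest

from trianiche.errors import InsufficientDataError
from trianiche.inference import (
    TERMS,
    build_design,
    collinearity_screen,
    fit_ols,
    fit_pgls,
    run_hypothesis_test,
    summarize_ensemble,
)
from trianiche.phylo import TopologySet, brownian_covariance
from trianiche.simulate import simulate_regression_dataset, simulate_yule_tree


def _traits(n=8, seed=0):
    tree = simulate_yule_tree(n, seed=seed)
    table, _ = simulate_regression_dataset(tree, seed=seed)
    return tree, table


# ---------------------------------------------------------------------------
# design

def test_build_design_transform_example():
    rows = [
        dict(species=f"s{i}", area_km2=np.e**2, tnb=4.0, pnb=9.0,
             **{f"dbr_{r}": 1 for r in ("class", "order", "family", "genus", "species")})
        for i in range(5)
    ]
    d = build_design(pd.DataFrame(rows), "species")
    np.testing.assert_allclose(d.y, 2.0)
    np.testing.assert_allclose(d.X[0], [1.0, 0.0, 2.0, 3.0])


def test_build_design_excludes_bad_rows():
    tree, table = _traits(8)
    table.loc[0, "dbr_species"] = 0  # cannot log
    d = build_design(table, "species")
    assert len(d.species) == 7
    assert table.loc[0, "species"] not in d.species


def test_build_design_insufficient_species():
    tree, table = _traits(8)
    with pytest.raises(InsufficientDataError):
        build_design(table.head(4), "species")


def test_designs_across_ranks_differ_only_in_diet_column():
    tree, table = _traits(10)
    designs = {r: build_design(table, r) for r in ("species", "genus", "class")}
    ref = designs["species"]
    for d in designs.values():
        np.testing.assert_allclose(d.y, ref.y)
        np.testing.assert_allclose(d.X[:, [0, 2, 3]], ref.X[:, [0, 2, 3]])


# ---------------------------------------------------------------------------
# collinearity

def test_collinearity_flags_duplicate_and_negated():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(50)
    df = pd.DataFrame({"a": x, "b": x, "c": -x, "d": rng.standard_normal(50)})
    rep = collinearity_screen(df)
    ab = rep.query("predictor_a == 'a' and predictor_b == 'b'").iloc[0]
    ac = rep.query("predictor_a == 'a' and predictor_b == 'c'").iloc[0]
    assert ab["r"] == pytest.approx(1.0) and ab["flagged"]
    assert ac["r"] == pytest.approx(-1.0) and ac["flagged"]


def test_collinearity_constant_predictor_is_nan():
    df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.1, 0.5, 0.9]})
    rep = collinearity_screen(df)
    assert np.isnan(rep.iloc[0]["r"])
    assert not rep.iloc[0]["flagged"]


def test_independent_predictors_rarely_flagged(rng):
    hits = 0
    for i in range(40):
        df = pd.DataFrame(rng.standard_normal((200, 2)), columns=["a", "b"])
        hits += int(collinearity_screen(df)["flagged"].iloc[0])
    assert hits <= 2  # |r| >= 0.4 at n=200 under independence is ~impossible


# ---------------------------------------------------------------------------
# OLS

def test_ols_exact_line():
    rng = np.random.default_rng(8)
    tnb = rng.uniform(1, 30, 10)
    pnb = rng.uniform(100, 2000, 10)
    dbr = rng.integers(1, 20, 10)
    rows = [
        dict(species=f"s{i:02d}", area_km2=float(np.exp(2 * np.sqrt(tnb[i]))),
             tnb=float(tnb[i]), pnb=float(pnb[i]),
             **{f"dbr_{r}": int(dbr[i]) for r in ("class", "order", "family", "genus", "species")})
        for i in range(10)
    ]
    d = build_design(pd.DataFrame(rows), "species")
    # y = 2*sqrt(tnb): slope on sqrt_tnb is 2, R² = 1
    fit = fit_ols(d)
    assert fit.estimates[TERMS.index("sqrt_tnb")] == pytest.approx(2.0, abs=1e-10)
    assert fit.r_squared == pytest.approx(1.0)


def test_ols_matches_normal_equations_oracle():
    tree, table = _traits(30, seed=3)
    d = build_design(table, "species")
    fit = fit_ols(d)
    beta = np.linalg.inv(d.X.T @ d.X) @ d.X.T @ d.y
    np.testing.assert_allclose(fit.estimates, beta, atol=1e-10)


# ---------------------------------------------------------------------------
# PGLS

def test_pgls_lambda_zero_equals_ols():
    tree, table = _traits(20, seed=5)
    d = build_design(table, "species")
    ols = fit_ols(d)
    pgls = fit_pgls(d, tree, lam=0.0)
    np.testing.assert_allclose(pgls.estimates, ols.estimates, atol=1e-8)
    np.testing.assert_allclose(pgls.ses, ols.ses, atol=1e-8)


def test_pgls_loglik_optimal_at_lambda_hat():
    tree, table = _traits(25, seed=7)
    d = build_design(table, "species")
    fit = fit_pgls(d, tree)
    for endpoint in (0.0, 1.0):
        other = fit_pgls(d, tree, lam=endpoint)
        assert fit.loglik >= other.loglik - 1e-8


def test_pgls_matches_statsmodels_gls_at_fixed_lambda():
    import statsmodels.api as sm

    from trianiche.phylo import lambda_transform

    tree, table = _traits(18, seed=9)
    d = build_design(table, "species")
    C = brownian_covariance(tree)
    V = lambda_transform(C.restrict(d.species), 0.6).matrix
    ours = fit_pgls(d, tree, lam=0.6)
    ref = sm.GLS(d.y, d.X, sigma=V).fit()
    np.testing.assert_allclose(ours.estimates, ref.params, atol=1e-8)
    np.testing.assert_allclose(ours.ses, ref.bse, atol=1e-8)
    np.testing.assert_allclose(ours.p_values, ref.pvalues, atol=1e-8)


def test_pgls_invariant_to_species_reordering():
    tree, table = _traits(15, seed=11)
    d = build_design(table, "species")
    shuffled = table.sample(frac=1, random_state=4)
    d2 = build_design(shuffled, "species")
    f1, f2 = fit_pgls(d, tree), fit_pgls(d2, tree)
    np.testing.assert_allclose(f1.estimates, f2.estimates, atol=1e-10)


# ---------------------------------------------------------------------------
# ensembles and the full test

def test_summarize_ensemble_constant():
    s = summarize_ensemble([3.14] * 7)
    assert (s.median, s.q2_5, s.q97_5) == (3.14, 3.14, 3.14)


def test_summarize_ensemble_quantile_oracle():
    s = summarize_ensemble(np.arange(1, 1001, dtype=float))
    assert s.median == pytest.approx(500.5)
    assert s.q2_5 == pytest.approx(25.975)
    assert s.q97_5 == pytest.approx(975.025)


def test_summarize_ensemble_order_invariant(rng):
    vals = rng.standard_normal(100)
    a, b = summarize_ensemble(vals), summarize_ensemble(vals[::-1])
    assert (a.q2_5 <= a.median <= a.q97_5)
    assert a == b


def test_summarize_ensemble_all_failed():
    with pytest.raises(InsufficientDataError):
        summarize_ensemble([np.nan, np.inf])


def test_hypothesis_test_universal_habitat_equals_all():
    tree, table = _traits(15, seed=13)
    for c in ("domiciliary", "peridomiciliary", "sylvatic"):
        table[c] = True
    res = run_hypothesis_test(table, tree, diet_ranks=("species",))
    est = res.ols.pivot_table(index="term", columns="stratum", values="estimate")
    for stratum in ("domiciliary", "peridomiciliary", "sylvatic"):
        np.testing.assert_allclose(est[stratum], est["all"], atol=1e-12)


def test_hypothesis_test_single_topology_medians_are_point_estimates():
    tree, table = _traits(15, seed=17)
    res = run_hypothesis_test(table, TopologySet([tree]), diet_ranks=("species",))
    ens = res.pgls_ensemble.query("quantity == 'estimate' and stratum == 'all'")
    d = build_design(table, "species")
    fit = fit_pgls(d, tree)
    for term, est in zip(TERMS, fit.estimates):
        row = ens[ens["term"] == term].iloc[0]
        assert row["median"] == pytest.approx(est)
        assert row["q2.5"] == pytest.approx(est)


def test_hypothesis_test_skips_small_strata():
    tree, table = _traits(12, seed=19)
    table["domiciliary"] = [True] * 3 + [False] * 9
    table["peridomiciliary"] = True
    table["sylvatic"] = True
    res = run_hypothesis_test(table, tree, diet_ranks=("species",))
    assert any(s.startswith("domiciliary") for s in res.skipped_strata)
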