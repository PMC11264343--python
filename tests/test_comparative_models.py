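"""PGLMM fitting, phylogenetic correlation and group t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mastphylo as mp
from mastphylo.comparative_models import (ModelSpec, fit_pglmm, group_t_test,
                                          phylo_correlation,
                                          univariate_height_model)
from mastphylo.errors import DegenerateInputError, InvalidInputError


@pytest.fixture
def toy_C():
    return mp.PhyloCovariance(np.array([[2.0, 1.0, 0.0],
                                        [1.0, 2.0, 0.0],
                                        [0.0, 0.0, 2.0]]), ("A", "B", "C"))


def test_gls_mean_matches_hand_inversion(toy_C):
    """Intercept-only GLS at fixed sigma2_p = sigma2_e = 1 equals
    (1'V^-1 y)/(1'V^-1 1) with V = C + I, inverted by hand."""
    traits = pd.DataFrame({"y": [1.0, 2.0, 3.0]}, index=["A", "B", "C"])
    fit = fit_pglmm(ModelSpec("y", ()), traits, toy_C, fixed_variance=(1.0, 1.0))
    V = toy_C.matrix + np.eye(3)
    Vi = np.linalg.inv(V)
    one = np.ones(3)
    y = np.array([1.0, 2.0, 3.0])
    assert fit.beta[0] == pytest.approx((one @ Vi @ y) / (one @ Vi @ one), abs=1e-12)


def test_identity_covariance_collapses_to_ols(rng):
    n = 40
    x = rng.standard_normal(n)
    y = 0.7 + 0.4 * x + rng.standard_normal(n)
    idx = [f"s{i}" for i in range(n)]
    traits = pd.DataFrame({"y": y, "x": x}, index=idx)
    ols = fit_pglmm(ModelSpec("y", ("x",), include_phylogeny=False), traits)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    r = y - X @ beta
    s2 = r @ r / n
    ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1)
    np.testing.assert_allclose(ols.beta, beta, rtol=1e-6)
    assert ols.logLik == pytest.approx(ll, rel=1e-6)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
    np.testing.assert_allclose(ols.se, se, rtol=1e-6)
    assert ols.sigma2_phylo == 0.0
    assert ols.aic == pytest.approx(-2 * ll + 2 * 3)


def test_z_invariant_to_predictor_rescaling(rng):
    tree = mp.simulate_tree(50, seed=1)
    C = mp.covariance_from_tree(tree)
    x = mp.simulate_continuous_trait(tree, 0.8, 1.0, seed=2, C=C)
    y = 0.3 * x.values + rng.standard_normal(50)
    traits = pd.DataFrame({"y": y, "x": x.values}, index=list(tree.tip_labels))
    f1 = fit_pglmm(ModelSpec("y", ("x",)), traits, C)
    traits2 = traits.assign(x=traits.x * 37.0 + 5.0)
    f2 = fit_pglmm(ModelSpec("y", ("x",)), traits2, C)
    assert abs(f1.z[1] - f2.z[1]) < 1e-6
    assert f1.beta[1] == pytest.approx(37.0 * f2.beta[1], rel=1e-6)


def test_pglmm_likelihood_beats_random_variance_probes(rng):
    tree = mp.simulate_tree(60, seed=3)
    C = mp.covariance_from_tree(tree)
    ds = mp.simulate_full_dataset(mp.SimulationConfig(n_species=60, seed=3))
    t = ds.traits.copy()
    t["log_height"] = np.log10(t.height_m)
    t["log_D"] = np.log10(t.D)
    Cn = mp.covariance_from_tree(ds.tree)
    spec = ModelSpec("log_D", ("log_height",))
    fit = fit_pglmm(spec, t, Cn)
    for _ in range(20):
        s2p, s2e = rng.uniform(0.01, 2.0, size=2)
        probe = fit_pglmm(spec, t, Cn, fixed_variance=(s2p, s2e))
        assert fit.logLik >= probe.logLik - 1e-6


def test_variance_ratio_recovery():
    """Median sigma2_p/sigma2_e over replicates near the generating ratio 1."""
    ratios = []
    for s in range(30):
        ds = mp.simulate_full_dataset(mp.SimulationConfig(n_species=150, seed=600 + s))
        t = ds.traits.copy()
        t["log_height"] = np.log10(t.height_m)
        t["log_D"] = np.log10(t.D)
        Cn = mp.covariance_from_tree(ds.tree)
        f = fit_pglmm(ModelSpec("log_D", ("log_height", "pollination")), t, Cn)
        ratios.append(f.sigma2_phylo / f.sigma2_resid)
    assert 0.5 <= np.median(ratios) <= 2.0


def test_design_matrix_errors(toy_C):
    traits = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [1.0, 1.0, 1.0]},
                          index=["A", "B", "C"])
    with pytest.raises(InvalidInputError, match="collinear"):
        fit_pglmm(ModelSpec("y", ("x",), include_phylogeny=False), traits)
    with pytest.raises(InvalidInputError):
        ModelSpec("y", ("y",))
    with pytest.raises(InvalidInputError, match="absent"):
        fit_pglmm(ModelSpec("y", ("nope",)), traits, toy_C)


def test_univariate_model_sign_and_subsets():
    ds = mp.simulate_full_dataset(mp.SimulationConfig(n_species=120, seed=9,
                                                      beta_height=0.5))
    t = ds.traits.copy()
    t["log_height"] = np.log10(t.height_m)
    t["log_D"] = np.log10(t.D)
    C = mp.covariance_from_tree(ds.tree)
    fit = univariate_height_model(t, C)
    assert fit.z[1] > 0
    sub = univariate_height_model(t, C, subset=("pollination", "anemophilous"))
    assert sub.n < fit.n
    with pytest.raises(InvalidInputError, match="< 5"):
        tiny = t.iloc[:6].copy()
        tiny.loc[tiny.index[:4], "pollination"] = "anemophilous"
        tiny.loc[tiny.index[4:], "pollination"] = "entomophilous"
        univariate_height_model(tiny, C, subset=("pollination", "entomophilous"))


def test_correlation_identical_traits(yule20):
    x = mp.simulate_continuous_trait(yule20, 1.0, 1.0, seed=4)
    res = phylo_correlation(x, x, yule20)
    assert res.R == pytest.approx(1.0) and res.p_value == 0.0


def test_correlation_star_tree_equals_pearson(rng):
    n = 15
    labels = [f"t{i}" for i in range(n)]
    star = mp.parse_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    res = phylo_correlation(dict(zip(labels, x)), dict(zip(labels, y)), star)
    assert res.R == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)


def test_correlation_gls_variant(yule20):
    x = mp.simulate_continuous_trait(yule20, 1.0, 1.0, seed=4)
    y = mp.simulate_continuous_trait(yule20, 1.0, 1.0, seed=5)
    res = phylo_correlation(x, y, yule20, method="gls")
    assert -1.0 <= res.R <= 1.0 and 0.0 <= res.p_value <= 1.0
    with pytest.raises(DegenerateInputError):
        phylo_correlation(x, pd.Series(1.0, index=x.index), yule20)


def test_group_t_test_welch_oracle():
    """Hand Welch example on the raw scale: (1,2,3) vs (2,3,4)."""
    vals = pd.Series([1.0, 2, 3, 2, 3, 4])
    grp = pd.Series(["a"] * 3 + ["b"] * 3)
    res = group_t_test(vals, grp, log10=False, welch=True)
    assert res.t == pytest.approx(-1.224745, abs=1e-6)
    assert res.df == pytest.approx(4.0, abs=1e-9)
    assert res.p_value == pytest.approx(0.287823, abs=1e-4)
    assert np.sign(res.t) == np.sign(res.means[0] - res.means[1])


def test_group_t_test_identical_and_errors():
    vals = pd.Series([1.0, 2, 3, 1, 2, 3])
    grp = pd.Series(["a"] * 3 + ["b"] * 3)
    res = group_t_test(vals, grp, log10=False)
    assert res.t == 0.0 and res.p_value == pytest.approx(1.0)
    with pytest.raises(InvalidInputError):
        group_t_test(pd.Series([1.0, 2]), pd.Series(["a", "a"]))
    with pytest.raises(InvalidInputError, match=">= 2"):
        group_t_test(pd.Series([1.0, 2, 3]), pd.Series(["a", "a", "b"]))
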