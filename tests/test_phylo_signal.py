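"""Pagel's lambda fitting and the Fritz–Purvis D statistic."""

from itertools import combinations

import numpy as np
import pytest

import mastphylo as mp
from mastphylo.errors import DegenerateInputError, InvalidInputError
from mastphylo.phylo_signal import (fit_pagel_lambda, fritz_purvis_d,
                                    lambda_randomization_test,
                                    sister_difference_sum)


def _grid_loglik(C, y, lam):
    """Independent profiled likelihood: dense MVN algebra, no eigen tricks."""
    n = len(y)
    M = C.matrix
    V = lam * (M - np.diag(np.diag(M))) + np.diag(np.diag(M))
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    mu = (one @ Vi @ y) / (one @ Vi @ one)
    r = y - mu
    s2 = (r @ Vi @ r) / n
    sign, logdet = np.linalg.slogdet(V)
    return -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdet + n)


def test_lambda_matches_grid_search_oracle(tree5, trait5):
    C = mp.covariance_from_tree(tree5)
    fit = fit_pagel_lambda(trait5, C)
    y = np.array([trait5[l] for l in C.labels])
    grid = np.arange(0.0, 1.0001, 0.001)
    lls = np.array([_grid_loglik(C, y, l) for l in grid])
    assert abs(fit.lambda_hat - grid[lls.argmax()]) <= 0.002
    assert fit.logLik_at_hat >= lls.max() - 1e-6
    assert fit.logLik_at_zero == pytest.approx(_grid_loglik(C, y, 0.0), abs=1e-8)


def test_lambda_hat_beats_grid_on_random_instances(rng):
    for seed in range(5):
        tree = mp.simulate_tree(30, seed=seed)
        C = mp.covariance_from_tree(tree)
        y = mp.simulate_continuous_trait(tree, 0.6, 1.0, seed=seed, C=C)
        fit = fit_pagel_lambda(y, C)
        yv = np.array([y[l] for l in C.labels])
        for lam in np.linspace(0, 1, 25):
            assert fit.logLik_at_hat >= _grid_loglik(C, yv, lam) - 1e-6
        assert fit.logLik_at_hat >= fit.logLik_at_zero - 1e-8
        assert 0.0 <= fit.lambda_hat <= 1.0


def test_lambda_brownian_vs_shuffled(rng):
    tree = mp.simulate_tree(200, seed=77)
    C = mp.covariance_from_tree(tree)
    y = mp.simulate_continuous_trait(tree, 1.0, 1.0, seed=8, C=C)
    assert fit_pagel_lambda(y, C).lambda_hat > 0.85
    yp = rng.permutation(y.values)
    assert fit_pagel_lambda(yp, C).lambda_hat < 0.15


def test_lambda_star_tree_flagged_unidentifiable():
    star = mp.parse_newick("(A:1,B:1,C:1,D:1,E:1);")
    C = mp.covariance_from_tree(star)
    fit = fit_pagel_lambda({"A": 1, "B": 2, "C": 0, "D": 1.5, "E": -1}, C)
    assert fit.unidentifiable and fit.lambda_hat == 0.0 and fit.p_value == 1.0


def test_lambda_degenerate_inputs(tree5):
    C = mp.covariance_from_tree(tree5)
    with pytest.raises(DegenerateInputError):
        fit_pagel_lambda({l: 3.0 for l in C.labels}, C)
    with pytest.raises(InvalidInputError):
        lambda_randomization_test({l: float(i) for i, l in enumerate(C.labels)},
                                  C, n_perm=0)


def test_lambda_randomization_detects_brownian_signal():
    tree = mp.simulate_tree(120, seed=5)
    C = mp.covariance_from_tree(tree)
    y = mp.simulate_continuous_trait(tree, 1.0, 1.0, seed=6, C=C)
    p = lambda_randomization_test(y, C, n_perm=99, seed=1)
    assert p <= 0.05


@pytest.mark.parametrize("trait, expected", [
    ({"A": 1, "B": 1, "C": 0, "D": 0}, 1.0),   # perfectly clumped
    ({"A": 1, "B": 0, "C": 1, "D": 0}, 2.0),   # alternating
])
def test_sister_difference_sum_hand_traversals(balanced4, trait, expected):
    assert sister_difference_sum(balanced4, trait) == pytest.approx(expected)


def test_sister_difference_monomorphic_errors(balanced4):
    with pytest.raises(DegenerateInputError):
        sister_difference_sum(balanced4, {"A": 1, "B": 1, "C": 1, "D": 1})


def test_fritz_purvis_exhaustive_random_null_oracle():
    """mean_d_random from the exhaustive mode equals the enumeration mean."""
    tree = mp.simulate_tree(6, seed=2)
    labels = tree.tip_labels
    trait = {l: (1.0 if i < 2 else 0.0) for i, l in enumerate(labels)}
    res = fritz_purvis_d(tree, trait, n_sim=100, seed=0, random_null="exhaustive")
    d_all = []
    for ones in combinations(labels, 2):
        t = {l: (1.0 if l in ones else 0.0) for l in labels}
        d_all.append(sister_difference_sum(tree, t))
    assert res.mean_d_random == pytest.approx(np.mean(d_all), abs=1e-12)


def test_fritz_purvis_reproducible_and_valid(yule20):
    trait = mp.simulate_binary_trait(yule20, "shuffle", 0.5, seed=9)
    r1 = fritz_purvis_d(yule20, trait, n_sim=200, seed=3)
    r2 = fritz_purvis_d(yule20, trait, n_sim=200, seed=3)
    assert r1.D_stat == r2.D_stat and r1.Pr == r2.Pr and r1.Pb == r2.Pb
    np.testing.assert_array_equal(r1.null_random, r2.null_random)
    assert 0.0 <= r1.Pr <= 1.0 and 0.0 <= r1.Pb <= 1.0
    # stored standardisation identity
    assert r1.D_stat == pytest.approx(
        (r1.d_obs - r1.mean_d_brownian) / (r1.mean_d_random - r1.mean_d_brownian))
    # +1 pseudo-count: p-values can never reach 0
    assert r1.Pr >= 1 / 201 and r1.Pb >= 1 / 201


def test_fritz_purvis_preconditions(yule20):
    with pytest.raises(DegenerateInputError):
        fritz_purvis_d(yule20, {l: 1.0 for l in yule20.tip_labels}, n_sim=100)
    trait = mp.simulate_binary_trait(yule20, "shuffle", 0.5, seed=9)
    with pytest.raises(InvalidInputError):
        fritz_purvis_d(yule20, trait, n_sim=10)


def test_fritz_purvis_regime_means_small_sample():
    """Smoke-scale calibration (the full 200-replicate version is in the
    acceptance suite): Brownian-threshold traits score near 0, shuffled near 1."""
    db, dr = [], []
    for s in range(25):
        tree = mp.simulate_tree(80, seed=300 + s)
        yb = mp.simulate_binary_trait(tree, "brownian_threshold", 0.5, seed=s)
        yr = mp.simulate_binary_trait(tree, "shuffle", 0.5, seed=s)
        db.append(fritz_purvis_d(tree, yb, n_sim=200, seed=s).D_stat)
        dr.append(fritz_purvis_d(tree, yr, n_sim=200, seed=s).D_stat)
    assert abs(np.mean(db)) < 0.35
    assert abs(np.mean(dr) - 1.0) < 0.35
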