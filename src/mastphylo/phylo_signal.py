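"""Phylogenetic signal: Pagel's lambda (continuous) and Fritz–Purvis D (binary).

Pagel's lambda multiplies the off-diagonal entries of the Brownian
covariance: lambda = 0 means tip values are independent of the tree,
lambda = 1 means full Brownian structure. The ML fit profiles the ancestral
mean (GLS) and the Brownian rate (ML variance) in closed form and optimises
the remaining one-dimensional likelihood in lambda over [0, 1]. Significance
comes either from a boundary-corrected likelihood-ratio test
(0.5*chi2_0 + 0.5*chi2_1 null) or from a tip-shuffle randomization test.

The Fritz–Purvis D statistic scores a binary trait by the sum of
sister-clade differences d_obs (nodal values are unweighted child means;
branch lengths enter only through the Brownian null) and standardises it
between two simulated nulls:

    D = (d_obs - mean d_Brownian) / (mean d_random - mean d_Brownian)

so phylogenetically random traits score ~1 and Brownian-threshold traits ~0.

On ultrametric trees (constant covariance diagonal) the lambda likelihood is
evaluated through a single symmetric eigendecomposition of C, making each
likelihood evaluation O(n); this is what keeps permutation tests and
Monte-Carlo calibration affordable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateInputError, InvalidInputError
from .phylo_core import PhyloCovariance, Phylogeny, _trait_vector

__all__ = [
    "LambdaFit",
    "DStatResult",
    "fit_pagel_lambda",
    "lambda_randomization_test",
    "sister_difference_sum",
    "fritz_purvis_d",
]

_LOG2PI = math.log(2.0 * math.pi)


class _LambdaLikelihood:
    """Profiled log-likelihood of lambda for one covariance matrix.

    mu and sigma2 are profiled out analytically; only lambda remains.
    When diag(C) is constant (ultrametric tree) the likelihood is computed
    through the eigendecomposition of C; otherwise each evaluation factors
    V(lambda) = lambda*C + (1-lambda)*diag(C) by Cholesky.
    """

    def __init__(self, C: PhyloCovariance):
        M = np.asarray(C.matrix, dtype=float)
        self.n = M.shape[0]
        diag = np.diag(M)
        if np.any(diag <= 0):
            raise InvalidInputError("covariance has non-positive diagonal entries")
        off = M - np.diag(diag)
        self.unidentifiable = np.abs(off).max() <= 1e-12 * diag.max()
        self.const_diag = np.allclose(diag, diag[0], rtol=1e-10)
        self._M = M
        self._diag = diag
        if self.const_diag:
            evals, Q = np.linalg.eigh(M)
            if evals.min() < -1e-8 * max(1.0, evals.max()):
                raise InvalidInputError("covariance is not positive semi-definite")
            self._evals = evals
            self._c = diag[0]
            self._Q = Q
            self._w = Q.T @ np.ones(self.n)

    def loglik(self, lam: float, y: np.ndarray):
        """Profiled log-likelihood; returns (ll, mu_hat, sigma2_hat)."""
        n = self.n
        if self.const_diag:
            d = lam * self._evals + (1.0 - lam) * self._c
            if d.min() <= 0:
                return -np.inf, np.nan, np.nan
            yt = self._Q.T @ y
            w = self._w
            mu = float((w * yt / d).sum() / (w * w / d).sum())
            r = yt - mu * w
            rss = float((r * r / d).sum())
            logdet = float(np.log(d).sum())
        else:
            V = lam * self._M + (1.0 - lam) * np.diag(self._diag)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                cond = np.linalg.cond(V)
                raise InvalidInputError(
                    f"V(lambda={lam:.4g}) is singular (condition number {cond:.3g})")
            one = np.ones(n)
            a = np.linalg.solve(L, np.column_stack([y, one]))
            ys, os = a[:, 0], a[:, 1]
            mu = float(ys @ os / (os @ os))
            r = ys - mu * os
            rss = float(r @ r)
            logdet = float(2.0 * np.log(np.diag(L)).sum())
        if rss <= 0:
            return -np.inf, mu, 0.0
        s2 = rss / n
        ll = -0.5 * (n * _LOG2PI + n * math.log(s2) + logdet + n)
        return ll, mu, s2

    def maximise(self, y: np.ndarray):
        """ML over lambda in [0, 1]; returns (lam, ll, mu, s2, ll0)."""
        neg = lambda lam: -self.loglik(lam, y)[0]
        res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-8})
        cands = [0.0, 1.0, float(res.x)]
        lls = [self.loglik(l, y)[0] for l in cands]
        k = int(np.argmax(lls))
        lam = cands[k]
        ll, mu, s2 = self.loglik(lam, y)
        ll0 = lls[0]
        return lam, ll, mu, s2, ll0


@dataclass
class LambdaFit:
    """ML estimate of Pagel's lambda for one continuous trait."""

    lambda_hat: float
    sigma2: float
    mu: float
    logLik_at_hat: float
    logLik_at_zero: float
    p_value: float          # boundary-corrected LRT of lambda_hat vs lambda = 0
    n_tips: int
    unidentifiable: bool = False


def fit_pagel_lambda(trait, C: PhyloCovariance) -> LambdaFit:
    """Maximum-likelihood Pagel's lambda on [0, 1] for a continuous trait.

    ``trait`` is a per-tip vector/Series aligned to (or keyed by) C's labels.
    On a star tree the likelihood is flat in lambda; the fit is returned with
    ``unidentifiable=True`` and lambda_hat = 0 rather than an arbitrary
    interior value.
    """
    y = _align_trait(trait, C.labels)
    if len(y) < 4:
        raise InvalidInputError(f"need >= 4 tips to estimate lambda, got {len(y)}")
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant trait: lambda is undefined")
    lik = _LambdaLikelihood(C)
    if lik.unidentifiable:
        ll0, mu, s2 = lik.loglik(0.0, y)
        return LambdaFit(0.0, s2, mu, ll0, ll0, 1.0, len(y), unidentifiable=True)
    lam, ll, mu, s2, ll0 = lik.maximise(y)
    lr = max(0.0, 2.0 * (ll - ll0))
    p = 1.0 if lr == 0.0 else 0.5 * stats.chi2.sf(lr, df=1)
    return LambdaFit(lam, s2, mu, ll, ll0, float(p), len(y))


def lambda_randomization_test(trait, C: PhyloCovariance, n_perm: int = 999,
                              seed: int = 0) -> float:
    """Tip-shuffle randomization p-value for Pagel's lambda.

    Trait values are permuted across tips ``n_perm`` times and lambda is
    refit each time; p = (1 + #{lambda_perm >= lambda_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise InvalidInputError(f"n_perm must be >= 99, got {n_perm}")
    y = _align_trait(trait, C.labels)
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant trait: lambda is undefined")
    lik = _LambdaLikelihood(C)
    if lik.unidentifiable:
        return 1.0
    lam_obs = lik.maximise(y)[0]
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        if lik.maximise(yp)[0] >= lam_obs:
            n_ge += 1
    return (1.0 + n_ge) / (n_perm + 1.0)


def _align_trait(trait, labels) -> np.ndarray:
    if hasattr(trait, "to_dict"):
        trait = trait.to_dict()
    if isinstance(trait, dict):
        from .phylo_core import canonical_label
        trait = {canonical_label(str(k)): v for k, v in trait.items()}
        missing = [l for l in labels if l not in trait]
        if missing:
            raise InvalidInputError(f"trait missing for tips: {missing[:10]}")
        return np.array([float(trait[l]) for l in labels])
    arr = np.asarray(trait, dtype=float)
    if arr.shape != (len(labels),):
        raise InvalidInputError(f"trait length {arr.shape} != {len(labels)} tips")
    return arr


# --------------------------------------------------------------------------- #
# Fritz–Purvis D
# --------------------------------------------------------------------------- #

def _sister_diff_sums(values: np.ndarray, arrays) -> np.ndarray:
    """Sum of sister-clade differences for each row of a (m, n_tips) matrix.

    Nodal values are unweighted means of child values; each internal node
    contributes sum_children |child - node|.
    """
    n = arrays.n_tips
    val = np.empty((values.shape[0], arrays.n_nodes))
    val[:, :n] = values
    d = np.zeros(values.shape[0])
    for v in arrays.postorder_internal:
        kids = arrays.children[v - n]
        kv = val[:, kids]
        nv = kv.mean(axis=1)
        val[:, v] = nv
        d += np.abs(kv - nv[:, None]).sum(axis=1)
    return d


def _simulate_bm_tips(arrays, m: int, rng: np.random.Generator) -> np.ndarray:
    """m Brownian realisations at the tips (root value 0, rate 1)."""
    eps = rng.standard_normal((m, arrays.n_nodes)) * np.sqrt(arrays.blen)
    x = np.zeros((m, arrays.n_nodes))
    for v in arrays.preorder:
        p = arrays.parent[v]
        x[:, v] = eps[:, v] + (x[:, p] if p >= 0 else 0.0)
    return x[:, : arrays.n_tips]


def sister_difference_sum(tree: Phylogeny, binary_trait) -> float:
    """Observed sum of sister-clade differences d_obs for a 0/1 trait."""
    y = _trait_vector(tree, binary_trait)
    _check_binary(y)
    return float(_sister_diff_sums(y[None, :], tree.arrays())[0])


def _check_binary(y: np.ndarray) -> None:
    states = set(np.unique(y))
    if not states <= {0.0, 1.0}:
        raise InvalidInputError(f"binary trait must be 0/1, got states {sorted(states)}")
    if len(states) < 2:
        raise DegenerateInputError("monomorphic binary trait: D is undefined")


@dataclass
class DStatResult:
    """Fritz–Purvis D statistic with its two null distributions."""

    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D_stat: float
    Pr: float               # probability of random phylogenetic structure
    Pb: float               # probability of Brownian phylogenetic structure
    n_sim: int
    seed: int
    null_random: np.ndarray = None
    null_brownian: np.ndarray = None


def fritz_purvis_d(tree: Phylogeny, binary_trait, n_sim: int = 1000,
                   seed: int = 0, random_null: str = "sample") -> DStatResult:
    """Fritz–Purvis D for a binary trait.

    The random null shuffles tip states preserving prevalence (``n_sim``
    draws, or every distinct assignment when ``random_null="exhaustive"``);
    the Brownian null simulates a continuous Brownian trait on the tree and
    sets the top-m tips to 1 (m = observed number of ones), which preserves
    prevalence exactly. Pr and Pb carry a +1 pseudo-count, so "Pr = 0" in
    the field's reporting corresponds to Pr < 1/(n_sim + 1) here.
    Polytomies are resolved (zero-length, seeded) before the traversal.
    """
    if random_null not in ("sample", "exhaustive"):
        raise InvalidInputError(f"unknown random_null mode {random_null!r}")
    if n_sim < 100:
        raise InvalidInputError(f"n_sim must be >= 100, got {n_sim}")
    y = _trait_vector(tree, binary_trait)
    _check_binary(y)
    work = tree.resolve_polytomies(seed=seed)
    if work is not tree:
        y = _trait_vector(work, dict(zip(tree.tip_labels, y)))
    a = work.arrays()
    n = a.n_tips
    m1 = int(y.sum())
    d_obs = float(_sister_diff_sums(y[None, :], a)[0])
    rng = np.random.default_rng(seed)

    if random_null == "exhaustive":
        combos = math.comb(n, m1)
        if combos > 200_000:
            raise InvalidInputError(
                f"exhaustive random null infeasible: C({n},{m1}) = {combos}")
        states = np.zeros((combos, n))
        for r, ones in enumerate(combinations(range(n), m1)):
            states[r, list(ones)] = 1.0
        n_rand = combos
    else:
        states = np.tile(y, (n_sim, 1))
        states = rng.permuted(states, axis=1)
        n_rand = n_sim
    d_rand = _sister_diff_sums(states, a)

    sims = _simulate_bm_tips(a, n_sim, rng)
    top = np.argpartition(-sims, m1 - 1, axis=1)[:, :m1]
    bstates = np.zeros_like(sims)
    bstates[np.arange(n_sim)[:, None], top] = 1.0
    d_brown = _sister_diff_sums(bstates, a)

    mr, mb = float(d_rand.mean()), float(d_brown.mean())
    if math.isclose(mr, mb, rel_tol=1e-12, abs_tol=1e-12):
        raise DegenerateInputError(
            "random and Brownian null means coincide: D scale undefined")
    d_stat = (d_obs - mb) / (mr - mb)
    pr = (1.0 + float((d_rand <= d_obs).sum())) / (n_rand + 1.0)
    pb = (1.0 + float((d_brown >= d_obs).sum())) / (n_sim + 1.0)
    return DStatResult(d_obs=d_obs, mean_d_random=mr, mean_d_brownian=mb,
                       D_stat=float(d_stat), Pr=float(pr), Pb=float(pb),
                       n_sim=n_sim, seed=seed,
                       null_random=d_rand, null_brownian=d_brown)
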