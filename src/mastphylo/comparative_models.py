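"""Gaussian phylogenetic mixed models, phylogenetic correlation, group tests.

The central model is a Gaussian PGLMM

    y = X beta + u + e,   u ~ N(0, sigma2_p * C),   e ~ N(0, sigma2_e * I)

with C the (height-normalised) Brownian covariance of the species tree used
as a phylogenetic random intercept. Fitting is by maximum likelihood: for a
given heritability-like ratio h = sigma2_p / (sigma2_p + sigma2_e) the
covariance is V(h) = h*C + (1-h)*I, beta is the GLS solution and the total
variance its ML estimate, leaving a one-dimensional profiled likelihood in h
that is optimised on [0, 1). Because V(h) is a convex combination with the
identity, a single eigendecomposition of C makes every likelihood
evaluation O(n p). ML (not REML) is used throughout so log-likelihood
differences across fixed-effect structures are valid for AIC and
likelihood-based partial R-squared.

Wald z statistics (normal tails) are reported for coefficients. The
phylogenetically corrected correlation uses Felsenstein's independent
contrasts by default, with a GLS alternative behind a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceError, DegenerateInputError, InvalidInputError
from .masting_index import log10_transform
from .phylo_core import (PhyloCovariance, Phylogeny, canonical_label,
                         covariance_from_tree, independent_contrasts)

__all__ = [
    "ModelSpec",
    "PGLMMFit",
    "CorrelationResult",
    "GroupTestResult",
    "fit_pglmm",
    "univariate_height_model",
    "phylo_correlation",
    "group_t_test",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Which trait is modelled on which predictors, with or without the
    phylogenetic random intercept."""

    response: str
    predictors: tuple
    include_phylogeny: bool = True

    def __post_init__(self):
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if self.response in self.predictors:
            raise InvalidInputError(f"response {self.response!r} cannot be a predictor")

    def drop(self, predictor: str) -> "ModelSpec":
        if predictor not in self.predictors:
            raise InvalidInputError(f"{predictor!r} not among predictors")
        return ModelSpec(self.response,
                         tuple(p for p in self.predictors if p != predictor),
                         self.include_phylogeny)

    def without_phylogeny(self) -> "ModelSpec":
        return ModelSpec(self.response, self.predictors, include_phylogeny=False)


@dataclass
class PGLMMFit:
    """Fitted Gaussian phylogenetic mixed model."""

    terms: tuple                 # ('intercept', predictor names...)
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    sigma2_phylo: float
    sigma2_resid: float
    logLik: float
    aic: float
    n: int
    n_params: int
    converged: bool
    species: tuple
    coding: dict = field(default_factory=dict)   # binary column -> level coded 1
    spec: ModelSpec = None

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "estimate": self.beta,
                             "se": self.se, "z": self.z, "p": self.p})

    def summary(self) -> str:
        lines = [f"Gaussian PGLMM: {self.spec.response} ~ "
                 + " + ".join(self.spec.predictors or ("1",))
                 + ("  (+ phylogenetic random intercept)"
                    if self.spec.include_phylogeny else "  (no phylogeny)"),
                 f"n = {self.n}, logLik = {self.logLik:.4f}, AIC = {self.aic:.2f}",
                 f"sigma2_phylo = {self.sigma2_phylo:.5f}, "
                 f"sigma2_resid = {self.sigma2_resid:.5f}, "
                 f"converged = {self.converged}"]
        for col, lvl in self.coding.items():
            lines.append(f"coding: {col} = 1 for level {lvl!r}")
        lines.append(self.coef_table().to_string(index=False))
        return "\n".join(lines)


def _design_matrix(traits: pd.DataFrame, spec: ModelSpec):
    """Complete-case y, X and metadata from a species-indexed trait table."""
    cols = [spec.response, *spec.predictors]
    missing_cols = [c for c in cols if c not in traits.columns]
    if missing_cols:
        raise InvalidInputError(f"columns absent from trait table: {missing_cols}")
    sub = traits[cols].copy()
    sub.index = [canonical_label(str(i)) for i in sub.index]
    dropped = sub.index[sub.isna().any(axis=1)].tolist()
    if dropped:
        warnings.warn(f"dropping {len(dropped)} species with missing values: "
                      f"{dropped[:5]}...", stacklevel=3)
    sub = sub.dropna()
    coding = {}
    for c in cols:
        if not pd.api.types.is_numeric_dtype(sub[c]):
            levels = sorted(sub[c].astype(str).unique())
            if len(levels) != 2:
                raise InvalidInputError(
                    f"non-numeric column {c!r} must be binary, has levels {levels}")
            coding[c] = levels[1]
            sub[c] = (sub[c].astype(str) == levels[1]).astype(float)
    y = sub[spec.response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub))]
                        + [sub[p].to_numpy(dtype=float) for p in spec.predictors])
    terms = ("intercept", *spec.predictors)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = [terms[j] for j in range(1, X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise InvalidInputError(f"rank-deficient design matrix; collinear: {bad}")
    return y, X, terms, tuple(sub.index), coding, dropped


def _ols_ml(y: np.ndarray, X: np.ndarray):
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    s2 = float(r @ r) / n
    ll = -0.5 * n * (_LOG2PI + math.log(s2) + 1.0)
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov)), s2, ll


def fit_pglmm(spec: ModelSpec, traits: pd.DataFrame, C: PhyloCovariance = None,
              *, strict: bool = False, fixed_variance: tuple = None) -> PGLMMFit:
    """Fit the Gaussian PGLMM by maximum likelihood.

    ``traits`` is indexed by species (or has a ``species`` column); rows
    with missing values are dropped with a warning, and ``C`` is restricted
    to and reordered by the retained species. Binary string columns are
    coded 0/1 with the alphabetically first level as 0; the coding is stored
    on the fit because coefficient signs depend on it.

    With ``include_phylogeny=False`` (or ``C is None``) the model collapses
    to ordinary least squares with the ML variance estimate.
    ``strict=True`` turns a non-converged optimisation into an error instead
    of a flagged result. ``fixed_variance=(sigma2_p, sigma2_e)`` skips the
    variance optimisation and returns the GLS fit at that covariance
    (useful for checks against closed-form GLS).
    """
    if "species" in traits.columns:
        traits = traits.set_index("species")
    y, X, terms, species, coding, _ = _design_matrix(traits, spec)
    n, p = X.shape
    if n < p - 1 + 3:
        raise InvalidInputError(f"need >= {p + 2} species for {p - 1} predictors, "
                                f"got {n}")
    use_phylo = spec.include_phylogeny and C is not None
    if spec.include_phylogeny and C is None:
        raise InvalidInputError("spec requests phylogeny but no covariance given")

    if not use_phylo:
        beta, se, s2, ll = _ols_ml(y, X)
        k = p + 1
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        return PGLMMFit(terms, beta, se, z, 2 * stats.norm.sf(np.abs(z)),
                        0.0, s2, ll, -2 * ll + 2 * k, n, k, True, species,
                        coding, spec)

    Cr = C.restrict(species)
    if fixed_variance is not None:
        s2p, s2e = (float(v) for v in fixed_variance)
        V = s2p * Cr.matrix + s2e * np.eye(n)
        Vi = np.linalg.inv(V)
        A = X.T @ Vi @ X
        beta = np.linalg.solve(A, X.T @ Vi @ y)
        r = y - X @ beta
        _, logdet = np.linalg.slogdet(V)
        ll = -0.5 * (n * _LOG2PI + float(logdet) + float(r @ Vi @ r))
        se = np.sqrt(np.diag(np.linalg.inv(A)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        return PGLMMFit(terms, beta, se, z, 2 * stats.norm.sf(np.abs(z)),
                        s2p, s2e, ll, -2 * ll + 2 * p, n, p, True, species,
                        coding, spec)
    evals, Q = np.linalg.eigh(Cr.matrix)
    if evals.min() < -1e-8 * max(1.0, evals.max()):
        raise InvalidInputError("covariance is not positive semi-definite")
    evals = np.clip(evals, 0.0, None)
    Xt, yt = Q.T @ X, Q.T @ y

    def profile(h: float):
        d = h * evals + (1.0 - h)
        w = 1.0 / d
        A = Xt.T @ (w[:, None] * Xt)
        beta = np.linalg.solve(A, Xt.T @ (w * yt))
        r = yt - Xt @ beta
        rss = float((w * r * r).sum())
        s2 = rss / n
        if s2 <= 0:
            return -np.inf, beta, s2, A
        ll = -0.5 * (n * _LOG2PI + n * math.log(s2)
                     + float(np.log(d).sum()) + n)
        return ll, beta, s2, A

    h_hi = 1.0 - 1e-6
    res = optimize.minimize_scalar(lambda h: -profile(h)[0], bounds=(0.0, h_hi),
                                   method="bounded", options={"xatol": 1e-9})
    cands = [0.0, h_hi, float(res.x)]
    lls = [profile(h)[0] for h in cands]
    h = cands[int(np.argmax(lls))]
    ll, beta, s2, A = profile(h)
    converged = bool(getattr(res, "success", True)) and np.isfinite(ll)
    if strict and not converged:
        raise ConvergenceError("PGLMM variance optimisation did not converge")
    cov = s2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    k = p + 2  # betas + two variance components
    return PGLMMFit(terms, beta, se, z, 2 * stats.norm.sf(np.abs(z)),
                    h * s2, (1.0 - h) * s2, ll, -2 * ll + 2 * k, n, k,
                    converged, species, coding, spec)


def univariate_height_model(traits: pd.DataFrame, C: PhyloCovariance, *,
                            response: str = "log_D", height: str = "log_height",
                            subset: tuple = None) -> PGLMMFit:
    """Univariate PGLMM of masting intensity on adult height, optionally on
    a subset of species (e.g. only wind- or only insect-pollinated ones);
    the covariance is re-restricted to the subset."""
    if "species" in traits.columns:
        traits = traits.set_index("species")
    if subset is not None:
        col, value = subset
        if col not in traits.columns:
            raise InvalidInputError(f"subset column {col!r} absent from trait table")
        traits = traits[traits[col] == value]
        if len(traits) < 5:
            raise InvalidInputError(
                f"subset {col}={value!r} leaves {len(traits)} species (< 5)")
    return fit_pglmm(ModelSpec(response, (height,)), traits, C)


@dataclass
class CorrelationResult:
    """Phylogenetically corrected pairwise correlation."""

    R: float
    p_value: float
    n_contrasts: int
    method: str = "contrasts"


def phylo_correlation(x, y, tree: Phylogeny, method: str = "contrasts") -> CorrelationResult:
    """Correlation of two continuous traits correcting for phylogeny.

    ``method="contrasts"`` (default): correlation through the origin of the
    independent contrasts, tested with t on (n_contrasts - 1) df.
    ``method="gls"``: correlation of GLS-centred tip values under the
    Brownian covariance, tested with t on (n - 2) df.
    """
    if method == "contrasts":
        cx = independent_contrasts(tree, x).contrasts
        cy = independent_contrasts(tree, y).contrasts
        sxx, syy = float(cx @ cx), float(cy @ cy)
        if sxx <= 0 or syy <= 0:
            raise DegenerateInputError("zero contrast variance in one trait")
        r = float(cx @ cy) / math.sqrt(sxx * syy)
        df = len(cx) - 1
        n_eff = len(cx)
    elif method == "gls":
        from .phylo_signal import _align_trait
        C = covariance_from_tree(tree, normalize=True)
        xv = _align_trait(x, C.labels)
        yv = _align_trait(y, C.labels)
        Ci = np.linalg.inv(C.matrix)
        one = np.ones(len(xv))
        denom = one @ Ci @ one
        xc = xv - (one @ Ci @ xv) / denom
        yc = yv - (one @ Ci @ yv) / denom
        sxx, syy = float(xc @ Ci @ xc), float(yc @ Ci @ yc)
        if sxx <= 0 or syy <= 0:
            raise DegenerateInputError("zero GLS variance in one trait")
        r = float(xc @ Ci @ yc) / math.sqrt(sxx * syy)
        df = len(xv) - 2
        n_eff = len(xv) - 1
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(R=r, p_value=float(p), n_contrasts=n_eff, method=method)


@dataclass
class GroupTestResult:
    """Two-sample t-test between the levels of a binary grouping."""

    levels: tuple           # (group1, group2); t is signed mean1 - mean2
    t: float
    df: float
    p_value: float
    means: tuple            # on the analysed (possibly log10) scale
    n: tuple
    log10_scale: bool
    welch: bool


def group_t_test(values, grouping, *, log10: bool = True,
                 welch: bool = True) -> GroupTestResult:
    """Two-sample t-test of a trait between two groups.

    By default Welch's unequal-variance test on log10-transformed values
    (the transformation applied to all traits before analysis); pooled
    variance and the raw scale are available behind flags. Groups are
    ordered alphabetically and t is signed as mean(group1) - mean(group2).
    """
    values = pd.Series(values).astype(float)
    grouping = pd.Series(grouping).astype(str)
    values, grouping = values.align(grouping, join="inner")
    levels = sorted(grouping.unique())
    if len(levels) != 2:
        raise InvalidInputError(f"grouping must have exactly 2 levels, got {levels}")
    g1 = values[grouping == levels[0]].to_numpy()
    g2 = values[grouping == levels[1]].to_numpy()
    if len(g1) < 2 or len(g2) < 2:
        raise InvalidInputError("both groups need >= 2 members")
    if log10:
        g1 = log10_transform(g1)
        g2 = log10_transform(g2)
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        warnings.warn("a group has zero variance; t-test computed anyway",
                      stacklevel=2)
    res = stats.ttest_ind(g1, g2, equal_var=not welch)
    return GroupTestResult(levels=tuple(levels), t=float(res.statistic),
                           df=float(res.df), p_value=float(res.pvalue),
                           means=(float(g1.mean()), float(g2.mean())),
                           n=(len(g1), len(g2)), log10_scale=log10, welch=welch)
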