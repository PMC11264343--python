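"""Likelihood-based partial R-squared for the phylogenetic mixed model.

The contribution of each factor (a fixed-effect predictor, or the
phylogenetic random intercept itself) to variation in the response is
measured by refitting the model without that factor and converting the
log-likelihood drop into

    R2_lik = 1 - exp(-2 * (lnL_full - lnL_reduced) / n)

with n the number of species in the fitted model. R2_lik can be negative
when the reduced model happens to fit better across model classes; such
values are reported as computed, never truncated at zero. Significance is a
likelihood-ratio chi-squared test with df equal to the parameter
difference; removing the phylogenetic variance component is a boundary test
and uses the 50:50 chi2_0/chi2_1 mixture, labelled approximate because the
phylogenetic and non-phylogenetic covariance structures differ in kind.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .comparative_models import ModelSpec, PGLMMFit, fit_pglmm
from .errors import InvalidInputError
from .phylo_core import PhyloCovariance

__all__ = ["PartialR2Result", "r2_lik", "partition_all"]


@dataclass
class PartialR2Result:
    factor: str
    r2_lik: float
    delta_logLik: float
    df: int
    p_value: float
    n: int
    approximate: bool = False    # boundary / non-nested comparison
    converged: bool = True


def r2_lik(full: PGLMMFit, reduced: PGLMMFit, factor: str = "",
           boundary: bool = False) -> PartialR2Result:
    """Likelihood partial R-squared of ``full`` against ``reduced``.

    Both fits must be ML fits on the identical species set (hard error
    otherwise). ``boundary=True`` applies the 50:50 chi-squared boundary
    mixture used when a variance component is removed.
    """
    if set(full.species) != set(reduced.species) or full.n != reduced.n:
        raise InvalidInputError(
            "full and reduced models were fitted on different species sets")
    n = full.n
    delta = full.logLik - reduced.logLik
    df = full.n_params - reduced.n_params
    if df <= 0 and not boundary:
        warnings.warn(f"{factor or 'comparison'}: reduced model is not nested "
                      "(no parameter difference); p-value omitted", stacklevel=2)
        p = float("nan")
    elif boundary:
        p = 1.0 if delta <= 1e-8 else 0.5 * float(stats.chi2.sf(2.0 * delta, df=1))
    else:
        if delta < -1e-6:
            warnings.warn(f"{factor or 'comparison'}: nested reduction increased "
                          f"the log-likelihood by {-delta:.3g}; optimiser may not "
                          "have converged", stacklevel=2)
        p = float(stats.chi2.sf(max(0.0, 2.0 * delta), df=df))
    r2 = 1.0 - math.exp(-2.0 * delta / n)
    return PartialR2Result(factor=factor, r2_lik=r2, delta_logLik=float(delta),
                           df=max(df, 0), p_value=p, n=n, approximate=boundary,
                           converged=full.converged and reduced.converged)


def partition_all(spec: ModelSpec, traits: pd.DataFrame,
                  C: PhyloCovariance) -> list:
    """Partial R-squared of every predictor plus the phylogeny itself.

    Each predictor is dropped from the full model in turn; the phylogeny
    partial refits the same fixed effects without the phylogenetic random
    intercept. All fits share the complete-case species set of the full
    model. Results are sorted by R2_lik, largest first. A reduced fit that
    fails to converge flags its factor but does not abort the others.
    """
    if not spec.include_phylogeny:
        raise InvalidInputError("partition_all expects a phylogenetic full model")
    if "species" in traits.columns:
        traits = traits.set_index("species")
    cols = [spec.response, *spec.predictors]
    missing = [c for c in cols if c not in traits.columns]
    if missing:
        raise InvalidInputError(f"columns absent from trait table: {missing}")
    complete = traits.dropna(subset=cols)
    full = fit_pglmm(spec, complete, C)
    if not full.converged:
        raise InvalidInputError("full model did not converge; partition aborted")
    out = []
    for pred in spec.predictors:
        try:
            reduced = fit_pglmm(spec.drop(pred), complete, C)
            out.append(r2_lik(full, reduced, factor=pred))
        except Exception as exc:  # keep the other factors alive
            warnings.warn(f"reduced fit without {pred!r} failed: {exc}", stacklevel=2)
            out.append(PartialR2Result(pred, float("nan"), float("nan"), 0,
                                       float("nan"), full.n, converged=False))
    no_phylo = fit_pglmm(spec.without_phylogeny(), complete, C)
    out.append(r2_lik(full, no_phylo, factor="phylogeny", boundary=True))
    out.sort(key=lambda r: (-(r.r2_lik) if np.isfinite(r.r2_lik) else np.inf))
    return out


def partition_table(results) -> pd.DataFrame:
    return pd.DataFrame([{"factor": r.factor, "r2_lik": r.r2_lik,
                          "r2_lik_pct": 100.0 * r.r2_lik,
                          "delta_logLik": r.delta_logLik, "df": r.df,
                          "p": r.p_value, "approximate": r.approximate,
                          "converged": r.converged} for r in results])
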