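"""Config-driven orchestration of the full comparative analysis.

Runs, in order: seed-crop screening and disparity computation (when crop
series are supplied), log10 transformation, tree pruning to the shared
species set, Pagel's lambda for the continuous traits, Fritz–Purvis D for
the binary traits, group t-tests, univariate and pollination-stratified
PGLMMs, the multivariate PGLMM, phylogenetically corrected correlation and
the likelihood partial R-squared partition. Every stage writes a TSV and
the run is reproducible from the echoed config and seeds.

All hypothesis tests are two-sided; no multiple-testing correction is
applied anywhere in the pipeline.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparative_models import (ModelSpec, fit_pglmm, group_t_test,
                                 phylo_correlation, univariate_height_model)
from .errors import InvalidInputError
from .masting_index import disparity_table, log10_transform, read_series_csv
from .phylo_core import canonical_label, covariance_from_tree, prune_to, read_newick
from .phylo_signal import fit_pagel_lambda, fritz_purvis_d, lambda_randomization_test
from .variance_partition import partition_all, partition_table

__all__ = ["AnalysisConfig", "AnalysisReport", "run_all"]


@dataclass
class AnalysisConfig:
    """Inputs, variable roles and tuning knobs for one analysis run."""

    tree: str
    traits: str
    out_dir: str
    crops: str = None                   # optional long/wide seed-crop CSV
    response: str = "D"                 # raw-scale masting intensity column
    height: str = "height_m"            # raw-scale adult height column
    binary: tuple = ("life_form", "pollination", "spermatophyte")
    stratify_by: str = "pollination"    # univariate model run per level
    k: float = 1.0
    min_series_length: int = 2
    log_transform: bool = True
    n_sim: int = 1000                   # Fritz–Purvis nulls
    n_perm: int = 999                   # lambda randomization permutations
    correlation_method: str = "contrasts"
    welch: bool = True
    seed: int = 42

    def __post_init__(self):
        self.binary = tuple(self.binary)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        missing = {"tree", "traits", "out_dir"} - set(raw)
        if missing:
            raise InvalidInputError(f"config missing required keys: {sorted(missing)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("tree", "traits", "crops"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise InvalidInputError(f"{key} file does not exist: {p}")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["binary"] = list(d["binary"])
        return yaml.safe_dump(d, sort_keys=True)


@dataclass
class AnalysisReport:
    tables: dict                    # stage name -> DataFrame
    config: AnalysisConfig
    warnings: list = field(default_factory=list)
    version: str = __version__

    def write(self, out_dir=None) -> Path:
        out = Path(out_dir if out_dir is not None else self.config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in self.tables.items():
            tab.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                       float_format="%.10g")
        (out / "config_echo.yaml").write_text(self.config.to_yaml())
        log = io.StringIO()
        log.write(f"mastphylo {self.version}\nseed: {self.config.seed}\n")
        log.write("stages: " + ", ".join(self.tables) + "\n")
        log.write("note: all tests two-sided; no multiple-testing correction "
                  "applied.\n")
        for w in self.warnings:
            log.write(f"warning: {w}\n")
        (out / "run_log.txt").write_text(log.getvalue())
        return out


def _read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    first = df.columns[0]
    if first.lower() in ("species", "taxon", "tip"):
        df = df.rename(columns={first: "species"})
    else:
        raise InvalidInputError(
            f"first trait-table column must name the species, got {first!r}")
    df["species"] = [canonical_label(str(s)) for s in df["species"]]
    if df["species"].duplicated().any():
        dup = df["species"][df["species"].duplicated()].tolist()
        raise InvalidInputError(f"duplicate species in trait table: {dup[:5]}")
    return df.set_index("species")


def run_all(config: AnalysisConfig) -> AnalysisReport:
    """Execute the whole analysis and return (and write) the report."""
    config.validate()
    caught: list = []
    tables: dict = {}
    rng = np.random.default_rng(config.seed)
    stage_seed = lambda: int(rng.integers(2 ** 31))

    traits = _read_traits(config.traits)

    # --- stage 1: seed-crop series -> D ---------------------------------- #
    if config.crops is not None:
        series = read_series_csv(config.crops)
        dtab = disparity_table(series, k=config.k,
                               min_length=config.min_series_length)
        tables["disparity"] = dtab
        dmap = dtab.set_index(dtab["species"].map(canonical_label))["D"]
        traits[config.response] = dmap.reindex(traits.index)

    # --- stage 2: config / column validation ----------------------------- #
    needed = [config.response, config.height, *config.binary]
    missing_cols = [c for c in needed if c not in traits.columns]
    if missing_cols:
        raise InvalidInputError(f"trait table lacks columns: {missing_cols}")

    # --- stage 3: transforms --------------------------------------------- #
    complete = traits.dropna(subset=needed).copy()
    if config.log_transform:
        complete["log_height"] = log10_transform(
            complete[config.height].to_numpy(), labels=list(complete.index))
        complete["log_D"] = log10_transform(
            complete[config.response].to_numpy(), labels=list(complete.index))
    else:
        complete["log_height"] = complete[config.height].astype(float)
        complete["log_D"] = complete[config.response].astype(float)
    n_dropped = len(traits) - len(complete)
    if n_dropped:
        caught.append(f"{n_dropped} species dropped for missing trait values")

    # --- stage 4: tree ---------------------------------------------------- #
    tree_full = read_newick(config.tree)
    shared = [s for s in complete.index if s in set(tree_full.tip_labels)]
    off_tree = sorted(set(complete.index) - set(shared))
    if off_tree:
        caught.append(f"{len(off_tree)} species absent from tree: {off_tree[:5]}")
        tables["species_rejected"] = pd.DataFrame(
            {"species": off_tree, "reason": "not-in-tree"})
    if len(shared) < 4:
        raise InvalidInputError(
            f"only {len(shared)} species shared between tree and traits (< 4)")
    complete = complete.loc[shared]
    tree = prune_to(tree_full, shared, on_missing="error").tree \
        if set(shared) != set(tree_full.tip_labels) else tree_full
    C = covariance_from_tree(tree, normalize=True)

    # --- stage 5: phylogenetic signal ------------------------------------ #
    sig_rows = []
    for name, col in (("height", "log_height"), ("masting_D", "log_D")):
        fitL = fit_pagel_lambda(complete[col], C)
        p_perm = lambda_randomization_test(complete[col], C,
                                           n_perm=config.n_perm,
                                           seed=stage_seed())
        sig_rows.append({"trait": name, "type": "continuous",
                         "estimate": fitL.lambda_hat, "d_obs": np.nan,
                         "mean_d_random": np.nan, "mean_d_brownian": np.nan,
                         "p_LRT": fitL.p_value, "p_perm": p_perm,
                         "Pr": np.nan, "Pb": np.nan, "n_sim": config.n_perm})
    for name in config.binary:
        coded = (complete[name].astype(str)
                 == sorted(complete[name].astype(str).unique())[-1]).astype(float)
        d = fritz_purvis_d(tree, coded.to_dict(), n_sim=config.n_sim,
                           seed=stage_seed())
        sig_rows.append({"trait": name, "type": "binary", "estimate": d.D_stat,
                         "d_obs": d.d_obs, "mean_d_random": d.mean_d_random,
                         "mean_d_brownian": d.mean_d_brownian,
                         "p_LRT": np.nan, "p_perm": np.nan,
                         "Pr": d.Pr, "Pb": d.Pb, "n_sim": d.n_sim})
    tables["signal"] = pd.DataFrame(sig_rows)

    # --- stage 6: group t-tests ------------------------------------------ #
    t_rows = []
    for by in config.binary:
        for name, col in (("height", config.height), ("masting_D", config.response)):
            res = group_t_test(complete[col], complete[by],
                               log10=config.log_transform, welch=config.welch)
            t_rows.append({"trait": name, "by": by, "group1": res.levels[0],
                           "group2": res.levels[1], "t": res.t, "df": res.df,
                           "p": res.p_value, "mean1": res.means[0],
                           "mean2": res.means[1]})
    tables["ttests"] = pd.DataFrame(t_rows)

    # --- stage 7: univariate + stratified PGLMM -------------------------- #
    uni_rows = []
    fits = {"all": univariate_height_model(complete, C)}
    if config.stratify_by in complete.columns:
        for lvl in sorted(complete[config.stratify_by].astype(str).unique()):
            try:
                fits[lvl] = univariate_height_model(
                    complete, C, subset=(config.stratify_by, lvl))
            except InvalidInputError as exc:
                caught.append(f"stratified fit {lvl!r} skipped: {exc}")
    for label, f in fits.items():
        uni_rows.append({"subset": label, "n": f.n, "beta_height": f.beta[1],
                         "se": f.se[1], "z": f.z[1], "p": f.p[1],
                         "sigma2_phylo": f.sigma2_phylo,
                         "sigma2_resid": f.sigma2_resid, "logLik": f.logLik,
                         "AIC": f.aic, "converged": f.converged})
    tables["pglmm_univariate"] = pd.DataFrame(uni_rows)

    # --- stage 8: multivariate PGLMM -------------------------------------- #
    spec = ModelSpec("log_D", ("log_height", *config.binary))
    full = fit_pglmm(spec, complete, C)
    tab = full.coef_table()
    tab.insert(0, "model", "multivariate")
    tab["AIC"] = full.aic
    tab["logLik"] = full.logLik
    tab["sigma2_phylo"] = full.sigma2_phylo
    tab["sigma2_resid"] = full.sigma2_resid
    tab["coding"] = [full.coding.get(t, "") for t in full.terms]
    tables["pglmm_multivariate"] = tab

    # --- stage 9: phylogenetic correlation -------------------------------- #
    corr = phylo_correlation(complete["log_height"], complete["log_D"], tree,
                             method=config.correlation_method)
    tables["correlation"] = pd.DataFrame([{
        "x": "log_height", "y": "log_D", "R": corr.R, "p": corr.p_value,
        "n_contrasts": corr.n_contrasts, "method": corr.method}])

    # --- stage 10: variance partition ------------------------------------- #
    tables["partition"] = partition_table(partition_all(spec, complete, C))

    report = AnalysisReport(tables=tables, config=config, warnings=caught)
    report.write()
    return report
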