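# mastphylo

Phylogenetic comparative analysis of mast seeding — the massive, intermittent,
synchronous seed production of some perennial plants — and its relationship to
adult plant height across seed-plant species.

The package is organised as an analysis project: the library under
`src/mastphylo/` implements every step, the numbered drivers under `analysis/`
run the study end to end on generated data, and `tests/` verifies each step
against independent oracles.

## What it computes

**Masting intensity.** Each species' interannual seed-crop record
p_1..p_n is summarised by the consecutive disparity index

    D = (1/(n−1)) Σ_{i=1..n−1} | ln((p_{i+1}+k)/(p_i+k)) |,   k = 1,

which captures both temporal variability and lag-1 structure (constant series
give D = 0; boom–bust alternation maximises it).

**Phylogenetic signal.** For continuous traits, Pagel's λ ∈ [0, 1] is
estimated by maximum likelihood (μ and σ² profiled in closed form, λ by
bounded scalar search), tested both by a boundary-corrected LRT and by a
tip-shuffle randomization test. For binary traits, the Fritz–Purvis D
statistic standardises the sum of sister-clade differences between a
prevalence-preserving shuffle null (D ≈ 1) and a Brownian-threshold null
(D ≈ 0), with Pr and Pb the corresponding tail probabilities.

**Comparative models.** A Gaussian phylogenetic generalized linear mixed
model (PGLMM) y = Xβ + u + e with u ~ N(0, σ²_p C) and e ~ N(0, σ²_e I),
C the height-normalised Brownian covariance of the tree, fitted by ML via a
profiled one-dimensional variance-ratio search; Wald z statistics; Welch
t-tests on log10-transformed traits; phylogenetically corrected correlation
through independent contrasts.

**Variance partition.** Likelihood-based partial R² per factor:
R²_lik = 1 − exp(−2ΔlnL/n), where ΔlnL is the log-likelihood drop from
removing that factor (a fixed effect, or the phylogenetic random intercept)
from the full model.

**Synthetic data.** Yule trees, λ-structured continuous traits,
Brownian-threshold or shuffled binaries, AR(1) log-normal seed-crop series
and full ground-truthed datasets, so every stage is verifiable without any
external data. Defaults emulate the study conditions (158 species, published
effect magnitudes).

## Worked example

```
python analysis/01_simulate_dataset.py
python analysis/02_masting_disparity.py
python analysis/03_full_analysis.py
```

prints (158 synthetic species, seed 42):

```
D: mean 1.018, range 0.521-1.581
phylogenetic signal:
  lambda(height) = 0.856 (perm p = 0.001)
  lambda(D)      = 0.450 (perm p = 0.001)
  D_stat(life_form) = 0.144 (Pr = 0.000999, Pb = 0.2318)
  D_stat(pollination) = -0.022 (Pr = 0.000999, Pb = 0.5594)
  D_stat(spermatophyte) = -0.324 (Pr = 0.000999, Pb = 0.8921)
univariate height effect: z = 3.933, p = 8.403e-05
evolutionary correlation height~D: R = 0.814, p = 1.183e-38
```

Height carries strong phylogenetic signal and masting intensity a moderate
one; the Brownian-threshold binaries sit near D ≈ 0 (Brownian structure,
Pb large, Pr ≈ 0); and taller species show higher masting intensity both in
the univariate PGLMM and in the contrasts correlation — the qualitative
pattern the generating parameters encode. Full stage tables (t-tests,
multivariate PGLMM coefficients, partial R² partition) land in
`results/analysis/`.

The same sequence runs on real inputs from a Newick tree plus a trait/crop
CSV via the CLI:

```
mastphylo run --config analysis.yaml
mastphylo disparity --series crops.csv --k 1 --out d_values.tsv
mastphylo pglmm --tree tree.nwk --traits traits.csv \
    --response log_D --predictors log_height,life_form,pollination,spermatophyte
```

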