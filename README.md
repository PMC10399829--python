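# commodular

Model-based ordination and null-model inference for **modularity in community
count data** — is a multivariate community of counted organisms a random
assemblage of independent populations, or is it organized into modules
(subsets of taxa that covary with each other and little with the rest)?

The package is written for community ecologists working with samples × taxa
count matrices from repeated surveys (the motivating setting is a
macroinvertebrate community sampled biweekly on six organic brassica farms
over two seasons: 36 taxa × 120 samples), but every step is generic.

## The method

**Ordination.** Counts are modeled with a negative-binomial generalized
linear latent variable model (GLLVM),

```
log μ_ij = α_i + β_0j + u_iᵀ θ_j ,     y_ij ~ NB(μ_ij, φ_j),   Var = μ + μ²/φ_j
```

with fixed sample effects α_i (absorbing total-abundance variation so the
latent axes describe *composition*), taxon intercepts β_0j, two latent sample
scores u_i, taxon loadings θ_j, and a per-taxon dispersion φ_j.  The model is
estimated by deterministic optimization of a Laplace-approximate marginal
likelihood (scores carry the standard-normal prior; see
`docs/methods.md`).  The taxon loadings θ are the ordination: taxa that load
together form a module.

**Null communities.** Two randomized universes calibrate the decision:

- *module-structured*: taxa are assigned to k modules by an abundance-ranked
  round robin and each taxon's counts are reordered across samples
  (Gaussian-copula rank reordering — marginals preserved exactly) until the
  mean pairwise Pearson correlation hits targets r_within / r_between;
- *completely randomized*: each taxon's column permuted independently, and
  among many trials the one whose correlation-test p-values are closest to
  Uniform(0,1) (smallest Kolmogorov–Smirnov distance) is selected.

**Decision.** The observed ordination is compared against each null
ordination as a bivariate distribution of loadings: Shapiro–Wilk normality
gate, pooled-variance t test and two-sided variance-ratio F test per axis,
the four p-values combined by Fisher's method (−2Σln p ~ χ²₈), plus
Fisher-z tests of the between-axis correlations.  Temporal centroids of the
latent scores and a likelihood-ratio test of a farm random intercept
(`response ~ time + (1|farm) + (1|year)`) describe when and where the
modules dominate.

## Worked example

The original field data are not public, so the analysis ships as numbered
drivers over a synthetic community with known ground truth (two modules
whose dominance crosses over through the season):

```sh
python analysis/01_simulate_community.py
python analysis/02_fit_ordination.py
python analysis/03_generate_null_communities.py
python analysis/04_test_modularity.py
python analysis/05_temporal_and_farm_structure.py
```

Output of a run (seed 1), abridged:

```
simulated 120 samples x 36 taxa (6 farms x 2 years x 10 occasions; 3600 plants inspected)
mean pairwise Pearson r: within modules 0.264, between modules -0.172

parameter accounting at 120 samples x 36 taxa, 2 axes: model-based 504,
NMDS-style 240, 8.6 observations/parameter
2-axis fit: loglik -15899.9, AIC 32808 (axis-free AIC 34748); converged=True
randomized-quantile residuals: mean -0.006, sd 0.985

module null (realistic): targets (0.25, 0.02) -> realized (0.235, 0.014)
complete randomization: selected trial 894/2000, KS distance 0.0158 (data: 0.5606)

2-module (realistic): LV1 loading variance data 0.636 vs null 0.453;
  combined chi2_8 = 13.58, p = 0.0933 -> not rejected
complete randomization: LV1 loading variance data 0.636 vs null 0.153;
  combined chi2_8 = 20.93, p = 0.0073 -> rejected

year1: centroid LV1 runs +1.61 -> -1.46 over 10 occasions (Spearman rho = -1.00)
```

Reading it: the model-based ordination spends 504 parameters (taxon
intercept, dispersion and two loadings each; a sample effect and two scores
per sample) against 240 for a distance-based ordination — about 8.6
observations per parameter here.  The community **rejects the random
assemblage** (its dominant axis carries far more loading variance than any
complete randomization supports, combined p = 0.0073) but is **consistent
with two modules** (p = 0.09 against the calibrated 2-module null), and the
latent-score centroids sweep monotonically along LV1 through the season —
one module's taxa giving way to the other's.

The same workflow runs from a shell on any dataset via the CLI:

```sh
commodular analyze --config my_run.yaml --seed 1 --out results/my_run
```

(subcommands `simulate | fit | nulls | compare | report | analyze`; counts
and metadata are plain CSV, results JSON/CSV).

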