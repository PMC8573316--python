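# Methods

## The prediction problem

Paired microbiome–metabolome studies measure, on the same biological
samples, the relative abundances of microbial gene families (from shotgun
metagenomics, metatranscriptomics, or both) and of metabolites (from LC-MS).
The package learns, per metabolite, a sparse linear map from gene-family
abundances to metabolite abundance, so that metabolomes can be predicted for
cohorts where only sequencing data exist, and so that the gene families (and
species) driving each prediction can be read off the model.

## Model

For one metabolite with transformed abundance $y_i$ and transformed
gene-family profile $x_i \in \mathbb{R}^p$, the plain elastic net (ENM)
minimises

$$L_{ENM} = \frac{1}{2N}\sum_{i=1}^N (y_i - x_i'\beta)^2 +
\lambda \sum_{j=1}^p \Big\{ \frac{1-\alpha}{2}\beta_j^2 + \alpha|\beta_j| \Big\}.$$

The importance-thresholded variant (ENVIM) adds a per-feature selection
indicator $s_{k,j} = \mathbb{1}\{VI_j \ge k\}$, where $VI_j$ is the
random-forest variable importance of gene family $j$ for this metabolite,
linearly rescaled to $[0,100]$, and minimises over $k$ as well:

$$L_{ENVIM}(k) = \frac{1}{2N}\sum_i (y_i - x_i' M_k \beta)^2 +
\lambda \sum_j s_{k,j}\Big\{ \frac{1-\alpha}{2}\beta_j^2 + \alpha|\beta_j| \Big\},
\qquad k \in K = \{0, 10, \dots, 90\}.$$

Because the candidate sets are nested in $k$ and every $(k,\alpha,\lambda)$
fit shares one fold assignment, the minimiser of the 10-fold CV MSE over the
full triple grid is well defined, and $K=\{0\}$ reduces the procedure
*exactly* to the plain elastic net (this reduction is asserted to 1e-12 in
the tests).

### Transforms

* **Predictors** — rank-based inverse normal per gene family across samples:
  value with average rank $r$ of $n$ maps to $\Phi^{-1}((r-0.5)/n)$;
  constant features map to zeros.  Training and testing matrices are
  transformed independently.  The phrase "per feature across samples" is the
  convention of the trait-transform this mirrors; the per-sample-across-
  features alternative was considered and rejected because the downstream
  model treats each gene family as a covariate whose marginal distribution
  must be normalised.
* **Responses** — Box–Cox with exponent $\omega$ profiled per metabolite on
  the training data over $\omega \in [-2,2]$; metabolites containing zeros
  get an offset $\delta$ of half their minimum positive training value,
  stored with $\omega$ and reused at inversion time.  Predictions are
  back-transformed with the training $(\omega,\delta)$ and clamped at 0.
* **Baseline mode** — arcsine square root on the responses and an interior
  mixing grid (10 points in $[0.05,0.95]$), mirroring the common practice
  this package's variant improves on; the ENVIM grid is 10 evenly spaced
  points *including* the ridge ($\alpha=0$) and lasso ($\alpha=1$)
  endpoints.

### Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k_grid` | 0,10,…,90 | cumulative importance thresholds (importance units) |
| `alpha_grid_size` | 10 | evenly spaced mixing values; endpoints included in ENVIM mode |
| `n_folds` | 10 | CV folds, shared across every fit of one metabolite |
| `n_trees` | 500 | random forest size; 150–200 suffices on desk-scale data |
| `mtry_grid` | {p/3, √p, 0.8p} | features-per-split candidates, tuned by CV MSE |
| `lambda_path_length` | 100 | log-spaced penalty path per α, from λ_max down to λ_max·`min_lambda_ratio` |
| `min_lambda_ratio` | 1e-3 | path depth; the λ at minimum CV MSE is kept (no one-SE rule) |
| gene filter | mean ≥ 5e-5, zeros ≤ 90% | compositional abundance/prevalence filter |
| metabolite filter | mean ≥ 1e-4, zeros ≤ 90% | idem, applied before imputation for the NA rule, after for zeros |
| WP threshold | Spearman ≥ 0.3 | "well-predicted" call, a conventional medium effect size |
| enrichment q | < 0.05 | BH-adjusted two-sample KS per species, `min_set_size` 5 |

λ paths use the glmnet-style entry point `max_j |z_j'y_c| / (N·max(α,0.001))`.
Ridge fits (α = 0) are solved exactly for the whole path through one SVD per
fold rather than by coordinate descent; this is also what makes the
closed-form ridge oracle in the tests exact to 1e-6.

### Tie-breaking and degeneracy

Equal CV MSE prefers the larger threshold $k$, then the larger $\lambda$
(the sparser model).  Constant metabolites raise a degenerate-target error
that `fit_all_metabolites` records per metabolite without aborting the run.
Features constant in a training fold get unit scale during standardisation
(their coefficient is necessarily 0).  Per-metabolite seeds are
`master_seed + column_index`, so serial and parallel execution produce
byte-identical weight matrices.

## Preprocessing

Total-sum scaling makes each sample's gene families sum to 1.  A table whose
features were filtered afterwards is a *subcomposition* (rows sum to < 1);
the package deliberately does not renormalise after filtering, so RELATIVE
tables are validated as rows summing to at most 1.  Combining DNA and RNA
assays concatenates per-assay compositions with `|DNA` / `|RNA` feature
suffixes; the combined table is labelled RAW because it is no longer a
single composition.

Metabolite missingness is treated as left-censoring: features with > 90% NA
(and samples with > 90% NA) are removed, then QRILC-style imputation works
per feature on the natural-log scale.  The underlying normal's $(\mu,\sigma)$
are estimated by least-squares regression of the observed empirical
quantiles, at 100 probabilities spanning $(m+0.001, 0.999)$ where $m$ is the
missing fraction, on standard-normal quantiles; missing entries are drawn by
inverse-CDF sampling from $N(\mu, \texttt{tune\_sigma}\cdot\sigma)$
truncated above at the censoring point $\mu + \sigma\Phi^{-1}(m)$, which is
additionally capped at the observed minimum so no imputed value can exceed
an observed one.  Draws are exponentiated back; observed values are never
altered.  With `tune_sigma = 0` the imputation collapses to the censoring
point itself.

The train/test split is a uniform random 75/25 partition by sample id,
reproducible by seed; no phenotype stratification is performed.  The
pathway filter is mapping-file driven: the caller supplies a
metabolite→pathway TSV and the set of pathways observed in the community's
functional profile; database lookups are out of scope.

## Evaluation and enrichment

Predictions are scored on the compositional scale (after back-transform):
per-metabolite Spearman correlation (average-rank ties), MSE, and the WP
flag at $r \ge 0.3$.  Undefined correlations (constant vectors) are reported
as missing, counted as not-WP but kept in the NM denominator.  Training-set
$R^2$ (squared Pearson between fitted and observed) is the overfitting
diagnostic.

For enrichment, genes with a non-zero weight for at least one well-predicted
metabolite are scored by the maximum $|{\rm weight}|$ across those
metabolites (`sum` and `count` aggregations are available; the choice of
aggregation is genuinely open — max was chosen because a single strong
contribution is the biologically interesting signal) and ranked descending.
Each species with at least `min_set_size` scored genes is tested by a
two-sided two-sample Kolmogorov–Smirnov test of its gene ranks against all
other scored genes, with Benjamini–Hochberg control across species.

## Synthetic data generator

The generator emulates the features of real paired data that matter for this
method: gene families are feature-specific log-normals (strong skew, heavy
right tail), independently zeroed with probability `zero_inflation` (default
0.3) and total-sum scaled; each signal metabolite is
$\sum_{j \in A} b_j z_j + \varepsilon$ on the transformed scale ($z$ =
rank-normalised gene features, $|A| = q$, $|b_j|$ uniform in the effect
range), pushed through an inverse Box–Cox into a small share
($10^{-4}$–$2\cdot10^{-2}$) of the per-sample composition.  Noise
metabolites split the remaining mass via per-sample Dirichlet weights, so
rows sum to exactly 1 and the signal metabolites remain strictly monotone in
their latent values.  Noise is parameterised by SNR = sd(signal)/σ on the
transformed scale, default 3.  With `within_species_support` one randomly
chosen donor species hosts every planted support, which is what the
enrichment power check needs; species sizes are multinomial with a floor of
$q+2$ genes.  Optional left-censoring masks exactly the lowest
⌊`censor_fraction`·n⌋ values per metabolite.

What the generator does **not** emulate: phylogenetic or within-species
correlation between gene families (features are independent given their
marginals), longitudinal/repeated sampling, batch effects, and measurement
error on the gene side.  Passing the planted-recovery tests therefore shows
the estimator works under its own assumptions — independent skewed
compositional predictors with sparse linear signal — not that it matches any
particular real cohort's accuracy.

## Benchmark problem sizes

The multi-seed planted benchmark (`envim.benchmark`) generates n=200
samples, p=500 gene families, 20 metabolites of which 3 carry signal with
support size q=5 at SNR 3, splits 75/25, and fits both modes with a lighter
model configuration chosen for single-CPU runs: 200 trees, a fixed
features-per-split of p/3, a 40-point λ path, 10 CV folds.  Ten independent
seeds are scored for support recovery (first signal metabolite), test-set
Spearman, WP counts for both modes, the false-WP rate on two pure-noise
metabolites per seed, and donor-species enrichment.  The uniform-null
enrichment calibration uses 400 genes in 20 species over 500 replicates.
All of these are recomputed, never cached, by `scripts/acceptance.py`.

## Known limitations

* The per-metabolite fit is marginal: no joint modelling across metabolites
  and no covariate adjustment (age, batch, phenotype).
* Repeated measures are not handled; samples are assumed exchangeable, so
  longitudinal cohorts must be collapsed or subsampled upstream.
* Impurity-based forest importance is biased toward high-cardinality
  features; rank-normalised inputs blunt but do not remove this.
* The baseline mode approximates the compared tool's published behaviour
  (interior α grid, arcsine-sqrt transform, "predictable" flag from
  training-set correlations at BH q < 0.05); its exact internal defaults
  cannot be confirmed from the description alone.
* The "10 models with different values of the tuning parameter" in the
  source procedure is read as 10 mixing values α including both endpoints;
  λ is selected on a per-α path at minimum CV error.
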