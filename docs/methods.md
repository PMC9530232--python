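# Methods

`episig` implements the computational core of a cytokine-response signature
study in intestinal epithelium: differential expression in cytokine-treated
colonic organoids under a hierarchical negative-binomial model, derivation of
a top-n response signature, single-sample enrichment scoring of patient
cohorts, stratification of treatment outcomes by enrichment score, overlap
statistics against external gene sets, and cross-species fold-change
concordance. Every stage is exercisable on synthetic data whose generative
model matches what the inference stage assumes, so parameter recovery and
error control are machine-checkable.

## Differential expression model

Counts for one gene across samples are modeled as

    y_i ~ NegativeBinomial(mean = s_i * exp(eta_i), dispersion = phi)
    eta_i = beta_0 + beta_t[i] + beta_p[i] + beta_c[i]
    beta_t ~ Normal(0, sigma_1),  beta_p ~ Normal(0, sigma_2),
    beta_c ~ Normal(0, sigma_3)

with varying intercepts for treatment (t), subject/donor (p; repeated
measures), and cluster (c; sample-similarity groups found by PCA + Ward
clustering). The NB dispersion is in the mean/dispersion form,
**Var(y) = mu + mu^2/phi**; this variance convention is stated prominently
because "dispersion" is overloaded across tools. Size factors s_i
(median-of-ratios over zero-free genes) enter as a fixed multiplicative
offset rather than by pre-dividing the counts, keeping the likelihood an
honest integer-count NB.

Genes are fit independently (the model indexes a single gene's counts;
nothing couples genes), so results are order-independent and the whole
matrix is fit through one vectorized solver.

### Priors

Weakly informative and configurable (`Priors`): `beta0 ~ Normal(0, 10)`,
`sigma_k ~ HalfNormal(2)`, `phi ~ Exponential(0.1)`. With
`treatment_fixed=True` the treatment intercepts get a flat-ish
`Normal(0, 10)` instead of the hierarchical prior.

### Inference

Two modes:

* **laplace** (default, deterministic). For fixed hierarchical SDs, the
  location parameters and log(phi) are maximized by a damped Newton ascent
  with eigenvalue-shifted steps (the penalized likelihood can be locally
  indefinite; an unmodified Newton direction stalls). The hierarchical SDs
  are then handled on a fixed multiplicative grid using the
  Laplace-approximated marginal posterior: sigma_2 and sigma_3 are profiled
  (coordinate search), while **sigma_1 — weakly identified when there are
  only two treatment levels — is integrated**: the posterior is represented
  as a quadrature mixture of Gaussian (Laplace) components along the
  sigma_1 grid, weighted by the marginal posterior times the grid cell
  width. Joint maximization over (beta, sigma) is deliberately avoided: the
  funnel makes the joint mode degenerate at sigma = 0. The mixture matters
  in practice: profiling alone over-shrinks two-level treatment contrasts
  by ~0.15 on the natural-log scale and underestimates tail mass.
* **sample**: affine-invariant ensemble MCMC (emcee) over all parameters
  including the SDs on the log scale, initialized near the Laplace mode;
  32+ walkers, 1200 steps, half discarded, thinned. Used as a cross-check
  and for genes where the Gaussian approximation is in doubt. The two modes
  agree on treatment contrasts to well within +/-0.15 on high-count genes
  (tested).

p-values are two-sided posterior tail probabilities of the treatment
contrast computed from draws, floored at 1/(n_draws+1); a Wald alternative
(`p_method="wald"`) uses the Laplace mean/sd. BH adjustment is applied
across all non-filtered genes; the significance convention is q < 0.01.
Genes that fail to converge are flagged and reported with p = q = 1, never
silently dropped.

**Estimation vs testing.** For *effect-size estimation* with exactly two
arms we recommend (and the acceptance runs use) the fixed-effect treatment
configuration: with two levels, sigma_1 cannot be estimated meaningfully
from within one gene and any hierarchical prior shrinks |Delta| toward zero
(~ -0.1 at Delta = 1 under our defaults), while the sampling noise floor of
this design — sqrt(2 * trigamma(phi)/4) ~ 0.33 at phi = 5 with four
subjects per arm — leaves no budget for bias. For *hypothesis testing* the
hierarchical default is kept: its shrinkage makes the null calibration
conservative (measured null q<0.1 fraction ~0 at 2000 genes) at no material
cost in power (~0.95 at a two-log effect).

### Posterior predictive checks

Replicates are drawn from posterior parameter draws through the NB
observation model; tail probabilities are reported for mean, variance, max
and zero-fraction with the mid-probability tie convention
(Pr(>) + 0.5 Pr(=)) so that discrete statistics the model reproduces
exactly sit at 0.5 instead of saturating at 1.

## Filtering, normalization, clustering

Genes with average count below 3 across all samples are removed before
fitting. Size factors are median-of-ratios; genes containing any zero are
excluded from the reference set, and if no zero-free gene exists the
function asks for an explicit pseudocount. Sample clusters are derived from
log1p-normalized counts projected on leading principal components, Ward
linkage, k chosen by maximum mean silhouette over k = 2..min(6, n-1) with a
fallback to a single cluster when the best silhouette is below 0.25 (no
random initialization anywhere, so labels are reproducible).

## Gene-set scoring

* **Top-n signature**: among genes at q < 0.01 with the requested sign,
  take the n of largest |logFC|; ties break by smaller p, then gene id.
  Short sets are returned whole and flagged.
* **GSVA**: per-gene Gaussian-kernel CDF statistic across samples
  (bandwidth sd/4), per-sample ranking with the symmetric |G/2 - rank|
  weight, and a KS-like random walk per set; ES = max positive deviation +
  min negative deviation, hence bounded in [-1, 1]. The single
  max-deviation variant is available (`max_diff=False`). Zero-variance
  genes are dropped with a warning; sets below `min_size` yield NaN rows.
* **ssGSEA**: per sample, ES = sum over rank positions of (weighted in-set
  ECDF - unweighted out-set ECDF), weight = (rank from bottom)^alpha,
  alpha = 0.25; optional normalization by the global score range (both are
  the canonical published defaults and configurable).
* **Preranked GSEA**: running sum with |score|^weight in-set increments and
  uniform out-set decrements; ES is the signed maximum-magnitude deviation;
  the null permutes gene labels; NES = ES / mean |null ES| of matching
  sign; empirical p floored at 1/(n_perm+1); BH across sets. Rank ties
  break by stable input order — documented because the ES can depend on it.
* **Overlap statistics**: exact upper-tail hypergeometric p, expected
  overlap and fold enrichment within a caller-supplied universe. Gene ids
  match by exact case-sensitive string equality; no symbol aliasing.

Each engine is verified against an independently coded step-by-step oracle
to |diff| < 1e-9 and against closed-form toys.

## Cohort stratification

Expression is optionally centred on the control-sample mean per gene.
Enrichment scores are binned with left-closed thresholds
(-inf, 0), [0, 0.25), [0.25, inf) by default — honouring both an "ES < 0"
low stratum and an "ES >= 0.25" high stratum convention simultaneously.
Outcome rates are tabulated per stratum and arm; pairwise stratum
comparisons use the classical two-sided Fisher exact test (sum of tables
with probability <= observed; the source analyses report strata
descriptively, so the pairwise test choice is ours). Spearman correlations
carry Fisher-z confidence intervals (se = 1/sqrt(n-3)); measured coverage
at rho = 0.5, n = 100 is ~94.5% over 10,000 simulations. Ordinal
comparisons use Kruskal-Wallis with tie correction and Dunn's pairwise z
with Bonferroni adjustment (BH selectable).

## Cross-species concordance

Fold-change tables are joined through an ortholog map; any id appearing
more than once on either side is dropped before joining (no collapsing, no
double counting — auditable). Transcript-level concordance is Spearman with
the Fisher-z CI on the paired fold changes. Pathway-level concordance runs
this package's permutation-GSEA per species and correlates the NES across
sets; this replaces proprietary pathway activation z-scores and is recorded
as such in the output metadata.

## Synthetic data

`simulate_organoid_counts` draws from exactly the model the DE stage fits.
Defaults emulate a cytokine-stimulation organoid experiment: 2 arms x 4
donors (paired), 2 latent clusters, 10% of genes truly responding at +/-2
natural-log units (half up, half down — balanced power evaluation),
baseline log-means uniform on (3, 8) (about 20-3000 counts, i.e. genes that
survive the low-expression filter), gene dispersions uniform on (2, 20),
size factors uniform on (0.7, 1.4). Effect-size and dispersion magnitudes
are calibration choices — the source experiments do not publish them — and
are stated here as such. A `noise_seed` field redraws counts under
identical gene-level truth, supporting replicate-experiment studies.
True DE effects are point masses at +/-effect_size; where a property needs
a continuous effect-size spectrum (rank-based concordance), tests add
sigma_1 > 0, since rank correlation within an equal-effect cluster is
structurally noise.

`simulate_cohort` emulates a trial-like biopsy cohort on a continuous
log-intensity (microarray-like) scale, not counts: per-patient latent
activation a_s ~ Normal(1, 1) shifts each program gene by delta * a_s
(delta = 2 by default), controls sit at baseline, residual noise is
Gaussian (sd 1). Binary response is Bernoulli(logistic(gamma0 + gamma1 *
a_s)); gamma1 < 0 encodes "high program activation predicts non-response".
Default sizes (550 patients, 18 controls) match the scale of a phase-3
biopsy substudy. An ordinal neutrophil-infiltration-like subscore (0-3) is
discretized from the activation. What this generator does **not** emulate:
probe-level artifacts, batch effects, correlated gene-gene noise, or
non-program disease heterogeneity — so passing tests demonstrate the
pipeline's statistical behaviour under its own assumptions, not robustness
to those real-data complications.

`simulate_crossspecies_fc` draws paired fold changes from a bivariate
normal latent with correlation rho plus independent per-species noise; the
observable rank correlation is therefore attenuated below rho, and tests
compare against a large-n simulation of the same law rather than rho
itself.

One global seed expands into named, independent substreams per component,
so adding draws in one generator never perturbs another.

## Problem sizes in the test and acceptance runs

Parameter recovery uses 200 genes (2 x 4 design, Delta in {0, +/-1},
phi = 5, half the genes DE); false-discovery control uses three fully-null
2000-gene simulations; power uses 300 genes at Delta = 2; stratification
uses 10 cohorts of 400 patients; CI coverage uses 10,000 draws of n = 100;
concordance uses 20 draws of 1000 ortholog pairs. These sizes give the
Monte-Carlo error stated alongside each check.

## Known limitations

* With two treatment levels, sigma_1 is not identifiable from a single
  gene; the hierarchical treatment prior is a regularizer, not an estimable
  quantity, and its posterior is prior-dominated.
* The Laplace mixture approximates the posterior; heavy right tails of the
  dispersion posterior at n = 8 are captured only through the log-phi
  Gaussian component. The emcee mode exists for exactness at small scale.
* The empirical p-value floor (1/(n_draws+1), 1/(n_perm+1)) bounds
  attainable significance; raise the draw/permutation counts for deeper
  tails.
* GSVA kernel scores scale as O(G * n^2); genes are chunked for memory but
  very large cohorts are better served by ssGSEA.
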