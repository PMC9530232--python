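# episig

Cytokine-response signatures in intestinal epithelium: a tested pipeline
from organoid RNA-seq differential expression to patient stratification.

## The problem

Cytokines such as IL-22 reprogram the colonic epithelium. Given (a) counts
from cytokine-stimulated organoids, (b) expression profiles of patient
biopsies with treatment outcomes, and (c) curated gene sets, the questions
this package answers are:

1. Which genes does the cytokine regulate, accounting for donor pairing and
   latent sample structure?
2. How active is that transcriptional program in each patient's biopsy?
3. Does program activation stratify treatment response?
4. Is the program conserved across species?

It is aimed at computational biologists who want each of those steps as a
reusable, unit-tested library function (plus a thin CLI), with synthetic
generators that make every statistical guarantee checkable end to end.

## The models

**Differential expression.** Per-gene counts follow a hierarchical
negative binomial with varying intercepts,

```
y_i  ~ NB(mean = s_i · exp(η_i),  dispersion = φ),   Var(y) = μ + μ²/φ
η_i  = β₀ + β_t[i] + β_p[i] + β_c[i]
β_t ~ N(0, σ₁),  β_p ~ N(0, σ₂),  β_c ~ N(0, σ₃)
```

for treatment t, subject p (repeated measures per donor), and cluster c
(sample-similarity groups from PCA + Ward clustering); s_i are
median-of-ratios size factors entering as a fixed offset. The default
inference is a deterministic profiled-Laplace fit that *integrates* over
the weakly identified treatment SD (quadrature mixture of Laplace
components); an ensemble-MCMC mode (emcee) is available. p-values are
two-sided posterior tail probabilities of the treatment contrast
(natural-log scale), BH-adjusted with a q < 0.01 significance convention.

**Scoring.** Three enrichment engines implemented from their published
definitions and verified against independently coded oracles: GSVA
(kernel-CDF rank walk, ES ∈ [−1, 1]), ssGSEA (weighted-ECDF difference,
α = 0.25), and preranked GSEA (permutation null, NES, empirical p).

**Stratification.** Enrichment scores are binned at left-closed thresholds
(default 0 and 0.25 → low / mid / high), outcome rates tabulated per
stratum and arm with exact Fisher comparisons, Spearman correlations carry
Fisher-z confidence intervals, and ordinal covariates are compared by
Kruskal–Wallis with Dunn's follow-up.

**Cross-species.** Fold-change tables joined through a one-to-one ortholog
map (many-to-many rows dropped); Spearman concordance at transcript level,
or at pathway level via per-species preranked-GSEA NES.

See `docs/methods.md` for assumptions, priors, numerical choices and
limitations.

## Worked example

```python
from episig import *

# 1. a simulated organoid experiment: 2 arms x 4 donors, 10% true DE at ±2
design = SimDesign(n_genes=400, frac_de=0.1, effect_size=2.0, seed=7)
counts, meta, truth = simulate_organoid_counts(design)
de = run_de(counts, meta, contrast=("t1", "t0"), seed=7)
print("significant genes:", int(de["significant"].sum()))

# 2. signature of the most strongly induced genes
sig = top_n_signature(de, n=50, direction="up")

# 3. a simulated 400-patient cohort whose latent program activation
#    lowers response probability (gamma1 = -1.5)
params = CohortSimParams(n_patients=400, n_controls=18, delta=2.0,
                         gamma1=-1.5, seed=7)
expr, cohort, _ = simulate_cohort(params)
es = ssgsea_scores(expr, GeneSet("program", "", tuple(params.program_genes))).iloc[0]
strata = assign_strata(es[cohort["group"] == "patient"])
rates, pairwise = outcome_rates(cohort, strata, "clinical_remission")
print(rates.to_string(index=False))
```

Output:

```
significant genes: 35
   arm stratum            outcome  numerator  denominator     rate
active     low clinical_remission         26           51 0.509804
active     mid clinical_remission         36          109 0.330275
active    high clinical_remission         23          240 0.095833
```

All 35 detected genes are true positives (check `truth.genes`). The rate
table is the package's core clinical readout: patients with *low* program
activation (ES < 0) remit at 51% versus 10% in the *high* stratum
(ES ≥ 0.25) — the simulated encoding of "high program activation predicts
non-response", recovered end to end from expression data alone.

The same steps are available as a CLI for file-based work:

```bash
episig simulate-organoid --seed 7 --out-dir sim/
episig de --counts sim/counts.tsv --meta sim/meta.tsv --contrast t1:t0 --out-dir de/
episig signature --de de/de.tsv --n 50 --out-dir sig/
episig score --method ssgsea --expr cohort_expr.tsv --gmt sig/signature.gmt --out-dir es/
episig stratify --es es/es.tsv --cohort cohort.tsv --outcome clinical_remission --out-dir strat/
```

Every run writes a JSON manifest (config, seed, version, input checksums).

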