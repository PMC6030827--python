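# Methods

This document describes the statistical model implemented by
`tissuenets`, the defaults and the reasoning behind them, what the
synthetic compendium does and does not emulate, and the numerical
choices that matter for correctness.

## 1. Evidence extraction

For an expression dataset (genes × samples, `NA` allowed), evidence for
a gene pair is the Fisher transform of the Pearson correlation,
*z* = atanh(*r*), computed pairwise-complete with at least 3 shared
samples. |*r*| is capped at 0.999 (`MAX_ABS_CORRELATION`) so *z* stays
finite; atanh(0.999) ≈ 3.80, well above any correlation distinguishable
from 1 at realistic sample sizes, so the cap does not distort real
signal. Constant genes have undefined correlations and yield no
evidence. Pairs without a score are MISSING, not zero: absence of
measurement is not evidence of absence of a relationship.

Pre-scored evidence (e.g. binary interaction reports) can be supplied
directly as an `EvidenceMatrix` with `kind="binary"`.

## 2. Discretization

Continuous evidence is discretized into `n_bins` (default 5) quantile
bins. Interior edges are the *i*/`n_bins` quantiles; intervals are
right-closed (a value equal to an edge falls in the lower bin). Edges
that coincide because of ties, and edges at or above the maximum value,
are dropped, with a warning when bins collapse. Quantile bins guarantee
roughly equal occupancy, which keeps every CPT cell well estimated
regardless of the evidence's marginal distribution. Five bins is enough
to capture the monotone relationship between co-expression strength and
functional relationship while keeping CPTs small; more bins mostly add
estimation variance.

## 3. Gold standards and tissue specialization

A *global* standard is built from a functional gene-set collection by
co-annotation: a pair is positive when both genes share a term of size
in [`min_term`=3, `max_term`=300]. Very small terms are statistically
unreliable; very large terms (generic processes) would label almost
everything related. Negatives are pairs of genes that are each
annotated somewhere but share no term — the standard "annotated,
unrelated" heuristic.

Tissue specialization *drops* (rather than relabels) positives whose
genes are not both active in the tissue: absence of tissue evidence for
a pair is ignorance, not evidence the pair is unrelated, so demoting to
negative would poison the negative class. Retained positives are
weighted by the product of the two genes' tissue weights; negatives pass
through at weight 1. Tissue activity comes from a curated tissue→genes
map (GMT, weight 1) or from expression (mean expression above a cutoff,
weight = mean / max mean, capped at 1; multiple contexts pooled by
averaging per-gene means).

## 4. Naive-Bayes integration

Each dataset *d* contributes a CPT P(bin | FR) for FR ∈ {1, 0},
estimated from the weighted standard with Laplace smoothing
(count + *c*) / (total + `n_bins`·*c*), pseudocount *c* = 1 by default.
Smoothing keeps likelihood ratios finite when a bin has no labeled
pairs; one pseudo-observation per cell is the weakest prior that does
so.

The posterior multiplies per-dataset likelihood ratios onto the prior
odds, in log space (logit/expit), skipping MISSING datasets (likelihood
ratio 1). The prior defaults to `"auto"`, the standard's weighted
positive fraction. Co-annotation standards typically overstate the
genome-wide prior probability of functional relationship, so a fixed
prior (e.g. 0.05) can be supplied when calibrated posteriors matter;
*rankings* are unaffected by the prior, which shifts all log-odds
equally.

Conditional independence of datasets given FR is of course wrong for
overlapping expression compendia; the standard consequence is
over-confident posteriors, not reordered rankings, and the model's
robustness and transparency (per-dataset CPTs are directly
interpretable as dataset quality) are why naive Bayes is used here.

## 5. NetWAS

Genes with GWAS p < `cutoff` (default 0.01) are noisy positive labels;
an equal number (`negative_ratio` = 1) of seeded-random other genes are
negatives. Features are each labeled gene's network edge weights to all
network genes (self-weight zeroed). A linear SVM (C = 1) is trained
under stratified 5-fold cross-validation; each labeled gene is scored by
the model that did not see it, and unlabeled genes by the mean decision
value over the five models. The output is the full gene ranking by
hyperplane distance. At least 5 genes per class are required
(`InsufficientLabelsError` otherwise) so every fold contains both
classes.

The nominal cutoff is deliberately strict: the positive set need not be
complete, only enriched, and the SVM tolerates the label noise from
random negatives. A linear kernel keeps the method deterministic, fast,
and interpretable (weights over network neighbours).

## 6. Query and enrichment

A query retrieves the `max_genes` most connected genes, ranking
candidates by summed edge weight (at or above `threshold`) to the query
set, ties broken lexicographically. Coordinated multi-tissue views share
a single gene ordering: genes in several views first (by descending view
count, then name), then view-unique genes lexicographically, so the same
gene occupies the same visual position in every tissue.

Enrichment uses the hypergeometric upper tail
P(X ≥ k | N, K, n) with BH FDR adjustment. Query genes outside the
universe are dropped with a warning; terms with no universe overlap are
skipped.

## 7. Synthetic compendium

The simulator plants disjoint single-factor Gaussian modules: in a
dataset where a module is active, member expression is
√s·factor + √(1−s)·noise (module strength *s*, default 0.7), giving
pairwise correlation *s* in expectation; elsewhere members are pure
noise. Shared modules are active in every tissue's datasets;
tissue-specific modules only in their own tissue's. Tissue gene maps
contain the active module genes plus a 50% sample of background genes.
GWAS p-values are Beta(α, 1) (via u^(1/α)) for the disease module —
the first tissue-specific module of the first tissue — and Uniform(0,1)
elsewhere; α = 1 is an exact null.

What it does **not** emulate: overlapping or hierarchically nested
modules, hub genes and scale-free degree structure, batch effects and
confounded sample covariance, non-Gaussian counts, linkage
disequilibrium or gene-length bias in GWAS p-values, and incomplete or
biased annotation. Passing the simulation-based tests therefore shows
the pipeline recovers the signal class it models, not that it matches
performance on real compendia.

## 8. Numerical choices

- **Hypergeometric tail.** Computed as a log-space suffix
  log-sum-exp of log point masses built from `gammaln` log-binomials.
  A 1 − CDF route loses all precision once the tail is below machine
  epsilon; the log-space suffix sum preserves *relative* precision
  (verified to < 1e-10 against exact integer arithmetic) even for tails
  ~1e-100, which matters because deeply significant terms are exactly
  the interesting ones.
- **Posterior in log space.** Products of many likelihood ratios
  under/overflow in linear space; logit/expit arithmetic agrees with
  brute-force enumeration to 1e-12.
- **BH via `statsmodels`**, cross-checked against the definitional
  step-up.
- **Determinism.** All stochastic steps (simulation, negative sampling,
  fold assignment) take explicit seeds; identical inputs give
  byte-identical output files (6-decimal fixed formatting, sorted
  rows).

## 9. Limitations

- Naive-Bayes independence inflates confidence when evidence sources
  overlap; posteriors are best read as relative scores unless the prior
  and dependence structure are known.
- Co-annotation standards inherit annotation bias: well-studied genes
  dominate both classes.
- The tissue-specialization drop rule cannot create tissue-specific
  *negatives*; the negative class stays global.
- NetWAS requires enough nominally significant genes to label a
  positive class; underpowered GWAS cannot be rescued.
- NetWAS AUC under an exact null is calibrated only on average: with a
  handful of positive labels a single disease gene falling among the
  labels can swing a single run's AUC to near 0 or 1, so per-run null
  AUCs have very high variance even though their mean is ~0.5.
- Simulation results (module recovery, NetWAS gain) quantify behaviour
  under the generator of §7 only.
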