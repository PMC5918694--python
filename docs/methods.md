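# Methods

## Label integration

Aberration status is binary per sample and integrates two evidence channels
over a user-supplied gene target specification (oncogenes, tumor
suppressors, and an optional wider pathway panel):

- **Mutation evidence**: any non-silent somatic variant in a target gene.
  The non-silent set defaults to {Missense_Mutation, Nonsense_Mutation,
  Frame_Shift_Del, Frame_Shift_Ins, In_Frame_Del, In_Frame_Ins, Splice_Site,
  Nonstop_Mutation, Translation_Start_Site} and is configurable. No
  functional-impact prediction is attempted; oncogenicity annotations are
  carried through as metadata only.
- **Copy-number evidence**: GISTIC-style threshold call +2 in a target
  oncogene or −2 in a target tumor suppressor. ±1 calls never count.

Status is 1 iff either flag is set; both provenance flags are retained so
that mutation-only and copy-only label ablations are exact subsets.

## Sample and cancer-type filters

Hypermutated tumors carry target-gene mutations by chance and would inject
label noise, so samples whose log10(mutation_count + 1) exceeds the cohort
mean by more than five standard deviations (sample SD, ddof = 1) are removed
before labeling. The +1 guards zero counts; the center is the mean (the
median would be a defensible alternative; the mean was chosen and is fixed).
With fewer than two samples the SD is undefined and nothing is removed.

Cancer types are then retained only when they have **more than 15** positive
samples (strict inequality) **and** a positive fraction of **at least 5%**.
The 5% rule is read as a minimum positive fraction: the alternative literal
reading (negatives/positives ≥ 5%) would almost never filter anything and
would defeat the rule's balancing purpose. Filters run in the order
hypermutator removal → status construction → cancer-type filter, so type
proportions are computed on the burden-filtered cohort.

## Features

- **Gene block**: the k = 8,000 most variably expressed genes ranked by
  median absolute deviation, MAD(g) = median(|x_g − median(x_g)|). MAD ties
  are broken lexicographically by gene symbol so builds are deterministic.
  MAD ranking happens *before* target-gene removal, so dropping targets
  never promotes lower-MAD replacements. The target genes themselves (and,
  for the pathway-panel ablation, the 14-gene RASopathy panel) are removed
  so the model must learn the downstream response rather than target-gene
  dosage. When the cohort has fewer than k genes the full set is used.
- **Covariate block**: one 0/1 indicator per retained cancer type — the
  full set, with no reference level dropped, which is safe because the model
  is penalized — plus log10(mutation_count + 1).
- **Standardization**: gene columns and the burden column are centered and
  scaled (population SD, ddof = 0) with constants estimated on the training
  partition only and applied everywhere; indicator columns are left as 0/1.
  Zero-variance features are dropped with a warning. The constants are
  stored in the model artifact, which is what makes later cohort-wide or
  cross-gene scoring reproducible. Standardization is fitted on the full
  training partition, including samples that later serve as CV evaluation
  folds; this mild leakage is shared by most published pipelines of this
  design and does not touch the held-out test partition.

## Training

The classifier minimizes

    (1/n) Σ log(1 + exp(−m_i)) + α ( l‖w‖₁ + (1 − l)/2 ‖w‖₂² ),

where m_i is the signed logistic margin, by stochastic gradient descent
(scikit-learn's `SGDClassifier`, log loss, elastic-net penalty). The
intercept is unpenalized; covariate columns sit in the same design matrix as
genes and are penalized with them. Default grids are
l ∈ {0.15, 0.155, 0.16, 0.2, 0.25, 0.3, 0.4} and
α ∈ {0.1, 0.13, 0.15, 0.18, 0.2, 0.25, 0.3}; at these strengths the L1 term
drives most gene weights exactly to zero.

Partitioning is stratified jointly by (cancer type × status): 10% of each
stratum (rounded) is held out for the test set, strata of size one go to
train, and training samples are dealt cyclically into five folds with a
random per-stratum offset. Everything is deterministic given the config
seed. Grid cells are scored by mean AUROC over the evaluation folds, each
fold predicted by a model that never saw it; single-class folds are skipped
with a warning. Ties prefer smaller α, then smaller l. The final model is
refit on the full training partition at the best cell and evaluated once on
the test partition.

**SGD schedule**: the `optimal` learning-rate schedule, up to 30 epochs,
loss-change tolerance 1e-3, fixed seed, no weight averaging. Thirty epochs
is enough for the solutions visited by the default grids at desk-scale
problem sizes; convergence-sensitive checks (e.g. comparison against a
full-batch proximal-gradient solver) raise the epoch cap and tighten the
tolerance explicitly. One caveat of the `optimal` schedule: its step size
scales as 1/α, so at absurdly large penalties (α ≫ 10) the weights collapse
to zero as expected but the intercept barely moves from its initialization;
at moderate penalties the intercept-only fit recovers the base rate as it
should.

## Evaluation

AUROC is the Mann–Whitney rank-concordance probability (ties count ½). AUPR
is the **average-precision** estimator — precision at each positive's rank,
averaged — not trapezoidal interpolation, which is biased for PR curves; its
random baseline equals the positive prevalence. Both are computed per
partition (train / CV / test), per cancer type (single-class types are
flagged not-evaluable rather than erroring), and for cohort-wide or
excluded-type scoring through `score_cohort`, which standardizes with the
stored training constants and gives unseen cancer types all-zero indicators.

The benchmarking battery reruns the full pipeline with a single change per
run, all sharing one partition seed:

- **Shuffled-expression null**: each gene's values are permuted across
  samples (preserving per-gene marginals, destroying sample linkage);
  labels and covariates stay intact. With uninformative covariates the
  penalized fit collapses to a near-constant predictor, giving test AUROC
  ≈ 0.5 and AUPR ≈ prevalence.
- **Label ablations**: mutation-only and copy-only status.
- **Feature ablations**: keep target genes, drop the RASopathy panel,
  expression-only, covariate-only. Gene-weight vectors are comparable
  across models by re-inserting dropped genes as zero weights.
- **Within-type models**: independently grid-searched single-type models
  (without type indicators) against the pan-cancer model's per-type CV
  AUROC.
- **Cross-gene evaluation**: an existing model scored against labels built
  from a different target spec, optionally excluding samples positive for
  the model's own targets — the phenocopy analysis.

Differential expression is a per-gene ordinary least-squares fit of
zero-one (min-max) normalized expression on status plus cancer-type
indicators (one level absorbed by the intercept), reporting the status
coefficient's t statistic, two-sided p, and Benjamini–Hochberg q.
Empirical-Bayes variance moderation is deliberately not implemented:
moderation matters at small n, and this analysis targets cohorts of
hundreds to thousands of samples. Constant genes are flagged with NaN
statistics. The t statistics are invariant to per-gene affine rescaling of
the input because the min-max step absorbs it.

## Transfer scoring

External profiles are scored as s = σ(Σ_g w_g z_g + b) where z is computed
by z-scoring each gene **within the external dataset** (not with the
training constants — the external platform and scale are arbitrary).
Covariate terms are omitted: external profiles carry no cancer-type or
burden covariates. Model genes missing from the external data, or with zero
variance there, contribute 0; scoring is refused below a configurable
minimum gene coverage (default 90%). Scores are therefore invariant to
per-gene affine transforms and to gene column order of the external matrix.

Downstream statistics: confusion counts at a fixed 0.5 threshold with
precision / NPV / accuracy as percentages (undefined ratios flagged);
variant-level mean scores keyed by (gene, nucleotide or protein change);
Pearson chi-square on 2×2 enrichment tables **without** continuity
correction (df = 1); Welch's unequal-variance t-test between score groups;
per-(drug, group) least-squares regressions of drug activity on score with
a Bonferroni family threshold of 0.05/(n_drugs × n_groups); and multi-hit
stratification of scores by core-gene status × number of other-pathway-gene
hits, bucketed 0 / 1 / 2 / 3+, separately for mutation and copy evidence.

## The synthetic-cohort generator

`simulate_cohort` emulates the statistical structure the pipeline assumes:

- Per-gene standard-normal baseline expression; aberrant samples shifted by
  `effect_size` (in SD units, default 1.0) on `n_signal_genes` randomly
  chosen non-target genes. Defaults: 1,000 samples, 2,000 genes, 100 signal
  genes, three cancer types at 20% aberration prevalence.
- Positive labels evidenced by a non-silent mutation in a random target
  oncogene or, with probability `copy_fraction` (default 0.2), a +2 copy
  call; copy evidence is generated independently of mutation evidence given
  the label.
- Background mutations at a Poisson rate (default 50/sample) in non-target
  genes, with realistic HGVS-style annotations on planted target variants;
  hypermutators (default 2%) draw at a 20× inflated rate from **all** genes,
  so they acquire target-gene mutations by chance — exactly the label noise
  the burden filter removes. Sparse ±1 copy-number background noise.
- Optional phenocopy genes: samples that carry the same expression
  signature plus a mutation in the phenocopy gene but no core target event.
- Fully deterministic given the seed.

`simulate_external_profiles` generates cell-line-like profiles on an
arbitrary per-gene scale (means ~100, SDs ~10) so transfer z-scoring is
actually exercised; mutant profiles carry the signature shift on a chosen
gene subset.

What the generator does **not** model: real gene–gene correlation
structure, RNA-seq count distributions, batch effects, mutation spectra, or
the dependence between mutation and copy evidence. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that it recovers
planted signal under its own assumptions — not that any particular
performance level will be attained on real tumor data.

## Numerical and interface choices

- Sample ordering is canonicalized lexicographically at load; the cohort
  sample universe is the intersection of the expression, copy-number and
  covariate tables (a sample with zero mutation rows is legitimate).
- Missing expression values are a hard load error; no imputation rule is
  defined. Gene identifiers are opaque symbols; no alias resolution.
- Matrix TSVs round-trip exactly: floats are written at shortest-repr
  precision and parsed with round-trip precision.
- Model artifacts are a single versioned text file (header + per-feature
  weight table, floats at full repr precision); zero-weight genes are pruned
  on save; truncated files or version mismatches fail loudly without
  returning a partial model.
- Hard classification threshold is fixed at 0.5 wherever a binary label is
  needed.
- Desk-scale problem sizes used by the test suite and the acceptance script
  (hundreds to a few thousand samples, hundreds to 2,000 genes, five null
  seeds) were chosen so the full statistical structure is present while a
  single-CPU run stays short.

## Known limitations

- SGD solutions are stochastic; sparsity-versus-penalty monotonicity holds
  in the majority direction over seeds rather than exactly per seed.
- Covariate columns are penalized along with genes (only the intercept is
  exempt). An unpenalized-covariate variant was not implemented.
- The within-type comparison refits single-type models with the same
  pipeline; types failing the event filters on their own are skipped.
- Transfer scoring assumes external profiles are comparable after per-gene
  z-scoring; platform effects that do not reduce to per-gene affine
  transforms are not corrected.
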