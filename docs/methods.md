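# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohort generator does and
does not emulate, and the numerical conventions that make runs
reproducible.

## Conditional mutual information on binarized data

Tissue microbiome abundances are zero-inflated, heavy-tailed and
measured on an arbitrary scale; bulk expression (FPKM) is log-normal-ish
with its own scale.  Rather than model either marginal, every feature
is reduced to a binary high/low state at its median across all samples
(below → 0, at or above → 1; even sample counts use the mean of the two
middle order statistics).  The dependency of gene G on microbe M given
phenotype P is then the plug-in conditional mutual information of three
binary variables,

    I(G; M | P) = Σ_{g,m,p} (n_gmp/n) · log2( n_gmp · n_p / (n_gp · n_mp) ),

with 0·log 0 := 0.  Logarithms are base 2, so values are in bits and
bounded by 1; the base cancels out of every rank-based decision
(p-values, edge sets).  The estimator is non-negative and equals zero
exactly when the empirical table factorizes conditionally.

**Conditioning direction.**  "Dependency of the gene on the microbe in
the context of phenotype" is read as I(G;M|P), which is also the
direction consistent with permuting the microbe vector in the
significance test; the alternative reading I(G;P|M) (phenotype–gene
dependence given the microbe) is available through the
`direction="gp_given_m"` flag of `permutation_test` and
`build_dependency_network`.

**Degenerate features.**  A feature whose binarized column is constant
(typical for taxa absent from more than half the samples, whose median
is 0 and which therefore map to all-ones) carries no information and
makes the permutation null a point mass.  Such features are flagged by
`binarize_median` and excluded from the network with a warning;
`permutation_test` on a constant input returns (0.0, p = 1).

## Permutation significance

Per pair, the real CMI is compared against `n_perm = 1000` null values
obtained by permuting the microbe vector (gene and phenotype fixed).
Two p-value conventions are implemented:

* `add_one` (default): p = (1 + #{null ≥ real}) / (n_perm + 1).  This
  is a valid permutation p-value — it can never reach 0 and is
  super-uniform under the null.
* `literal_rank`: the descending rank of the real value within the
  null distribution divided by `n_perm` (clipped at 1).  Kept because
  it is the convention some practitioners expect; it differs from
  `add_one` by at most one rank unit.

Ties between real and null values count toward the null, a conservative
choice that matters for the discrete CMI values of small samples.  No
multiple-testing correction is applied by default — edges are called at
a flat α = 0.05, matching common practice for exploratory dependency
networks — but `fdr=True` switches significance to Benjamini–Hochberg
adjusted p-values.

The flat threshold has a direct consequence worth stating: on a table
with E null pairs the network is expected to contain about 0.05·E false
edges.  The measured type-I rate of the test on null simulations is
0.045–0.05 (slightly below nominal because of the add-one correction
and ties), inside the calibration band [0.03, 0.07] asserted by the
test suite.

**Per-pair substreams.**  Pair (i, j) draws its permutations from a
generator seeded by `SeedSequence(seed, spawn_key=(i, j))`.  Results
are therefore invariant to evaluation order and safe to parallelize,
and any single pair can be recomputed in isolation.

## Synthetic paired cohorts

No public cohort with this paired T/PT multi-omic design is available,
so correctness is established against a generator with known truth.

* **Microbes.**  Counts are negative binomial with dispersion fixed at
  1.0 and per-taxon means log-normal across taxa (log-mean ln 10,
  log-sd 1.0) — heavy-tailed low-biomass profiles without extra knobs.
  Paracancerous samples have their mean multiplied by `pt_enrichment`
  (default 2.0), reproducing the higher abundance and richness of PT
  tissue.  Structural zeros occur independently with probability
  `zero_inflation` (default 0.2).
* **Expression.**  Log-normal: per-gene log-mean N(3, 1), within-gene
  log-sd σ = 1.0.
* **Planted dependencies.**  A planted pair (m, g, δ) adds +δ·σ to the
  log-expression of g in exactly the samples whose abundance of m is at
  or above m's median across all samples.  This split is the same
  binarized state the CMI stage measures, so δ maps directly onto
  detection power (δ = 2 gives per-pair power ≈ 1 at 30 pairs; δ = 0 is
  exactly the null).  A within-stratum median split was considered and
  rejected: once PT enrichment separates the strata it disagrees with
  the measured binarized state for ~15% of samples and silently
  attenuates δ.  For the same reason taxa carrying planted pairs are
  drawn without structural zeros and with their mean floored at the
  across-taxa median — a taxon absent from most samples binarizes to a
  constant and cannot host a planted dependency at all; key taxa in
  this design are high-abundance taxa, so the exemption matches what
  the planted signal emulates.
* **Response cohorts.**  Covariates are drawn from ranges typical of
  routine NSCLC clinical chemistry: Ca ~ N(2.35, 0.15) mmol/L, Age ~
  U(35, 80) years, HGB ~ N(135, 15) g/L, HCT ~ N(0.41, 0.04), ALT
  log-normal with median 25 U/L, and PT Prevotella relative abundance ~
  U(0, 0.2).  The latent score is the panel's linear combination plus
  N(0, noise_sd) (default 50 score units); the label is CBR iff the
  latent score strictly exceeds the cutoff.  Under the published panel
  these ranges put the score distribution astride the 720.7 cutoff, so
  both labels occur at realistic frequencies.

All randomness flows from the single config seed through one numpy
Generator; identical configs are bitwise reproducible.

**What the generator does not emulate:** read-level sequencing noise
and taxonomic misassignment, compositional closure effects, batch
effects, covariance among taxa or among genes, and any real biological
coupling between the microbial and response modules.  Tests passing on
this generator demonstrate that the machinery detects exactly the
dependency structure it is pointed at, under clean marginals — not that
the method is robust to the full messiness of tissue microbiome data.

## Key-taxon funnel

GDMs (microbes with ≥ 1 network edge) are filtered three ways and
intersected:

1. **Differential enrichment:** two-sided paired Wilcoxon signed-rank
   on per-pair T vs PT relative abundances, zero differences discarded
   (classic convention), p < 0.05.
2. **Discriminative power:** a 100-tree random forest on relative
   abundances vs phenotype.  Both mean decrease in accuracy
   (permutation importance, 10 shuffles per taxon) and mean decrease in
   impurity (Gini) are computed; since neither is canonical the default
   ranking averages the two rank positions, and the top 20 qualify.
3. **Tissue abundance:** top 10 taxa by mean relative abundance, ties
   broken lexicographically for determinism.

The forest consumes relative abundances, not binarized states:
binarization is specific to the information-theoretic stage, while
discrimination benefits from the full abundance profile.

## Diversity

Alpha indices follow classic community-ecology conventions: Chao1 in
the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) (defined when no
doubletons are observed; requires integer counts), Shannon with the
natural logarithm, Simpson as 1 − Σp².  Beta distances are Bray–Curtis,
binary Jaccard on presence/absence, and Euclidean; the distance between
two all-zero samples is defined as 0 with a warning.  PCoA is classical
scaling (Gower centering, eigh); only positive-eigenvalue axes are
embedded and negative eigenvalues are reported unembedded.

PERMANOVA is the one-way pseudo-F on the standard among/within
partition of squared distances, with p from label permutations and the
add-one correction (default 999 permutations).  It is implemented
in-package so the permutation stream is seeded and R² is reported; the
pseudo-F agrees with scikit-bio's implementation (asserted in the test
suite), and its type-I error on null simulations sits in [0.03, 0.07].

## Immune infiltration

ssGSEA per sample: genes ranked by expression (descending; average
ranks on ties, deterministic gene-id tie-break for the traversal
order), in-set rank weights rank^0.25, enrichment score = sum over the
ranked list of the running difference between cumulative normalized
in-set weight and the cumulative uniform out-of-set step.  Scores are
deliberately left unnormalized across samples: the downstream use is
Spearman correlation against taxa abundances, which is invariant to any
common monotone rescaling.  For the same reason a prior log transform
of FPKM is inert.  The 28 published immune cell-type signatures are not
redistributed; `synthetic_immune_gene_sets` generates a synthetic
stand-in collection for exercising the stage, and any real GMT file can
be supplied instead.

## Response predictor

The published panel is encoded verbatim on raw clinical units
(coefficients 9.675, 1.749, 8.086, 3.332, −1.676, −5.930; cutoff
720.7; responder iff score strictly above the cutoff).  No rescaling is
applied — the magnitude of the cutoff relative to the Age and HGB terms
implies raw units, and the panel is a fixed published artifact, not
something refit here.

Per-biomarker associations use a plain binomial logistic fit (IRLS via
statsmodels).  The source analysis calls this a GLMM but specifies no
random effect, so the "mixed" label is treated as nomenclature; this is
recorded prominently because it changes nothing numerically but could
confuse a reader expecting variance components.  Complete separation is
detected and flagged rather than reported as a converged estimate.  ROC
uses the rank-statistic AUC (ties ½), identical to the trapezoidal
area.  The 8:2 split is stratified by outcome — not part of the source
description, but an unstratified split of a ~100-patient cohort too
easily yields a single-class validation fifth.

Parameter-recovery checks refit the panel on large synthetic cohorts
and assert sign recovery for Age, HGB and ALT only: the Ca, HCT and
PT_Prevotella terms contribute under one score unit of spread against
noise of order 50–100, so their signs are not identifiable at any
desk-scale n and asserting them would test the noise, not the code.

## Pipeline and determinism

A run is one flat config (YAML or `RunConfig`), one output directory,
one manifest.  Stage order is fixed (simulate → preprocess → cmi →
key-taxa → diversity → infiltration → predict); dependencies are
validated before execution.  Every output is TSV; the manifest records
the config echo, SHA-256 checksums per output, captured warnings,
package version and timestamps.  With a fixed seed the result tables
are byte-identical across runs (the manifest differs only in its
timestamps).  Default problem sizes for the bundled synthetic runs (30
pairs, 20 taxa, 50 genes, 1,000 permutations) keep a full end-to-end
run at a few seconds on one CPU while leaving every statistical check
well-powered.

## Known limitations

* The CMI stage is specific to two-level phenotypes and binarized
  features; continuous estimators and higher-order conditioning are out
  of scope.
* The flat α = 0.05 edge threshold implies a ~5% false-edge floor by
  construction; use the FDR flag when the edge list feeds downstream
  enrichment.
* Chao1 is undefined on relative abundances (integer counts required);
  the pipeline skips it automatically for non-integer tables.
* The published panel's covariate units are those of the source
  cohort's laboratory; applying it to data in different units requires
  conversion before scoring, which the package does not attempt to
  guess.
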