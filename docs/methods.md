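# Methods

## Problem setting

Paired dental-plaque samples (a caries lesion and a non-caries site from the
same child) are collected in two cohorts, AA (n = 12 subjects) and LAH
(n = 7). RNA-seq reads from each sample are assigned to genes of specific
species, and the within-subject caries/non-caries contrast is estimated per
cohort. The questions the pipeline answers are: which (species, gene)
features respond to caries in both cohorts, which in only one, and whether
functions (KEGG orthologs) that respond in both cohorts are carried by the
same or by different species.

## Unique-region read counting

Homologous genes of related oral species can be nearly identical, so a read
placed by best alignment alone would often be assigned to the wrong species.
The reference build therefore computes, for every gene, the regions unique
to it: position *p* of gene *g* is unique iff every k-mer of *g* overlapping
*p* occurs — as a canonical, strand-collapsed k-mer — in exactly one
(species, gene) of the whole catalog, namely *g*. Masks are the maximal runs
of unique positions. Only alignments overlapping a unique region by at least
`min_unique_overlap` (default 1 bp) are counted.

Choices worth knowing:

- **k defaults to 14**, the seed length of the aligner, so "unique" and
  "seedable" coincide. Uniqueness is verifiable by a brute-force census, and
  unique coverage is monotone non-decreasing in k.
- **Canonical k-mers**: a gene duplicated in reverse complement is not
  unique; transcript orientation is not trusted.
- **ALL-vs-ANY**: a position is unique only when *all* covering k-mers are
  unique (conservative). The permissive ANY variant is available via
  `mode="any"` but off by default.
- A k-mer repeated *within* one gene still counts as unique to that gene;
  within-gene repeats cannot cause cross-species misassignment.
- Genes shorter than k get an empty mask and a warning.

The prevalence rule for choosing catalog species (union over samples of each
sample's top-150 species with >= 1,000 assigned reads) is implemented
per-sample-then-union, with a `pooled=True` alternative; ranking ties break
lexicographically. Species lacking gene annotations borrow the gene set of
the closest congener, "closest" operationalized as longest shared name
prefix, then lexicographic order — deterministic, since no phylogeny is
available.

## Seeded alignment

Reference genes are seeded with 14-mers every 2 bp; a read's k-mers (every
offset, both strands) vote for (gene, strand, diagonal) candidates with a
±2 bp diagonal tolerance. A candidate with >= 4 seed hits triggers a full
ungapped extension; identity = matches / read length, with overhang beyond
the gene counted as mismatch. The best candidate is kept at identity >= 0.9;
identity ties across genes make the read *ambiguous* (never counted);
a kept alignment without sufficient unique-region overlap is
*aligned_nonunique* (recorded, not counted). Limitations: no indels (the
generator produces substitution errors only) and no quality-aware scoring.
On error-free reads the assigned set equals a brute-force exhaustive
substring oracle, and 100% of reads lying wholly inside unique regions are
assigned to their true source.

## The paired NB model

Design: `~ Subject + Group + CariesStatus + Group:CariesStatus`. Subjects
are nested in groups, so the group main effect is aliased with the subject
dummies and dropped; the within-group caries contrasts — the only quantities
used downstream — are unaffected. Fits use a log size-factor offset
(median-of-ratios factors rescaled to geometric mean 1) and a fixed
per-feature dispersion.

- **Dispersion**: a Poisson working fit supplies fitted means; alpha solves
  the Pearson moment equation `sum (y-mu)^2 / (mu + a mu^2) = n - p`
  (residual-df corrected), then is shrunk 50/50 in log space toward a trend
  `a(mu) = a0 + a1/mu` fitted across features, floored at 1e-8. Recovery
  tests confirm median estimates within [0.1, 0.4] when the truth is 0.2 and
  near zero on Poisson data.
- **Wald tests** use the raw (unshrunken) contrast against a standard normal
  reference, the convention of count-model DE tools. A t(n−p) reference was
  also evaluated and proved conservative here, because the moment dispersion
  estimator already pays the residual-df penalty; the normal reference is
  well calibrated on pure-null simulations (P(p < 0.05) ≈ 0.04–0.05 per
  contrast at 2,000 features).
- **Shrinkage**: reported log2 fold changes are posterior modes under a
  zero-centered Cauchy prior — an intentionally light approximation of
  apeglm's heavy-tailed empirical-Bayes prior. The prior scale is the median
  absolute raw LFC of the contrast family (for a Cauchy, median |X| equals
  the scale), floored at 0.05. Heavy tails leave large effects nearly
  untouched while pulling noisy small ones toward zero; contraction
  (|shrunken| <= |raw|, sign preserved) is guaranteed by construction, with
  an explicit comparison against 0 because a Cauchy-Gaussian posterior can
  be bimodal.
- **BH adjustment** is per contrast family; NaN p-values (non-converged or
  all-zero features) pass through and do not count toward m. Whether the
  published analysis pooled families is unknowable from the text; the
  per-contrast choice is flagged here.
- Internal link is natural log; everything reported is converted to log2.

## Labeling and convergence

SDE: `padj <= 0.05` and `|shrunken log2FC| > 0.58` (strict inequality on the
fold change). Labels: both-SDE → shared; one-SDE → shared when the other
cohort's shrunken LFC is within 0.5 log2 units *and shares the sign* of the
significant one (the sign guard prevents a small opposite-signed effect from
being "similar"; the literal unsigned window is available via
`rescue_sign_guard=False`); otherwise `<group>_only`. Both-SDE genes with
opposite signs are shared/opposite; the rescue rule is symmetric between
groups. Opposite counts come only from both-SDE genes.

Consistency: per subject, the size-factor-normalized caries/non-caries ratio
with pseudocount 0.5; a subject is consistent with an up (down) gene at
ratio >= 2 (<= 1/2); a cohort's consistency for a gene is the fraction of its
subjects consistent, and the cohort average is taken over SDE genes.

KO categories: a KO with several functional-hierarchy paths takes the path
most frequent among SDE genes' KOs, ties to the deeper path, then
lexicographic. Convergence: per KO and cohort, the species set of its SDE
genes; the KO-level direction is the majority sign of those genes. KOs SDE
in both cohorts with matching direction are classified
identical_attribution / overlapping_but_different / no_overlap (the
convergence signal); single-cohort KOs are group_specific. Categories are
mutually exclusive and exhaustive over KOs with any SDE gene.

## Synthetic data

The generator is the testbed's ground truth, emulating the study layout: two
cohorts of 12 and 7 subjects, two samples per subject, and a pan-species
gene catalog (default 12 species x 50 genes of 600 bp, 40 KOs cycling over
gene slots so each KO spans species).

- Counts: NB with variance mu + alpha mu^2; per-feature baselines log-normal
  around 200 (sigma 0.3); per-feature dispersions log-normal around the
  design alpha 0.1 (sigma 0.3) so dispersion estimation is non-trivial;
  alpha = 0 gives exact Poisson. Subject effects are log-normal (sigma 0.3)
  multiplicative factors shared by a subject's two samples; library size
  factors are log-uniform over [0.5, 2].
- Planted classes partition features: shared up/down, group-specific,
  opposite, null, with per-group log2 effects of +/-1.5 by default. The
  defaults (baseline 200, dispersion 0.1, |lfc| 1.5) are moderate-depth,
  moderately overdispersed values typical of per-gene metatranscriptome
  counts; they were fixed once as the study conditions of all calibration
  and recovery checks.
- Reads: single-end (assignment logic is identical per mate; mate pairing is
  a non-goal), uniformly positioned, reverse-complemented with probability
  0.5, substitution errors only, constant FASTQ quality. Read names encode
  `species|gene|start|strand|serial` so assignment oracles are exact.
- `make_convergent_truth` plants KO-level convergence: per chosen KO, one
  species' genes DE only in cohort A and a disjoint species' genes only in
  cohort B.

What the generator does *not* emulate: rRNA carryover, host contamination,
adapters, strand chemistry, indels, gene-length and GC biases, and any
calibration to the real cohort's count distributions (the source study
publishes no per-gene distributions). Passing tests therefore demonstrate
correctness of the algorithms and calibration of the statistics under a
clean NB world, not performance on real plaque metatranscriptomes.

## Problem sizes and numerics

Verification runs use sizes chosen to make Monte-Carlo error small relative
to the tolerances while staying desk-scale: 2,000 features for null
calibration, 1,000 for effect recovery, a 40-KO / 10-species catalog for
convergence, 10,000 reads for the aligner oracle, 30 genes x 3 values of k
for the mask census, and the default design for the end-to-end run. The
pipeline's own accuracy claims (e.g. label-rule and mask agreement = 100%,
aligner agreement >= 99%) are recomputed by `scripts/acceptance.py`, never
hard-coded.

Numerical details: GLM fits are IRLS with up to 100 iterations;
non-convergence yields NaN p-values that are flagged and excluded from BH's
m. The shrinkage optimizer is bounded scalar minimization between 0 and the
raw estimate (xatol 1e-10). Dispersion trend fitting needs >= 10 informative
features, else raw moments are used. All randomness flows from explicit
integer seeds; identical seeds give byte-identical outputs.

## Known limitations

- The shrinkage prior is a fixed-form Cauchy, not apeglm's fitted t prior;
  numerical agreement with DESeq2+apeglm outputs is approximate by design
  (raw LFCs agree with pydeseq2 to ~0.002 median absolute difference on a
  paired design; shrunken values follow the same ordering but not the same
  magnitudes).
- The aligner is ungapped and substitution-only; indel-containing reads
  would be unassigned rather than recovered.
- With `min_unique_overlap = 1`, a single unique base suffices to count an
  alignment; stricter values trade sensitivity for specificity.
- Cohort descriptive statistics default to the pooled-variance t-test
  (Welch by flag) and two-sided Fisher exact tests; with n = 12 + 7 these
  detect only large effects.
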