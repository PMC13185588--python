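# plaquetx

Species-resolved comparative metatranscriptomics for paired dental-plaque
studies. The package implements, end to end and on synthetic data with
planted ground truth, the analysis used to compare caries-associated
microbial gene expression between two cohorts of children with early
childhood caries: reads are assigned to (species, gene) features only where
the gene's sequence is unique within a pan-species catalog, a paired
negative-binomial interaction model yields within-cohort caries contrasts
with shrunken log2 fold changes, genes are labeled shared or cohort-specific,
and KEGG-ortholog (KO) level species attribution reveals functional
convergence — distinct taxa filling the same functional niche in different
populations.

## Who it is for

Researchers analysing paired (lesion vs healthy site, within subject)
metatranscriptomes across two cohorts who need species-level gene resolution,
and anyone who wants a fully synthetic, truth-known testbed for this class of
pipeline.

## The model

For feature *i* (a gene of a species) in sample *j*, counts follow a
negative binomial with log link,

```
log mu_ij = log s_j + Subject_j + Caries_j * (beta_i + gamma_i * I[group_j = B])
Var(y_ij) = mu_ij + alpha_i * mu_ij^2
```

i.e. the design `~ Subject + Group + CariesStatus + Group:CariesStatus`,
where `s_j` are median-of-ratios size factors and the group main effect is
aliased with the subject terms (subjects are nested in groups) and dropped.
The caries effect in the reference group is `beta_i`; in the other group it
is `beta_i + gamma_i`. Per-feature dispersions `alpha_i` come from a Pearson
moment equation shrunk toward a mean-dispersion trend; Wald tests use the
raw coefficients; reported log2 fold changes are posterior modes under a
zero-centered Cauchy prior whose scale is fit from the data (apeglm-style
shrinkage). p-values are Benjamini–Hochberg adjusted per contrast family.

A gene is significantly differentially expressed (SDE) in a cohort when
`padj <= 0.05` and `|shrunken log2FC| > 0.58` (log2 1.5). Genes SDE in both
cohorts are **Shared**; a gene SDE in one cohort is rescued into Shared when
the other cohort's fold change has the same sign and lies within 0.5 log2
units; otherwise it is **AA only** / **LAH only**. Shared genes with
opposite-signed effects are direction **opposite**. Per KO and direction,
the species contributing SDE genes in each cohort are compared: identical
attribution, overlapping-but-different, or no overlap (functional
convergence), with KOs SDE in a single cohort reported as group-specific.

Counting is restricted to *unique regions*: a gene position is unique iff
every canonical k-mer covering it (default k = 14, matching the 14 bp / 2 bp
interval / 4-hit seeded aligner) occurs in exactly one (species, gene) of
the catalog. Reads whose best alignment does not touch a unique region are
recorded but never counted, which prevents cross-species misassignment
between homologous genes.

## Worked example

```
python examples/paired_differential_expression.py
```

simulates 400 features across 10 species for 12 + 7 subjects (two samples
each) with planted effects of |log2FC| = 1.5, runs the paired model and the
labeling rule, and prints:

```
label counts (rows: planted truth, columns: called label):
label        AA_only  LAH_only  none  shared
klass
groupA_only       20         0     0       0
groupB_only        0        20     0       0
null              0         0   312       0
opposite          0         0     0       8
shared_down       0         0     0      20
shared_up         0         0     0      20

average fraction of subjects with a >= 2-fold concordant change per SDE gene:
  AA: 0.75
  LAH: 0.75
```

Every planted class is recovered: genes DE in both cohorts (including the
opposite-direction ones) are labeled shared, cohort-specific genes get their
cohort's label, and no null feature is called. The consistency figure is the
average, over SDE genes, of the fraction of a cohort's subjects whose paired
samples individually change at least twofold in the called direction.

Other examples: `examples/unique_regions.py` (mask construction around a
planted shared block), `examples/functional_convergence.py` (KO-level
no-overlap attribution), `examples/full_pipeline.py` (reads through the
aligner, end to end). The same stages are exposed as a CLI:

```
plaquetx run-all --seed 42 --outdir out/
plaquetx simulate|build-db|assign|dge|compare|summarize --help
```

`run-all` writes the catalog FASTA, per-sample FASTQ, mask BED, count/DGE/
label TSVs, and a JSON + Markdown report under `--outdir`.

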