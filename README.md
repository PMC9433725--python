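# seqfinemap

Case–control fine-mapping for targeted-sequencing panels: a variant-QC
cascade, per-variant allelic association, and sequential conditional
logistic regression that partitions each associated region into lead-SNP
tagged signal clusters ("haplotypes").

## Who this is for

Groups that deep-sequence disease-associated loci in a case–control cohort
(rather than relying on array + imputation) and need a reproducible
post-calling analysis: which variants survive hard QC, which are associated
with the phenotype, and how many statistically independent signals each
region carries.

## The method

**QC cascade.** Starting from a joint multi-sample VCF, sites pass through
ordered hard filters, each with a per-site audit trail: an exact
Hardy–Weinberg test in each control batch (exclude *P* < 0.001), mean
genotype quality (exclude mean GQ < 30 in any batch × phenotype group),
per-group missingness (> 0.05), batch intersection, low-complexity-region
overlap, case–control differential missingness (Fisher *P* < 0.05),
phred-scaled excess heterozygosity (one-sided exact *P* ≤ 3.4×10⁻⁶), an
external pass/fail flag, and a reference-population allele-frequency
outlier filter (|z| ≥ 9 on the control-vs-reference AF difference).

**Association.** For each retained site, a two-sided Fisher exact test on
the allele-count table (alt/ref × case/control); each diploid contributes
two alleles. The odds ratio is the sample cross-product ratio. Variants
with *P* < 0.001 are *informative* (no multiplicity adjustment: the panel
targets loci with previously established association).

**Haplotype decomposition.** Within a region, the most associated variant
becomes the first lead SNP. Every other informative variant is re-tested by
logistic regression of case status on additive dosage conditioning on all
current leads; while any variant keeps a conditional Wald *P* < 0.1, the
smallest becomes the next lead. On exit, each non-lead variant joins the
lead it is most correlated with (cohort genotypic r²), so the informative
set is partitioned into signal clusters. A "haplotype" here is a
statistical cluster — the variants whose association vanishes given their
lead — not a phased segment.

**Synthetic cohorts.** A bundled generator composes genotypes from regional
founder-haplotype pools by a mosaic switching process (block-wise LD),
draws disease status from an additive logistic model over planted causal
variants (logit *P* = logit π₀ + Σ ln OR·dosage), ascertains cases and
controls by rejection sampling, and injects every QC-artifact class the
cascade filters — so the whole pipeline is testable end to end without any
external data.

## Worked example

```python
import seqfinemap as sf
from seqfinemap.simulate import two_signal_region_config

sim = sf.simulate_cohort(two_signal_region_config(seed=3))
res = sf.FineMapModel(sim.geno, sim.sites).fit()
print(res.summary())
```

```
Case-control fine-mapping results
================================================================
Samples: 2750 (2000 cases / 750 controls)    Sites tested: 12
Informative threshold: P < 0.001    Conditional threshold: P < 0.1
Informative variants: 2
----------------------------------------------------------------
region SIG: 12 sites, 2 informative, 2 haplotypes
  haplotype 1: lead chr9:21800300:A:G  OR=1.69  P=6.83e-11  members=1
  haplotype 2: lead chr9:21800800:A:G  OR=1.52  P=8.58e-10  members=1
================================================================
```

The fixture plants two independent causal variants (population allelic ORs
1.6 and 1.4 at allele frequencies 0.15 and 0.25). Both are recovered: two
informative variants, each the lead of its own haplotype, with
case–control ORs (1.69, 1.52) near the planted values — case–control
ascertainment slightly inflates the allelic OR relative to the per-allele
population OR. `res.association_frame` and `res.haplotype_frame` expose the
same results as DataFrames.

The same analysis runs from the shell:

```bash
seqfinemap simulate --config sim.yaml --out fixture/   # sim.yaml: preset + sizes + seed
seqfinemap run --config run.yaml --out results/        # run.yaml: input paths + thresholds
```

`run` writes `association.tsv`, `haplotypes.tsv`, `qc_report.tsv` and a
`manifest.json` with input checksums and per-stage counts; identical
configs and seeds give byte-identical outputs.

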