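# Methods

## Statistical model and procedure

### Exact tests on genotype counts

The Hardy–Weinberg filter uses the exact conditional test: given the number
of genotyped individuals *n* and the minor-allele count *m*, the
heterozygote count *h* (same parity as *m*) has conditional mass

P(h | n, m) ∝ n! · 2ʰ / ( n_hom-min! · n_hom-maj! · h! ),

with n_hom-min = (m−h)/2 and n_hom-maj = n − h − n_hom-min. The two-sided
P sums the masses of all configurations no more probable than the observed
one (ties included, relative tie tolerance 10⁻¹²); the excess-heterozygosity
score is the phred-scaled one-sided tail −10·log₁₀ P(h ≥ h_obs). Both are
computed by direct enumeration with log-gamma weights, numerically exact to
well below 10⁻⁹ against big-integer rational enumeration for all n ≤ 50
(property-tested) and stable at cohort scale (n ≈ 3000 means ≤ ~1500
enumerated terms).

The allelic association test is the two-sided Fisher exact test
("sum of equally-or-less-probable tables") on the alt/ref × case/control
allele-count table, delegated to scipy; the test suite verifies agreement
with exact integer hypergeometric enumeration to < 10⁻¹² over every table
with both row margins ≤ 30. The odds ratio is the unconditional
cross-product ratio with 0/∞ sentinels for zero cells and no continuity
correction; NaN marks the undefined 0/0 case.

### Logistic regression

The conditional analysis uses an in-package IRLS fitter (intercept +
additive dosage terms): Newton steps with step-halving, convergence when
the maximum absolute score < 10⁻⁸ or the relative log-likelihood change
< 10⁻¹⁰, at most 100 iterations. Rank-deficient designs (detected by SVD
rank), separation (unbounded slopes, |β| ≥ 30 on the dosage scale) and
degenerate outcomes are flagged `converged=False`; the stepwise procedure
maps such fits to conditional P = 1, i.e. the variant is treated as fully
explained by the conditioning set. Wald P-values are (β/SE)² against
χ²₁. Estimates and standard errors are cross-checked against an independent
maximum-likelihood implementation in the tests.

### Stepwise decomposition

Within each region holding ≥ 1 informative variant: the variant with the
smallest marginal Fisher P is lead 1 (ties break to higher minor-allele
frequency, then lexicographic site id). Each round re-tests *all* non-lead
variants against the full current lead set (complete cases per fit, rows
dropped only for missingness in included columns); if any conditional
P < 0.1 survives, the smallest such variant becomes the next lead. On
termination every non-lead variant is assigned to the lead with maximal
cohort genotypic r² (ties to the earlier-discovered lead), making the
output a partition of the informative set. r² is the squared Pearson
correlation of dosage vectors over pairwise-complete samples — phase-free,
computed on the analysed cohort itself, not on an external reference panel.
With the continuation threshold set to 0 the procedure returns exactly one
haplotype per region.

Because the procedure continues while *any* conditional P < 0.1, each
non-collinear variant in high LD with a lead contributes roughly a 10%
chance per round of spawning a spurious extra lead under the null; users
analysing regions with many near-duplicate variants should expect
occasional singleton haplotypes led by tagging variants, exactly as the
threshold implies.

## QC cascade

Filters run in a fixed order (HWE → mean GQ → missingness → batch
intersection → LCR → differential missingness → excess het → external flag
→ AF z-score); a site removed at step *k* is never re-evaluated, so every
removed site carries exactly one label and the per-filter counts are
attributable and order-dependent by construction. Defaults and boundary
conventions, as literally specified: HWE strict P < 0.001 in either
control group (cases never enter); mean GQ strict < 30 in any
batch × phenotype group (absent GQ disables the filter with a warning);
missing fraction strict > 0.05; differential missingness strict Fisher
P < 0.05 (cases vs controls pooled over batches); excess het one-sided
P ≤ 3.4×10⁻⁶, i.e. phred ≥ 54.69 — a published phred cut of 54.96 is
mutually inconsistent with that P-value, and the P-value, being the
statistically meaningful quantity, is the parameter here; AF z-score
inclusive |z| ≥ 9.

The z-score filter standardizes Xᵢ = (control AF − reference AF) by the
mean and population SD of X over all eligible sites in the dataset
(computed globally, not per region; control AF from post-exclusion controls
with missing genotypes out of the denominator; sites without a reference AF
are exempt). A consequence worth knowing: because the outliers inflate the
very SD that standardizes them, k outliers among n eligible sites can reach
at most |z| ≈ √((n−k)/k); the filter can only ever catch a rare
contamination (k ≲ n/82 at the |z| ≥ 9 default).

Batch intersection: in a single jointly-called VCF no record is "absent
from a batch", so the consolidation step removes sites failing any
per-group filter and additionally flags sites with zero called genotypes in
an entire batch — the single-VCF analogue of batch-private variants.

## Synthetic-data generator

What it emulates: a two-batch case–control cohort (defaults 1959 cases /
737 controls, scalable) over multi-region target panels; block LD from a
founder-mosaic process (each haplotype walks over K founders, switching
with per-site probability 0.05–0.1 by config; adjacent-site r² decays
monotonically in the switch rate — property-tested); planted causal
variants under an additive logistic disease model with baseline prevalence
0.02 (a realistic lifetime-risk scale for the melanoma-like setting that
motivates the defaults); ascertainment by rejection sampling, which
preserves odds ratios (not risks) — the realized case–control allelic OR
slightly exceeds the planted per-allele population OR when prevalence is
non-negligible. With no causal plan the sampler short-circuits to a plain
population draw with quota labels (exact, and much faster for calibration
runs). Default site-frequency spectrum: pool minor AFs ~ Uniform(0.05,
0.5) — a common-variant spectrum appropriate to fine-mapping established
GWAS loci, not a rare-variant discovery spectrum.

Artifact classes are planted on disjoint site sets so QC counts are
attributable: control het-deficit resampling (inbreeding-like coefficient,
1 = no hets) for the HWE filter; case het-excess resampling for the
excess-het filter (cases, so the controls-only HWE filter stays blind to
it); truncated-normal GQ degradation; uniform and phenotype-differential
missingness; reference-AF shifts; single-position LCR intervals; external
fail flags. All randomness flows from one integer seed through spawned
generator streams; identical configs give byte-identical fixtures.

What it does not emulate: realistic demography or recombination maps,
indels/multi-allelic sites, genotyping error correlated with genotype,
sequencing reads, or population stratification (ancestry exclusion is an
input list, mirroring an upstream PCA step). Passing tests therefore
demonstrate the *statistical* behaviour of the filters and tests under the
stated generative model, not robustness to every real-data pathology.

## Fixture design choices

*Saturation fixture for the cascade* (150 sites, 1000/1000): differential
missingness uses case rate 0.02 vs control 0 — large enough that Fisher
P < 0.05 is near-certain, small enough that no per-group missing fraction
approaches the 0.05 missingness cut; the AF-shift class has exactly one
site (see the √((n−k)/k) cap above); the uniform-missingness class rate is
0.3. Residual risk: the HWE filter's own type-I rate (~10⁻⁴ per control
group at the exact test's conservativeness) can occasionally claim a site
planted for a later filter; at the fixed test seed the recovery is exact.

*Two-signal fixture* (12 sites, 2000/750, ORs 1.6/1.4 at AFs 0.15/0.25):
built on 400 equifrequent founders so that every carrier-set overlap equals
its exact independence product (e.g. 60·100/400 = 15 shared carriers
between the causal sets), making founder-level covariances between nulls
and causals exactly zero and between the two causals zero (cohort r²
~ 1/n). This matters: any residual founder-level LD between "null" sites
and a causal inflates the null informative rate and, through the
continue-while-any-P<0.1 rule, the spurious-lead rate.

## Problem sizes

The test suite and acceptance script use desk-scale sizes chosen to keep
Monte-Carlo error well inside the asserted margins: 20 seeds × 2000 sites
(40 000 null tests) for Fisher calibration, 1000 replicates for Wald
uniformity (KS sampling noise ≈ 0.03), 200 replicates for two-signal
recovery (binomial SE ≈ 2% at a ~96% true rate vs the 90% bound), and a
320-site, 2696-sample study-scale default run. The acceptance script scales
the same computations to 5 seeds / 50 replicates.

## Known limitations

- Exact-collinearity handling (conditional P := 1) means a variant
  *identical* to a lead is silently absorbed; a variant at r² = 0.99 is
  not, and contributes a uniform conditional P. This cliff is inherent to
  the published procedure, not smoothed here.
- The Wald test misbehaves near separation; such fits are flagged and
  absorbed rather than switched to likelihood-ratio or penalized fits.
- Sex chromosomes are not treated specially (no haploid HWE).
- The pipeline is single-threaded; study-scale runs complete in seconds,
  so no parallelism is warranted.
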