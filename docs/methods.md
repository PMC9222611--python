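# Methods

## The partition model

The unit of analysis is a single (usually circular) organelle reference
genome. Every position receives exactly one label in each of three
orthogonal layers, so each layer's label lengths sum to the genome length
and can serve as abundance denominators:

* **functional** — `NONSYN_SITE`, `SYN_SITE`, `RRNA`, `TRNA`,
  `PSEUDOGENE`, `INTRON`, `INTERGENIC`;
* **copy** — `REPEAT` where any supplied repeat interval covers the
  position, else `SINGLE_COPY`;
* **structural** — `LSC` / `SSC` / `IRA` / `IRB` for plastids, `NONE`
  otherwise.

Overlapping functional features are resolved by a configurable precedence,
default `CDS > rRNA > tRNA > pseudogene > intron > intergenic`; overlaps
are logged. Introns are derived, not read from the annotation: each gene's
span minus the union of its CDS/exon parts. Repeats are taken from the
annotation or a BED file — there is no de novo repeat detection. The two
structural single-copy arcs are the circular complement of the two IR
intervals; the longer arc is LSC, the shorter SSC (for the canonical
quadripartite plastid this matches the conventional naming). Internally
all intervals are 0-based half-open; GFF3 (1-based inclusive), VCF
(1-based) and BED (0-based half-open) conventions apply only at I/O
boundaries. A feature may wrap the circular origin (`start >= end`); the
partition is invariant under genome rotation.

## Synonymous and nonsynonymous sites

CDS positions are classified from codon degeneracy under a configurable
NCBI translation table (default: the standard code, which plant organelle
CDSs use). The degeneracy class of a codon position is the count of
amino-acid-preserving substitutions there (0 preserved → 0-fold,
1 → 2-fold, 2 → 3-fold, 3 → 4-fold; substitutions creating a stop never
preserve). Three site-classification modes:

* `fourfold` (default, hard): a position is a synonymous site iff it is
  4-fold degenerate. This is the only unambiguous hard rule producing an
  integer bipartition of CDS length; published per-species splits derived
  from other tools cannot be reproduced exactly because the precise rule
  behind them is not documented, and no attempt is made to match them.
* `any_syn` (hard): synonymous iff at least 2-fold degenerate. Lax
  superset of `fourfold` (tested monotonicity).
* `fractional`: NG86-style weight = (synonymous one-step changes)/3 per
  position; weights per codon sum to the codon's synonymous site count.

Terminal stop codons and codons containing ambiguous bases count as
nonsynonymous sites (weight 0) so the two classes always sum to the
annotated CDS length; internal stops raise in strict mode and are counted
nonsynonymous otherwise. Minus-strand and multi-exon genes are spliced in
transcription order (phase-adjusted) before classification and mapped back
to genomic coordinates; overlapping CDS with conflicting classes resolve
to nonsynonymous (conservative).

When tabulating variants, a CDS SNP is assigned by the *site class of its
position* by default (`cds_mode="site"`), keeping the numerator definition
identical to the denominator's. `cds_mode="effect"` instead classifies a
biallelic CDS SNP by whether the alternate codon translates identically;
both modes leave non-CDS rows untouched (tested).

## Variant filtering and statistics

Hard-filter criteria (defaults): fail on QUAL < 60, QD < 20.0, FS > 10.0
or MQ < 30.0 — strict inequalities, so threshold-equal values pass.
Missing annotation fields fail closed by default (`missing="pass"`
available). The same parameterized predicate serves both per-accession and
merged-file filtering stages. Genotypes are haploid: diploid-encoded
homozygous calls collapse to one allele; heterozygous (heteroplasmic-
style) calls collapse to the most frequent allele of the call, ties to the
lower index, logged.

Minor allele frequency is computed over non-missing sampled accessions
only (the reference genome is not a sample); it is the second-largest
allele frequency, so a site fixed for a non-reference allele has MAF 0.
Category MAF columns are arithmetic means over the category's variants
(median available). Ts/Tv counts cover biallelic SNPs only — multiallelic
SNPs count toward category SNP totals but are excluded from the Ts/Tv
summary — and the ratio is reported NA when there are no transversions.
Accession merging takes the union of sites, first-seen alt order, and
reference genotype for accessions without a record (configurable to
missing); a conflicting REF at a position is an error.

Indels are assigned to the category of their VCF anchor position; how
boundary-spanning indels should be attributed is genuinely open, and the
anchor rule is the simplest deterministic choice.

Neutrality ratios divide each functional category's SNP abundance by the
intergenic abundance; bands (default < 0.8 "below baseline", 0.8–1.25
"near baseline", > 1.25 "above baseline") are configurable and only
qualitative. Report files round abundances and MAFs to 4 decimal places
and ratios to 2, matching conventional table precision; full precision is
retained in memory. Rows with 0 sites report NA rates (0/0).

## Depth windows and copy number

Depth input is the 3-column `samtools depth` format; positions absent from
the file are zero-coverage (the producer omits them by default — a
documented contract, since silently dropping them would bias window
means). Windows tile the genome from position 1 in non-overlapping 1000-bp
steps; the final partial window is averaged over its own length (a
`drop_partial` flag drops it). Normalized copy number is the window mean
divided by the *median* of all window means — median, not mean, so the CNV
segments themselves do not shift the baseline. Windows overlapping any
repeat interval by ≥ 1 bp are flagged. No segmentation or significance
model is attempted: the output is the profile plus a simple fold-change
flag (norm_copy outside [0.5, 2.0], configurable). GC-bias correction is a
known confounder of depth-based copy number and is out of scope.

## The synthetic-data generator

The generator emulates the study conditions end to end. Defaults:

* **Genome:** 200 kb circular, with 12 CDS genes (900–2400 bp, 0–2
  introns of 600–1500 bp, valid ORFs on random strands), 3 rRNA and 15
  tRNA genes, 1 pseudogene, and 3 exact duplicated repeat pairs
  (2–6 kb per copy); an optional inverted-repeat pair switches on the
  plastid structural layer. Features are shuffled and separated by random
  intergenic gaps. 200 kb is a scaled-down plant mitogenome — large
  enough for per-category rate recovery, small enough that the whole
  suite runs in seconds.
* **Population:** 40 accessions, haploid genotypes. Per-category per-site
  SNP rates default to observed mitogenome magnitudes (nonsynonymous
  0.0008, synonymous 0.0009, rRNA 0.0012, tRNA 0.0011, intron 0.0006,
  intergenic 0.0009, pseudogene 0.0009 per site); indels only in rRNA
  (0.0002), intron (0.0003) and intergenic (0.0005). Transition bias 2:1.
  The minor allele count at each variant site is uniform on
  1..n_samples/2.
* **Filter fields:** QUAL/QD/FS/MQ are drawn from passing ranges; with
  probability `f_fail` (default 0.3) exactly one field is drawn failing.
  Rate semantics: `snp_rates[c]` is the expected rate of *filter-passing*
  variants; the raw per-site event rate is inflated by `1/(1 - f_fail)`,
  so the post-filter abundance estimates `snp_rates[c]` while a fraction
  `f_fail` of emitted records fails the hard filter. This keeps the
  parameter-recovery check (pipeline abundance within 3 binomial SEs of
  the simulated rate) and the failure-fraction check simultaneously
  meaningful.
* **Depth:** Poisson noise around 50× (zero-noise mode available), one
  implanted 2-fold CNV segment of 15 kb, three replicate samples.

Everything is deterministic under the configured seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage between sites (variants are independent
per site), gene-conversion homogenization of repeat copies and IRs
(copies mutate independently), sequencing-error structure and mapping
artifacts (filter fields are drawn, not derived from reads), GC-coverage
bias, and substoichiometric genome conformations (CNV is a clean step
function). Parameter recovery on these fixtures validates the estimators'
bookkeeping, not robustness to upstream noise.

## Numerical and design notes

* Partition painting is deterministic and order-independent: permuting
  input feature order never changes the labels (tested against a naive
  per-position membership oracle on ≤ 10-kb genomes).
* Abundance recovery is checked at 3 binomial standard errors,
  `3·sqrt(mu(1-mu)/sites)`, per category; CNV fold at 10% relative error
  over 30 replicates. The qualitative category-contrast check (synonymous
  near the intergenic baseline, nonsynonymous below it when simulated
  that way) uses elevated rates (0.009/0.003 over a 400-kb, 60-gene
  genome) because band classification of a handful of SNPs carries no
  statistical power; the design was sized analytically from the binomial
  SEs.
* Degenerate inputs: empty variant sets produce header-only tables;
  all-missing genotype sites are skipped with a warning; a zero median
  window depth yields NA copy numbers; a zero intergenic abundance yields
  NA neutrality ratios.
* Known limitations: no dN/dS or formal selection tests; no CNV
  segmentation model; repeat intervals must be supplied, not detected;
  single-reference coordinates only (no lift-over); VCF parsing assumes
  GATK-style QD/FS/MQ INFO fields where filtering is wanted.
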