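# Methods

## Scope and model

`phaseq` implements the computational core of a two-part study of
heterotrophic PHA production in *Ralstonia eutropha* H16: (i) quantifying
phase-resolved transcriptomes from single-end 36-bp RNA-seq alignments, and
(ii) quantifying Rubisco-mediated ¹³CO₂ incorporation into
poly(3-hydroxybutyrate) from GC-MS mass-isotopomer data. Alignment itself
(BWA), wet-lab steps, and biological interpretation of specific gene
clusters are out of scope; the pipeline starts at mapped reads and at
fragment isotopomer abundances.

## Quantification (quant)

**Filtering.** The published rule discards "alignments with mismatch or
mapped to the five rRNA regions". We apply it per alignment (locus): any
locus with NM > 0 is removed, any locus overlapping an rRNA interval is
removed, and a read whose loci are all removed is dropped. A read is
tallied as an rRNA read when at least one locus hit an rRNA interval and no
genic locus survived. The stricter alternative — one rRNA locus discards the
whole read — is available as `drop_whole_read_on_rrna=True`; the original
description does not distinguish the two, and the per-locus reading is the
closest literal one. A missing NM tag is treated as zero mismatches with a
warning rather than silently dropping data.

**Overlap rule.** A 36-bp locus "maps to" a CDS if it overlaps it by at
least 1 bp; when a locus overlaps m CDS features the weight splits 1/m.
With reads this short, any-overlap is the least-assumption rule.

**Fractional counting.** A read with k surviving loci contributes 1/k at
each locus (the reciprocal-of-mapped-loci rule for multi-hit reads); loci
overlapping no CDS contribute nothing. Weights are accumulated in double
precision; conservation holds to well below 1e-9 at the library sizes used.

**Library size and RPKM.** The library size is the summed counted CDS
weight per sample — the convention in which "reads on CDSs other than rRNA
regions" and "total reads" are the same quantity — so
RPKM = counts / (length/10³) / (library/10⁶) and
Σ_g RPKM·length_kb = 10⁶ exactly for all-genic samples. The denominator is
per *million* counted reads: the alternative per-megabase reading is
irreconcilable with the magnitudes the study reports (an RPKM > 20,000
"highly expressed" band would be unreachable), so per-million is adopted.

**Coordinates.** 1-based inclusive throughout (SAM/GFF3). Exclusion
intervals listed high-to-low are normalised to (min, max) on input.

## Significance gating and reporting (diffexpr)

Each gene is tested by a one-way fixed-effects ANOVA of its RPKM values
across the sampled phases, with the two technical replicates per phase as
observations (k groups, N = 2k, F with (k−1, N−k) df). The published
analysis is ambiguous between a single four-group test and pairwise tests;
the one-way form is adopted. Gating is on raw P < 0.05 by default — no
multiple-testing correction, matching the original gate — with an optional
Benjamini–Hochberg flag. Genes with zero variance everywhere are assigned
p = 1 (flat genes are displayable as non-significant, not undefined); zero
within-group variance with distinct group means yields p = 0. The
implementation vectorises the sums of squares over genes; `scipy.stats.
f_oneway` serves as the per-gene cross-check oracle in the tests.

Expression bands use strict thresholds: mean RPKM < 250 silent-or-weak,
> 20,000 high, else moderate (a gene exactly at a threshold is moderate).
Fold-change tables divide replicate means, by default with no pseudocount
and skipping zero-denominator genes rather than emitting infinities; log₂
export uses a pseudocount of 1 RPKM. Sample clustering is average linkage
on 1 − Pearson correlation over log₂(RPKM+1) — the metric behind the
MeV-style heatmap, which the original work names only by tool. Significance
filtering is applied at export; it does not affect the computed values.

## Isotope analysis (isotope)

The ¹³C atom fraction of a fragment MID is Σᵢ i·Mᵢ / n, which recovers the
per-carbon labelling probability exactly for a binomial MID. The P(3HB)
abundance is the unweighted mean over the three 3HB methyl ester fragments
(m/z 45: 2 C; m/z 87: 4 C; m/z 103: 4 C as written — the methyl carbon of
m/z 103 derives from derivatisation methanol but is counted as printed,
because that reading closes the published results table; a 3-C reading does
not). Natural-abundance and derivatisation background are handled by
subtracting the matched unlabelled-bicarbonate control culture, not by an
isotope-correction matrix.

The conversion of the abundance difference to molar incorporation is not
stated in the source and was fixed by closure: increase = Δ(atom fraction)
× n̄_C / M × 1000 mmol/g, with n̄_C = (2+4+4)/3 = 10/3 and M = 86.09 g/mol
(C₄H₆O₂ repeat unit). This is the unique simple candidate that reproduces
all four published strain rows at two-decimal precision (e.g. a 4-carbon
monomer basis gives 0.51 instead of 0.42 for the wild type); the closure is
asserted in the test suite. Fold ratios between strains compare the
two-decimal reported increases, as quoted fold changes do. MIDs are
renormalised to sum 1 on construction; channels beyond M+n are dropped with
a warning.

## Synthetic data (synth)

The generator emulates the study conditions: three replicons, five rrn
regions (one written with reversed coordinates to exercise normalisation),
36-bp single-end reads, two technical replicates of each phase (F16, F26,
F36, O26), and an 80% rRNA read fraction — the middle of the 72–89% range
observed in the real libraries. Defaults of 60 genes (300–1500 bp) and
20,000 reads per sample keep whole-pipeline runs to seconds while leaving
per-gene read counts deep enough for ratio recovery; tests that need other
regimes set them explicitly. Reads fall into disjoint classes (rRNA,
mismatched with NM=1, clean), genic origins are sampled proportionally to
expression level × placeable positions with uniform placement within the
gene (no insert/coverage model is claimed by the source; uniform is
assumed), and multimapped reads repeat the QNAME at k uniformly chosen gene
loci as primary + secondary records without an NH tag — the dialect a
BWA-era consumer must handle. All outputs are byte-deterministic in the
seed; per-sample streams derive their seed from (seed, condition,
replicate).

What the generator does *not* model: base-level sequencing error (quality
strings are constant), strand specificity, coverage bias, operon structure,
overlapping CDS (off by default), and GC-MS fragmentation chemistry beyond
per-carbon binomial labelling with multiplicative lognormal channel noise.
Passing recovery tests therefore demonstrate correctness of the counting,
gating and conversion arithmetic under controlled conditions, not
robustness to real-library artefacts.

## Numerical choices and degenerate inputs

- Zero library size raises an error rather than returning NaNs; genes with
  zero counts get RPKM 0.
- ANOVA with any condition below two replicates raises a design error.
- Constant matrices cluster with all-zero distances and a warning; the
  resulting order is arbitrary but stable.
- An all-zero isotopomer spectrum is rejected; negative channel abundances
  are rejected.
- Reported abundances and increases are rounded to two decimals only at
  reporting; full precision is kept internally.

## Problem sizes in the checked examples

The test suite and acceptance script use 200–10,000 reads per sample,
8–30 genes, 5,000 simulated null genes for the type-I calibration of the
ANOVA gate, and 1,000 spectra for the enrichment-bias Monte Carlo — sizes
chosen so every property is measured with comfortable statistical margin
while the full suite runs in seconds.
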