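# Methods

`mozpopgen` implements the genomic analyses used to detect and
characterise cryptic taxa of the *Anopheles gambiae* species complex in
surveillance sequencing data, together with a synthetic-data generator
that provides ground truth for every stage. This note records the models,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Taxon assignment from ancestry-informative markers

Taxa in the complex are morphologically indistinguishable; assignment
uses two panels of ancestry-informative markers (AIMs) — sites whose
alleles differ diagnostically between taxa. For a sample and a panel, the
AIM fraction is

    f = (# target-taxon diagnostic alleles at called panel sites) / (2 × # called panel sites).

The decision is two-stage and the first stage is decisive: a sample with
arabiensis AIM fraction > `t_arab` (default 0.6) is called
*An. arabiensis*; otherwise the gambiae-vs-coluzzii panel is consulted,
with coluzzii fraction > `t_col_hi` (default 0.9) calling *An. coluzzii*
and < `t_col_lo` (default 0.12) calling *An. gambiae*. Samples between
thresholds stay unassigned — they may be other taxa of the complex or
hybrids, and no automatic call is attempted for them. An alternative
operating point used in some published analyses (arabiensis > 0.85,
coluzzii < 0.1) is supported through the same `TaxonThresholds` object;
neither is privileged. Samples with fewer than `min_sites` (default 10)
called panel sites are treated as missing rather than silently dropped.

Half-calls in the VCF are conservatively treated as fully missing, and
multiallelic panel sites are discounted. These conventions are ours; the
assignment recipe does not prescribe them.

## Introgression profiling

Adaptive introgression of the 2L centromere-proximal region (carrying
the pyrethroid target-site resistance alleles in *Vgsc*) from
*An. gambiae* into *An. coluzzii* is profiled through the donor-allele
dosage: per window and per sample, the mean fraction of donor-diagnostic
alleles over called panel sites. Over the region of interest the mean
dosage `d` is thresholded into zygosity states: `d ≥ 0.75` homozygous,
`0.25 ≤ d < 0.75` heterozygous, `d < 0.25` none. The 0.25/0.75 cut
points are the midpoints between the expected dosages 0, 0.5 and 1 of
the three true states; no published rule exists, and at desk scale the
observed dosages sit essentially on the expected values, so the calls
are insensitive to the exact cuts.

## Diversity and differentiation statistics

All statistics run on per-cohort allele counts `c_a` with per-site
called totals `n_s` (missing genotypes excluded at counting time).

* Nucleotide diversity: `θπ = Σ_sites Σ_{a<b} c_a c_b / C(n_s, 2) / L`.
* Watterson's theta: `θw = S / (a1 · L)` with `a1 = Σ_{i<n} 1/i` and `S`
  the number of sites with ≥ 2 observed alleles.
* Tajima's D uses the classical constants (a1, a2, b1, b2, c1, c2, e1,
  e2); the test suite checks them against an independent second
  transcription of the formulas.
* Hudson's FST per biallelic site:
  `N = (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)`,
  `D = p1(1−p2) + p2(1−p1)`, combined as the ratio of sums
  `ΣN / ΣD` (ratio of averages, never the average of per-site ratios).
  Sites with fewer than two called alleles in either cohort, or with
  zero denominator (both cohorts monomorphic for the same allele), are
  excluded from both sums — the latter contribute nothing analytically
  but can poison the ratio in floating point.

Two conventions exist for the per-base denominator `L` and the field's
reported magnitudes do not always say which was used: per accessible
base (from the BED mask) or per variant/segregating site. Both are
supported; the caller chooses. With missing data the Watterson/Tajima
sample size is not unique; the per-region **median called allele count**
is used so the classical constants remain valid — a single-`n`
convention chosen over per-site corrections for transparency.

Windowed variants of the statistics are provided; a genome-wide value
should be recomputed from pooled per-site components, not averaged over
windows.

## Population structure

Structure SNPs are PASS, biallelic, minor allele frequency above a floor
(default 0.2%) and zero missing calls, thinned to a target count by
**equal rank spacing** along the chromosome. Rank spacing (rather than
equal physical spacing) guarantees exactly the target count whenever
enough SNPs qualify and is the common practice in the source ecosystem.
Chromosome 3 is the conventional choice because it is free of the large
polymorphic inversions.

PCA runs on per-variant-centered alternate-allele dosages with Patterson
scaling (`/√(p(1−p))`) by default; constant variants are dropped and
logged. Component signs are fixed (largest-magnitude coordinate
positive) so output is deterministic and invariant to sample order. The
neighbour-joining tree uses cityblock (L1) distances between **raw**
dosage vectors — scaling off, matching the convention of operating on
allele counts — with Saitou–Nei agglomeration (via scikit-bio) and
negative branch lengths clamped to zero (clamp count logged).

Inversion karyotypes (2La, 2Rb) appear as up to three clusters along PC1
of a region-restricted PCA: 0/1/2 copies of the inverted arrangement,
heterozygotes midway by dosage additivity. The cluster count is chosen
by gaps in sorted PC1: a gap is split-worthy when it exceeds 30% of the
PC1 range (at most two splits). No published rule exists; this one is
deterministic, calls one cluster on continuous (structureless) PC1
spreads at the sample sizes involved, and cleanly separates the discrete
karyotype groups, which sit several cluster-widths apart.

## Resistance substitution frequencies

Coding effects are annotated per SNP against the reference codon
background: the codon containing the variant is read from the FASTA
(reverse-complemented for minus-strand genes), mutated at the variant
base, and translated with the standard genetic code; non-synonymous
changes get the community label `<refAA><codon><altAA>` with
`codon = CDS index // 3 + 1 + offset`. The per-gene numbering offset
lets community labels (L995F, I114T, G280S, the 296/345 pair) be
reproduced regardless of the transcript chosen for numbering. No
codon-haplotype (MNV) reconstruction is attempted — two variants in one
codon are each evaluated independently against the reference codon, a
known limitation shared with per-SNP frequency reporting generally.

Per-cohort substitution frequency is the ALT allele count over called
alleles; variants producing the same amino-acid change have their
frequencies summed. Substitutions are retained when their frequency
strictly exceeds 5% (configurable) in at least one cohort — a filter
against sequencing error and drift noise.

Genotypes are unphased, so the joint frequency of a linked pair
(e.g. *Vgsc* V402L + I1527T) is estimated as the cohort mean of
`min(dosage₁, dosage₂)/2`. The estimator is exact under complete
coupling, which is precisely the regime the pair lists describe; under
partial coupling it is an upper bound on the coupled-haplotype
frequency.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume —
it is the source of ground truth, not a model of mosquito biology:

* **Taxa** are separated by fixed differences at AIM sites (diagnostic
  allele at frequency 1 in the carrier taxon, 0 elsewhere), making pure
  samples perfectly assignable — the correctness bar for the classifier.
* **Background differentiation** between geographic cohorts follows the
  Balding–Nichols model: cohort frequencies drawn from
  `Beta(p(1−F)/F, (1−p)(1−F)/F)`, the minimal single-dial model whose
  `F` is recovered by Hudson's estimator in expectation. Ancestral
  frequencies are uniform on (0.01, 0.5) — a flat folded spectrum, not a
  neutral coalescent SFS, which is why synthetic Tajima's D is positive
  and the synthetic diversity magnitudes are not comparable to field
  values. Default `F` = 0.006, the differentiation scale typical of
  connected *An. coluzzii* populations.
* **Introgression** is planted as whole-region allele replacement on
  1 or 2 haplotypes per recipient sample (no recombination breakpoints
  within the block — the region is treated as a single introgressed
  unit). Default zygosity proportions (none/het/hom) are
  (0.16, 0.46, 0.38). By default states are drawn multinomially;
  `introgression_exact_counts` plants largest-remainder exact counts for
  experiments that need the planted proportions verbatim. Five percent
  of the gambiae-vs-coluzzii panel is placed inside the region (the rest
  explicitly outside), so the region is informative while an
  introgressed sample's genome-wide AIM fraction remains diagnostic —
  mirroring the field situation, where the introgressed block carries
  only a small share of the panel.
* **Resistance alleles** are planted as independent per-haplotype
  Bernoulli draws at their target frequencies inside small synthetic
  gene models carrying the community gene identifiers; CDS extents are
  sized so the community codon numbers fall inside the coding sequence.
  Only the V402L/I1527T pair shares one haplotype indicator (complete
  coupling). Reference codons at planted positions are written into the
  otherwise-random reference sequence; the rest of each CDS is random
  and need not be a valid ORF, since annotation only reads the affected
  codon. Gste2 is placed on the minus strand so strand handling is
  always exercised.
* **Missingness** is uniform random per call, default 0.

Default cohort design: a Kenyan cohort (Turkana) carrying all three taxa
with 100 coluzzii, plus a West African coluzzii reference cohort of 40 —
sample sizes at which binomial recovery bands are tight enough to be
informative. The scaled-down genome (five contigs, 1.45 Mb total, 20 000
variants, full-size AIM panels of 2612 + 700 sites) keeps every analysis
in seconds; all statistics are denominated per base or per site, so
scale affects precision, not correctness.

What passing on synthetic data does **not** show: robustness to
real-data features the generator omits — linkage disequilibrium beyond
the planted blocks, a realistic site-frequency spectrum, sequencing and
alignment artefacts, batch effects, within-taxon admixture gradients.

## Numerical conventions

Coordinates are 1-based inclusive internally; BED is converted at the
file boundary. Beta draws are clipped to `[1e-12, 1 − 1e-12]` to avoid
degenerate 0/1 frequencies at tiny `F·p`. All simulation randomness
flows from one seeded `numpy` generator, making outputs bit-reproducible
under a fixed seed; the analysis pipeline itself contains no randomness,
so reports are byte-identical across reruns. NJ ties resolve by input
order; karyotype cluster labels are ordered by mean PC1; equal-rank SNP
selection uses `floor(i·n_qualifying / n_target)`.

## Known limitations

* The unassigned class conflates hybrids, other complex taxa and
  low-coverage samples; resolving them needs the PCA/NJT context, not
  the AIM thresholds alone.
* Copy-number variation at *Ace1*/*Gste2* and metabolic-resistance
  expression are out of scope; frequencies here are SNP allele
  frequencies only.
* The min-dosage joint estimator cannot distinguish coupling from
  repulsion in doubly heterozygous samples; with phased data it should
  be replaced by a haplotype count.
* Datasets are held dense in memory; the design targets desk-scale
  surveillance batches (hundreds of samples, ≤ a few hundred thousand
  variants), not biobank scale.
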