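# Methods

This note documents the models behind `ribocnv`, the parameter defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions used throughout.

## Read-mapping copy-number estimator

**Model.** nrDNA copy number per 2C is estimated from the fraction of
whole-genome reads attributable to the rDNA repeat unit.  If a genome of
2C size *G* bp contains CN copies of a unit of length *U* bp, and reads
sample the genome uniformly, the expected mapped fraction is
*q* = CN·*U*/*G*.  Inverting: CN = (*m*/*n*)·*G*/*U*.  The computation is
staged exactly as it is reported — genome proportion (%), genome space
(Mb and Kb), copy number — so each intermediate matches the published
survey table's columns.  A complete transcription unit
(18S–ITS1–5.8S–ITS2–26S) is the reference rather than the ITS alone,
which avoids the coverage imbalance between genes and spacers.

**Assumptions.** Uniform read sampling (no GC or mappability bias);
single-copy-equivalent background (reads from non-rDNA repeats do not hit
the reference); reference divergence from the genome's own units low
enough that true rDNA reads pass the identity floor.  Foreign-ribotype
units share the flanking genes, so their gene-derived reads map to the
native reference; with foreign copies at the observed 0.1–2% of native,
this inflates CN well below other error sources.

**Matcher.** Bowtie2-style local alignment is replaced by an in-repo
k-mer-seeded ungapped matcher with an explicit contract: a read maps iff
it shares an exact k-mer with the reference (either strand) whose implied
ungapped overlap is ≥ `min_match_length` bases at ≥ `min_identity`.
Seeds are evaluated at every read offset, so the decision is identical to
a brute-force scan over all exact k-mer co-occurrences (tested against
one).  Defaults: k = 20 (spurious exact hits against a ≤ 6 kb reference
are ~10⁻⁷ per 100-bp read), identity 0.90 (tolerates ~1% sequencing
error plus moderate reference divergence), match length 50 (every read
wholly inside a tandem array retains a ≥ ⌈L/2⌉ contiguous piece within a
single unit, so array-interior reads are never lost at L = 100).  Each
read counts once; multi-mapping within the tandem array is irrelevant
because the reference is a single unit.

**Conventions.** 1 pg dsDNA = 978 Mb.  Coverage targets are defined
against 1C = *G*/2, matching the convention that ~35 M × 150 bp reads are
~1× of a ~5.2 Gb 1C genome.  Rounding at reporting only: proportion
2 d.p., genome space 3 d.p. (Mb) and integer Kb, copy number to the
nearest 10 (halves away from zero); unrounded values propagate
internally.  Subsampling clamps to the available reads with a warning.

**Diagnostics.** Per-component mean depth over the unit, with a bias flag
when any component deviates from the unit-wide mean by more than 1.5×
(default) in either direction — the pattern expected when dispersed
ITS-only fragments inflate spacer coverage, or when 26S coverage sags.
The flag is suppressed when nothing maps.

## qPCR absolute quantification

**Standards.** A linearised plasmid with insert length *L* bp carries
copies/ng = 6.022×10²³/(*L*·10⁹·660), i.e. ≈ 6.022×10¹⁴/(660·*L*): one
nanogram divided by the fragment mass at 660 g/mol/bp.  (A widely
circulated rendering of this formula writes the exponent as 10⁻⁹, which
is off by 10¹⁸ and yields physically impossible ~10²⁷ copies/ng; the
package implements the dimensionally correct form.)  Default insert
lengths per assay: native 644, *Panicum*-like 538, *Paspalum*-like 537,
*Setaria*-like 539, *Euclasta*-like 536 bp.  Serial 10-fold dilution of a
1 ng/µl stock spans the 10⁶ → 1 copy working range (a helper reports the
dilution indices covering it).

**Calibration.** Cq = *a*·log₁₀(copies) + *b*, fitted by OLS over all
replicates of all dilution points (≥ 3 distinct levels required).
Efficiency E = 10^(−1/*a*) − 1 — the standard qPCR relation; perfect
doubling gives *a* = −1/log₁₀2 = −3.3219.  R² is reported as the fit
diagnostic.

**Quantification.** Replicate Cq values invert to copies
10^((Cq−*b*)/*a*) and are averaged on the copies scale (absolute-
quantification semantics; the difference from Cq-scale averaging is
second-order at replicate noise ≤ 0.2 Cq).  Copies per reaction ÷
template (ng) → copies/ng; × 2C size (pg) × 10⁻³ → copies per 2C.
Non-finite replicates are dropped with a warning.  Detection limit: a
mean below 1 copy per reaction is reported "n.d." — a missing value,
never a zero.

**Known bias.** When a universal (total-nrDNA) assay proxies the native
ribotype — necessary when no native-specific assay can be designed — the
native estimate is inflated by at most Σforeign/total;
`native_overestimation_bound` computes this bound (≈ 7.8% in the worst
observed cohort row, < 1% typically).

## Assay specificity screening

Primer annealing is modelled by mismatch counting only: a site qualifies
with ≤ `max_mismatch` (default 2) mismatches and a perfect match in the
3′-terminal `three_prime_window` (default 3) bases; amplification
requires a forward site and a downstream reverse site with product length
in `product_range` (default 50–1500 bp).  The check is strand-symmetric.
No Tm/ΔG model is attempted: the empirical criterion being emulated is
cross-amplification screening, for which counting works at desk scale.
Window selection ranks candidate primer placements by the minimum
mismatch count between target and every non-target (ties broken
leftmost); `design_assay` places both primers on windows whose score
exceeds the mismatch budget, making in-silico specificity structural.

## CNV statistics

Lineage summaries support two levels: taxon means (replicate rows
averaged per taxon first) and individuals.  Published per-lineage means
and s.d. that were computed from individual-level accession data are only
reproducible at that level; the taxon-mean level exactly reproduces the
summary cells that derive from the per-taxon table (I-Eurasian mean,
I-American and H fold ratios).  Foreign-ribotype fractions average
100·foreign/native over taxa with a detection (the denominator convention
that reproduces the published 0.1–1.9% range; a native-plus-foreign
denominator is available).  Missing ("n.d.") values are excluded, never
zero-filled.  Reporting follows the survey tables: means to integers,
fold ratios and percentages to one decimal, with unrounded values carried
alongside.

OLS (with adjusted R² and slope p-value), one-way ANOVA and Type-II
two-way ANOVA use statsmodels/scipy.  Tukey-type pairwise comparisons use
the Tukey–Kramer statistic referred to a Monte-Carlo sample of the
studentized range null (k standard normals over a pooled χ²-based scale),
seeded and with ≥ 10⁴ draws; at 2×10⁵ draws the simulated 5% critical
value matches published tables to within 2%.  This keeps the package free
of special-function tables while remaining family-wise exact in the
Monte-Carlo limit.

## Synthetic-data generator

The generator produces the structure the estimators assume, with exact
ground truth:

* **Genomes.** Diploid: two haplotype contigs summing to the stated 2C
  size exactly.  Native units form one contiguous tandem array per
  haplotype (copy number split across haplotypes); foreign units are
  dispersed insertions of 1–2 units per site outside the native array,
  mirroring their inferred residence in donor-derived chromosomal
  segments apart from the NORs.  Background sequence is i.i.d. with
  configurable GC (default 0.44); realized unit coordinates are recorded
  0-based half-open.
* **Ribotype panel.** A native ITS plus four foreign ITS variants with a
  conserved 5.8S, built by seeded two-round mutation so expected pairwise
  divergence is ~0.20 native↔foreign and ~0.10 foreign↔foreign — enough
  for discriminative primer windows to exist, as in the real ITS data.
* **Reads.** Single-end, uniform starts, random strand, i.i.d.
  substitution errors, constant Phred-35 placeholder qualities (the
  estimators do not use qualities).  Read count = coverage × 1C/L.
* **qPCR plates.** Cq = intercept − log₁₀(copies)/log₁₀(1+E) + N(0, σ);
  default 10⁶ → 1 series with 3 replicates per standard and 2 per sample.

Not emulated: indels and chimeric reads, paired ends, PCR duplicates, GC
bias, repeat families other than rDNA, pseudogenisation substitution
patterns, amplification-curve shapes and melting behaviour.  Passing
recovery tests therefore demonstrates correctness of the estimators under
their own assumptions, not robustness to those real-data artefacts.

## Problem sizes and study conditions

Simulation-based validation uses a scaled repeat unit of 1.0 kb
(18S 300 / ITS1 130 / 5.8S 100 / ITS2 130 / 26S 340 bp) inside 20 Mb 2C
genomes, so copy numbers spanning 500–5000 occupy a realistic 2.5–25% of
the genome while a 20-replicate experiment (100 000 reads each at 1×
coverage, 1% error) completes in about a minute; full-scale defaults
(U = 5800 bp) are used everywhere arithmetic, not simulation, is being
exercised.  The qPCR round trips use the 10⁶ → 1 series with Cq noise 0
(closed-form checks) and 0.2 (stochastic recovery, 20 seeds).  Every
stochastic component is a pure function of its seed.

## Known limitations

* The matcher is ungapped; indel-rich data would undercount mapped reads.
* Reference/genome divergence above ~(1 − min_identity) suppresses
  mapping of true rDNA reads; per-species references are expected.
* qPCR modelling starts at Cq values; amplification-curve processing,
  inhibitor effects and chemistry differences (TaqMan vs SYBR) are out of
  scope — both chemistries reduce to the same Cq model here.
* Specificity screening ignores annealing thermodynamics and primer
  dimers; it bounds, rather than predicts, wet-lab cross-amplification.
* FISH locus counts and clade labels are metadata; no phylogenetic
  comparative correction is applied to the cohort statistics.
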