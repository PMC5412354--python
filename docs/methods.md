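# Methods

`paneldepth` is a desk-scale re-implementation of the analysis behind a
clinical gene-panel sequencing workup: how much sequencing depth a targeted
panel needs before SNPs and small indels are reliably called, and how an
annotated variant table is reduced to a single Mendelian diagnosis.  Real
patient reads are not publicly available, so the package carries a
synthetic-panel generator whose outputs have the statistical structure the
analysis assumes; everything downstream of read generation is the analysis
itself.

## The synthetic panel world

**Panel geometry.** One chromosome per gene (`panel_chr1` …), each with
`exons_per_gene` exons of `exon_len` bp separated by `exon_gap` bp introns.
Capture targets are the exons padded by `pad_bp` (default 100 bp) on each
side and merged where pads touch.  Coordinates are BED-style 0-based
half-open for intervals and VCF-style 1-based anchored for variants.  The
default panel — 27 genes × 5 × 200 bp exons, 100 bp pads, 300 bp gaps —
gives a 54 kb padded target, the size class of a real neuropathy panel.

**Truth variants.** Exact requested counts of SNPs and indels (defaults 162
and 42, the size of a real patient's on-panel call set) are planted
uniformly inside the padded targets, left-normalized, and spaced at least
150 bp apart.  The spacing — farther than a read length — means no read
ever straddles two variants, which keeps the genotype-aware read overlay
exact and each read's indel evidence unambiguous.  It costs nothing at
panel scale (204 variants in 54 kb) and is stated here because it is the
one way the synthetic truth set is *simpler* than real data, where nearby
variants and multi-nucleotide haplotypes occur.

**Pedigree genotypes.** A pedigree carries its inheritance model and a
penetrance.  The causal variant's genotypes are constructed to satisfy the
model (AR: affected members homozygous-alt with obligate-carrier parents;
AD: every affected member carries the allele, unaffected carriers permitted
only when penetrance < 1, otherwise a consistency error), then the
remaining members are filled by rejection-sampled gene drop.  All other
variants gene-drop from Hardy–Weinberg founders at a configurable allele
frequency (default 0.2).  Every assignment is verified against an
exhaustive gamete-transmission check.

**Reads.** Paired-end 100 bp reads with a Gaussian fragment length
(300 ± 30 bp).  Capture non-uniformity is a per-interval gamma depth
multiplier with coefficient of variation `capture_cv` (default 0.7,
shape = 1/cv²), normalized to a panel-wide mean of 1.  That one dial
reproduces the signature of real capture data — a high mean with a long
left tail (~90% of target at ≥50× despite a >200× mean) — without modelling
hybridization chemistry.  The number of pairs per interval is Poisson with
rate `coverage × multiplier × length / E`, where `E` is the expected
on-target bases per pair computed against the chromosome's target mask by
quadrature over the fragment-length distribution.  This calibration matters:
fragment ends spill off 400 bp targets (and into neighbouring targets), and
without it realized on-target coverage misses the request by ~20%.  With it,
realized coverage lands within ~1% (the contract is 5%).

Each fragment draws one haplotype, so heterozygous alleles appear in half
the fragments in expectation.  Substitution errors are i.i.d. per base at
`error_rate` (default 0.005).  A read records a planted indel — and is
rebuilt from the alternate haplotype — only when it spans the site with at
least `INDEL_FLANK` = 10 bp on each side; shorter overlaps stay
reference-built, standing in for reads an aligner would soft-clip.  This
flank requirement is what makes indel recall systematically lower than SNP
recall at equal depth, as observed in real rarefaction curves.  An optional
`homopolymer_slip_rate` attaches spurious single-base deletion evidence at
homopolymer runs ≥ 6, the error mode behind poly-A tract artifacts.

**What the simulator does not model:** alignment and mapping error,
duplicate reads, GC-dependent coverage bias, base-quality variation
(a single global error rate stands in), multi-nucleotide and clustered
variants, structural variation.  Passing tests therefore demonstrate the
*analysis* is correct and calibrated on data satisfying its stated
assumptions — not that the caller would match a production pipeline on real
reads, where mapping noise moves the recall curves substantially to the
right (real C95 values are several-fold higher than the clean-simulation
ones).

## The genotype caller

Reads carry true placements, so pileup is exact counting: per-base A/C/G/T
counts from vectorized bincount, plus sparse indel-event counts.  At a
biallelic site with error rate *e*, a read supports alt with probability
e/3 (hom-ref), (1−e)/2 + e/6 (het) or 1−e (hom-alt); the posterior over the
three genotypes is the prior times the per-read product, and

    QUAL = −10·log10 P(hom_ref | reads),  capped at 1000.

The default prior (0.998, 0.001, 0.001) encodes the ~10⁻³ heterozygosity a
diploid caller conventionally assumes.  A variant is emitted when the
maximum-posterior genotype is non-reference, QUAL ≥ 50 (the clinical
pipeline's cutoff, applied to QUAL rather than genotype quality — the
source pipeline leaves this ambiguous), and the site lies in a padded
target.  Indels use the same three-genotype model with alt = reads carrying
the event and ref = spanning reads without it; multi-allelic pileups
resolve to the highest-count allele, ties lexicographic.  The test suite
checks the implementation against brute-force per-read likelihood products
for every pileup of depth ≤ 12 and against an analytic scan of the QUAL-50
emission boundary.

## Rarefaction and C95

The full-coverage call set is the pseudo-truth; recall at fraction 1.0 is
100% by construction, a bias the original analysis acknowledges and this
package keeps (no asymptotic extrapolation of total variant count is
attempted).  Reads are thinned pair-wise — each pair kept independently
with probability equal to the grid fraction, mates never split — over a
descending grid (default 1.00 → 0.05 in 0.05 steps, 10 replicates).
Replicate *r* uses seed `base_seed + r` at every fraction, coupling the
thinnings into nested subsets: replicate counts are exactly reproducible
and adjacent fractions share sampling noise.  Matching against the
pseudo-truth is on (chromosome, position, ref, alt); genotype is ignored,
because the quantity of interest is "variants recovered", not concordance.

Means and SDs (sample SD, n−1) print to 1 decimal, rounded half-up, the
convention of the source tables.  Effective coverage is
`fraction × mean target coverage` to 1 decimal; C95 bracket endpoints are
the integer-rounded effective coverages of the two adjacent grid points
around the 95% crossing of the mean-recall curve (highest crossing wins if
noise produces several, with a warning).  One known arithmetic discrepancy:
0.85 × 184.2 rounds to 157 where the source prints 156 for one indel
bracket — that value was likely derived from measured post-thinning
coverage; this package reports the arithmetic value.

`min_fraction_all_replicates` reports the smallest grid fraction at which a
given variant is called in *every* replicate, with its effective coverage
and mean site depth — the per-variant "minimal reliable depth" statistic.
Homozygous variants reach it at lower site coverage than heterozygous ones
(all reads support alt versus half), a property the tests assert by direct
simulation of the caller's emission probability.

## The prioritization cascade

Input is an annotated variant table; the annotation tools themselves
(functional annotators, the MutationTaster-style classifier, the
KGGSeq-style 14-algorithm Mendelian ensemble) are upstream of this package
and their outputs are consumed as columns, never re-implemented.  Filters,
in reporting order: overall population MAF (fail iff any database MAF ≥
0.05; absent data passes), maximum sub-population MAF (same cutoff),
genotype QC (GQ ≥ 20 and depth ≥ 4, inclusive), functional class
(non-synonymous and splice-site variants are diagnosis-eligible; synonymous
and UTR variants stay in the report, flagged), predictor consensus
("strong" = Mendelian-ensemble disease call, with P_disease ≥ 0.5 inclusive
at the boundary; "weak" = classifier-only), and inheritance mode (AR keeps
homozygous-alt; AD keeps carriers; compound-het search is deliberately
absent).  The three mandatory filters are an intersection, so their order
cannot change the surviving set — asserted by permutation testing.  A final
candidate needs strong consensus plus inheritance compatibility; ties rank
by consensus then P_disease.  Indels at the end of a homopolymer run ≥ 6
with a multi-allelic pileup are flagged suspected-artifact.  Known-mutation
lookup is an exact (gene, HGVS) match in a local table.

Segregation grading verifies gamete-level transmission first, then the
disease model; under AD, an unaffected carrier downgrades the verdict to
"consistent with incomplete penetrance" rather than inconsistent.

The synthetic annotation generator plants one causal variant (rare or
database-absent, model-compatible genotype, ensemble probability ~Beta(12,3))
among background variants drawn from the mixture a panel actually yields
(70% common polymorphisms that the frequency filters remove, ensemble
probabilities ~Beta(1,12) for the benign non-synonymous ones).  With 50
background variants the cascade recovers the causal variant as sole
candidate in ≈98–99% of simulated families; the residual failures are
causal variants whose sampled ensemble probability falls below 0.5 —
mirroring the real risk that a predictor under-calls a true pathogenic
variant.

## Benchmarking

Calls are scored against an independent truth set per variant class after
left-normalization, by exact site+allele matching (no distance windows —
the simplest defensible rule, stated so results are reproducible).
Genotype concordance is additionally required only in validation mode.
Recall and precision print to 2 decimals; precision is undefined (None) on
an empty call set.

## Numerical and reporting choices

* Ties round away from zero (`round_half_up`), matching printed-table
  conventions; implemented over decimal representations so float artifacts
  like 0.05 × 213.4 = 10.670000000000002 round to 10.7.
* QUAL is capped at 1000 to avoid infinities when the hom-ref posterior
  underflows.
* Zero-depth sites are no-calls, not errors; an empty truth class makes
  recall undefined and raises.
* Every stochastic operation takes an explicit seed; the orchestrator
  derives stage seeds as fixed offsets from the single config seed, so a
  rerun with the same config reproduces every table byte-for-byte.

## Problem sizes

The default experiment (27 genes, 54 kb padded target, 213.4× mean
coverage, 20 fractions × 10 replicates) runs the complete grid — 200 call
rounds — in well under a minute on one core, thanks to the bincount pileup.
Unit tests run a smaller 8-gene, ~11 kb panel at 150×; the determinism
check runs a 5-gene configuration end-to-end twice.  These sizes are the
package's own defaults for a quick, fully reproducible desk experiment;
all of them are plain config parameters.
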