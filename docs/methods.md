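# Methods

This note documents the models behind `pdxpurity`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical decisions a maintainer would want to know about.

## ssPAL quantitation

### Signal model

A capillary-electrophoresis trace for one primer pair is modelled on a
0.1 bp fragment-size grid as

```
y(s) = baseline
     + A·f  · N(s; L_mouse, σ)
     + A·(1−f) · N(s; L_human, σ)
     + ε(s),       ε ~ iid Normal(0, c·h_max),  y clipped at 0
```

where `f` is the murine DNA fraction, `L_mouse`/`L_human` the amplicon
lengths of the pair, `σ` the peak width, and `h_max` the taller peak's
height.  Peak *areas* are proportional to template amounts — that is the
assay's core assumption, and the generator enforces it exactly so that the
estimator's own biases are observable.

Defaults: `σ = 0.4 bp`, noise SD `c = 0.002` of the major peak height,
baseline 0, total area 1000 intensity·bp.  These were fixed once so that a
1% minor component is comfortably above noise (relative height ≈ 0.0101
against noise SD 0.002) while 0.5% sits at the detection threshold — the
regime in which the assay's published 1–99% working range is meaningful.
The generator does not model PCR stutter, dye pull-up, size-standard
mis-calibration, or baseline drift; passing tests therefore demonstrate
correctness of the estimator under proportional-area mixing with additive
noise, not robustness to those instrument artifacts.

### Peak calling and quantitation

* Baseline = median intensity, subtracted before all thresholding.
* Local maxima above `min_rel_height = 0.005` of the global maximum are
  candidate peaks.  Maxima closer than 2 bp are merged (tallest wins).
  The merge distance is a numerical necessity, not a tuning knob: near the
  top of a *small* peak the point-to-point signal differences are below
  the noise SD, so additive noise fragments one physical peak into several
  local maxima; integrating only the tallest fragment halves the minor
  peak's area and with it the low-end fraction estimates.  2 bp is far
  below the smallest inter-species gap (5 bp for pair 43), so distinct
  species peaks are never merged.
* Each peak is integrated by the trapezoid rule between its flanking
  minima, capped at centroid ± 3 bp (± 7.5 σ, > 99.99% of a Gaussian's
  area).  The centroid is the intensity-weighted mean size inside those
  bounds, which on the 0.1 bp grid recovers a noise-free peak position to
  better than ± 0.05 bp.
* Species assignment: a peak within 1.5 bp of a species' amplicon length
  is labelled with that species (largest area wins on ties).  1.5 bp
  leaves margin for noise-driven centroid error while staying under half
  of the 5 bp pair-43 gap, the point at which assignment would become
  ambiguous (the code rejects tolerances that large).
* `mouse_fraction = A_mouse / (A_mouse + A_human)`; a species with no
  detected peak contributes area 0; if neither species amplified the
  sample is reported as a failed reaction rather than a fraction.
* The two primer pairs are combined by a plain arithmetic mean.  Combined
  estimates below 1% or above 99% carry a censoring flag — the assay's
  sensitivity limits — and the mouse-origin call is a strict step:
  `suspect_mouse` iff combined fraction > 0.95, with 0.95 itself still
  called human.

Measured behaviour under the defaults (recomputed by the test suite and
`scripts/acceptance.py`): detection limit ≤ 1% mouse DNA at ≥ 95%
replicate detection, and |mean estimate − truth| < 0.001 across the whole
1–99% grid.

The built-in screening table (`MOUSE_ORIGIN_SCREEN`) stores per-pair
murine/human *percentages* as printed in the originating report; one row
sums to 100.1 due to rounding, so every row is renormalized by its sum
before conversion to fractions.  With pair-averaging all four lines exceed
the 95% cutoff — including the one line whose pair-5 value alone (94.5%)
does not, which is why classification uses the averaged fraction.

## Two-species genome model

The human contig is uniform random ACGT; the mouse homolog derives from it
by i.i.d. substitutions at a configurable per-base divergence (default
0.10) outside the ssPAL loci.  One direction of derivation (human =
ancestor) keeps locus placement deterministic.  Inside each locus the
sequence is copied unchanged except for a single mid-amplicon indel that
resizes the amplicon to its mouse length; primer sites are never touched,
so both species remain amplifiable and the loci are the only
species-identical (hence alignment-ambiguous) regions.  No indels exist
anywhere else, which is what licenses the ungapped aligner below.  A
substituted base always changes (uniform over the other three), so the
realized divergence is exactly the configured rate in expectation.

## Reads

Single-end, fixed length (default 100 bp), constant quality, uniform start
positions, uniform strand, i.i.d. substitution errors (default 0.001 per
base for benchmark samples; 0 where the test calls for error-free reads).
Per contig, `round(depth · L / read_len)` reads are drawn, giving
Poisson-like per-base depth away from contig edges.  Paired-end structure,
quality-dependent errors and GC bias are deliberately absent: none of them
interact with the contamination mechanism under study, which operates at
the whole-read level.

## Hybrid alignment

The reference is every human and mouse contig with a full exact k-mer
index over both strands (default `k = 15`).  A read nominates candidates
from seeds at its start, middle and end offsets, scores each candidate by
ungapped full-length comparison (score = matches − mismatches), and keeps
the best; equal best scores define `ambiguous`, a best placement with more
than 10% mismatches defines `unmapped`.  Ambiguous reads are dropped
entirely rather than assigned at random — an auditable reading of
multi-mapping loss that makes "coverage under hybrid ≤ coverage under
human-only" a base-wise invariant instead of a distributional one.  At 10%
divergence a 100 bp read straddling the two species differs by ≈ 10 bases,
so cross-species seeds frequently fire but cross-species placements never
win against an error-free true placement; misassignment of human reads to
mouse contigs is measured at < 10⁻³ in the tests.

## Virtual samples

* **virtual normal / tumor**: two independently seeded read simulations of
  the same human genome, each simulated at twice its target depth and then
  binomially downsampled to 30× / 60× (exercising the same thinning
  operation a BAM-level pipeline would apply).
* **mutation spike-in**: `n` distinct positions uniform on the human
  contigs, alternate allele uniform over the three non-reference bases,
  VAFs cycled over the configured levels (default {0.05, 0.1, 0.2, 0.5} —
  a repository choice spanning subclonal to clonal-heterozygous; n = 80
  gives 20 mutations per level).  Each read covering a site switches its
  base to the alternate independently with probability VAF; this matches
  the marginal VAF behaviour of molecule-level spike-in tools without
  their haplotype bookkeeping.
* **contamination**: each tumor read is independently replaced with
  probability λ by a mouse read drawn without replacement from a pool
  sized at 1.2× the tumor depth.  Total read count is preserved exactly,
  so the human-side depth after mouse exclusion is (1 − λ)·60 in
  expectation — replacement, not addition, is our reading of
  contamination, and it makes depth loss the sole mechanism by which λ
  acts.

## Somatic calling and evaluation

The caller is a binomial tumor-vs-normal test: a site is called iff tumor
depth ≥ 10, alternate count ≥ 3, the binomial upper tail
P(X ≥ alt | n = depth, p = e/3) < 10⁻³ with assumed error rate e = 0.01,
and the matched normal carries that allele at ≤ 3%.  The defaults were
chosen so that an uncontaminated 60× sample calls VAF ≥ 0.2 mutations
essentially perfectly, which pins the benchmark's ceiling at F1 ≈ 1 and
makes any degradation attributable to contamination.  `alpha` is a fixed
per-site threshold with no multiplicity correction: evaluation is against
a known truth set, so calibration is absorbed into precision/recall.  The
assumed error rate is deliberately conservative (10× the simulated rate);
with ~3 effective tests per site this keeps genome-wide false positives
near zero at desk scale.

Evaluation matches calls to truth by exact (contig, position, alternate
allele); a call at a truth position with the wrong alternate is a false
positive.  True positives and false negatives are binned by *true* VAF,
false positives by *observed* alternate fraction.  Empty-cell conventions:
precision = 1 when nothing was called and nothing was missed (else 0 when
nothing was called), recall = 1 when a bin holds no truth, F1 = 0 when
both are 0.

The sweep derives per-λ child seeds from one master seed via numpy
`SeedSequence.spawn`, and caches per-read alignments across λ (a read's
best placement does not depend on sample composition), so single-λ reruns
are reproducible and the grid costs one alignment pass.

## Problem sizes

The package's own benchmarks run at desk scale, chosen as the smallest
sizes at which the measured quantities are statistically stable: 20 kb
genomes / 80 mutations / 60× for the contamination sweep (≈ 2 s per grid),
50 kb for alignment truth-recovery rates, and 500 kb at 30× for the
hybrid-coverage figure (≥ 15× depth at > 99.8% of bases, against a ≥ 98%
expectation).  All quantities reported by `scripts/acceptance.py` are
recomputed at run time from the single command-line seed.

## Known limitations

* The trace model omits instrument artifacts (stutter, pull-up, sizing
  drift); the quantitation chain has not been validated against real
  fragment-analysis exports beyond format support.
* The aligner is exact-seeded and ungapped; it is adequate for the
  indel-free simulator but is not a general-purpose mapper, and its
  ambiguity behaviour (drop entirely) is one defensible reading of how
  production mappers handle multi-mapping reads, not the only one.
* Contamination is whole-read replacement at uniform rate; targeted
  capture effects (mouse fragments enriched by human baits) and
  region-dependent homology are not modelled, so exonic-vs-genome
  differences in calling performance are out of scope.
* The somatic caller handles SNVs only — no indels, no copy number.
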