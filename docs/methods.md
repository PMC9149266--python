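# Methods

This note documents the models, parameters, and design choices behind
`mir166kit`, and what its synthetic-data tests do and do not demonstrate
about real genomes.

## Homology scan

Candidate precursor loci are found by exact local alignment (Smith–Waterman
with affine gaps) of known pre-miR166 queries against both strands of every
scaffold. The alignment engine is Biopython's `PairwiseAligner` (an exact
Gotoh dynamic program in C); the test suite independently verifies its
optima against a hand-written exhaustive recursion on short sequences. The
scoring convention is match +2, mismatch −1, and a gap of length *k* costing
`gap_open + k·gap_extend` with gap_open −5 and gap_extend −1. These are
screening parameters, not inferences — a published BLAST screen rarely
reports its exact parameters, so they are exposed on the command line and in
the config.

Multiple hits per query/scaffold pair are found by iterated best-hit
extraction with hard masking of reported loci. Hits whose scaffold intervals
overlap reciprocally by ≥ 50% are one locus (best score wins), which
de-duplicates hits from near-identical queries. Defaults: `min_identity
0.85`, `min_coverage 0.8`, `flank 0`. The zero default flank is deliberate:
under the simplified folding model below, unpaired genomic context folds
into spurious side helices, so candidates are the aligned span alone. All
coordinates are 0-based half-open internally and 1-based inclusive in every
report.

## Folding model

Secondary structure is predicted by a Nussinov-style dynamic program that
minimizes the sum of base-pair energies — G:C −3.0, A:U −2.0, G:U −1.0
kcal/mol — over all pseudoknot-free structures with hairpin loops of at
least 3 unpaired bases. Ties are resolved deterministically (pair the
leftmost pairable base, smallest partner first). The model is chosen for
verifiability: the test suite enumerates *every* nested structure of short
random RNAs and confirms the DP optimum exactly.

Three consequences of this simplification matter downstream:

- **Absolute energies are not thermodynamic.** MFE and MFEI values are not
  comparable to nearest-neighbor folders; screening thresholds are therefore
  parameters (`max_mfe −15.0`, `min_mfei 0.85`), and `FoldResult` is a plain
  data contract, so a thermodynamic folder can be slotted in without
  interface changes.
- **No loop penalties ⇒ register trades.** Breaking one stem pair can make
  a shifted register (trading A:U columns for G:C) strictly optimal,
  widening a single substitution into a multi-column interior loop. The
  NM statistic used for screening is therefore computed at the sequence
  level (below) rather than from the fold.
- **The model's symmetry is sequence reversal**, not reverse
  complementation: a G:U wobble maps to C:A under complementation and
  cannot pair. The property tests assert reversal symmetry.

## Stem-loop topology and arms

After folding, lone pairs (helices of one un-stacked pair) are pruned — the
standard no-lone-pair convention — and each hairpin loop is weighted by the
number of pairs closing it alone. A candidate is a simple stem-loop when
exactly one loop is closed by a *substantial* stem (≥ 3 pairs); incidental
two-pair helices, which arise freely under the flat energy model, are
ignored, while genuinely branched structures are rejected. The 5′ arm, loop,
and 3′ arm are the closing stem's flanks; interior-loop and bulge columns
belong to the arms.

## NM (arm-duplex mismatches)

Two counters are provided. `count_duplex_mismatches` walks the folded
duplex between two mature spans and counts, for each unpaired run,
`max(unpaired 5′ side, unpaired 3′ side)` columns — a symmetric mismatch
counts once, a bulged base counts once; spans are clipped to the stem. This
is the declared structural reading of the statistic.

The screened candidate statistic (`HairpinCandidate.nm`) instead slides the
located mature ungapped along the whole region on the other side of the
loop and counts columns that are neither Watson–Crick nor G:U at the best
offset. This sequence-level count equals the substitution burden of the
duplex and is insensitive to the register-trade artifact of the flat energy
model; it is also the natural reading of "mismatches between the 5′ and 3′
arms" as a table statistic. Screening defaults: `max_nm 4` (boundary
inclusive), `min_mfei 0.85`, `max_mfe −15.0`, rejections carry the first
failed rule in the order stem-loop → nm → mfei → mfe.

Mature miRNAs are located by ungapped sliding comparison against 20–24-nt
references with at most `max_mismatch 3` substitutions; the arm is assigned
from the window midpoint relative to the loop, ties go to the first
reference in input order.

## Phylogenetics

Distances are p-distances (differing columns / gap-free comparable columns)
on a supplied alignment; the model is the simplest declared choice and is
easily hand-checked. UPGMA merges the closest pair at height *d*/2 with
size-weighted average distances; ties break on the lexicographically
smallest pair of cluster labels, making trees reproducible. Bootstrap
support of an internal node is the percentage of column-resampled replicate
trees containing the same leaf set. A convenience star-guided progressive
aligner (global pairwise to the longest sequence) is included for closely
related precursor sets; pre-aligned FASTA remains the canonical input.

## Promoter elements

Promoter windows are taken as given fixed-length sequences (1,600 bp in the
study design); TSS prediction is out of scope. Motifs are IUPAC strings,
each mapped to one response category; scanning reports every exact match on
both strands (overlaps included), and a category is present in a promoter
iff it has ≥ 1 hit. Prevalence percentages are rounded half-up to one
decimal so that 7/9 prints as 77.8. The default dictionary ships editable
consensus strings in the style of public plant cis-element collections; no
default consensus is load-bearing for any published-arithmetic check, which
uses the transcribed element-presence matrix directly.

## Target prediction

The expectation score is an additive penalty over miRNA positions: mismatch
1.0, G:U wobble 0.5, each bulged base 2.0, doubled inside the seed span
(positions 2–13 from the miRNA 5′ end). Windows are ungapped plus at most
one single-base bulge on either strand — the dominant plant-target geometry
— which keeps a brute-force window oracle feasible. Sites with expectation
≤ cutoff (default 5.0) are reported, overlapping windows collapsed to the
best per locus. Inhibition is called "translation" iff any non-WC state
falls on central positions 9–11, else "cleavage". Transcripts are scanned
on the sense strand only.

## Functional similarity

DICE similarity `2|A∩B|/(|A|+|B|)` over binary function profiles; Nei
distance `D = −ln S`. The transform is consistent with the internally
consistent published pairs (0.28 ↔ 1.27, 0.36 ↔ 1.02); some printed pairs
are not consistent with any single transform, so full-matrix reproduction
is not a validation surface. Zero-similarity pairs have infinite distance;
UPGMA substitutes a configurable cap (default 10.0) with a warning, and the
reported distance matrix keeps +inf.

## qPCR quantification

Technical replicates are averaged first; ΔCt = mean Ct(gene) − mean
Ct(reference) per (treatment, timepoint, biological replicate); ΔΔCt
subtracts the mean control-timepoint ΔCt; fold = 2^−ΔΔCt with amplification
efficiency fixed at 2 (exposed as a parameter; no efficiency correction is
modeled). Means and SDs are over biological replicates. Tukey's HSD runs on
log2 folds (variance-stabilizing under Ct-scale Gaussian noise) via the
studentized-range distribution, with a greedy compact-letter display from
the highest mean; a zero mean-square error degenerates to "significant iff
means differ".

Under the generator's noise model (independent Gaussian Ct noise of
`noise_sd` per technical replicate, plus a per-sample loading shift that
ΔCt removes exactly), the mean log2 fold estimator has standard error
`noise_sd · sqrt(4/(n_bio·n_tech))`. The Monte-Carlo calibration check uses
this analytic SEM: with an *empirical* between-replicate SEM and n_bio = 3,
a ±3·SEM band is a t-like interval with only ≈ 90% coverage, so the
empirical band cannot certify the ≥ 95% calibration the check is after;
the analytic SEM is the quantity the generator actually controls.

## Synthetic data: what it shows and what it does not

Backgrounds are i.i.d. uniform A/C/G/T — the simplest null that cannot
systematically mimic implants. Implanted precursors are constructed
hairpins: reverse-complement arm + minimal all-A loop + mature + random
stem extension, with engineered arm mismatches placed outside the mature
duplex. The minimal loop and absent flanking spacers are forced by the flat
energy model (larger or mixed loops trade into spurious helices at zero
cost). FALSE cells of a promoter specification are guaranteed motif-free by
local scrubbing of any off-category match, so presence-matrix round-trips
are exact rather than probabilistic. Problem sizes in the shipped analysis
(two 3-kb scaffolds, 3–5 implants, nine 1,600-bp promoters, 200–300-nt
transcripts, 1,000 bootstrap replicates) keep every stage exact and fast.

Passing these tests shows the algorithms are correct and the pipeline is
calibrated under its own generative assumptions. It does not show that the
thresholds transfer to real genomes: real backgrounds have repeats and
skewed composition, real precursors have interior loops within the mature
duplex, real folds obey a nearest-neighbor energy model, and real qPCR
noise is not exactly Gaussian with perfect doubling.

## Known limitations

- The folding model omits stacking, loop penalties, dangles, and
  pseudoknots; its MFE/MFEI/NM values are model-specific.
- The homology scan has no E-value statistics; identity/coverage thresholds
  are the only filters.
- Target scoring explores at most one bulge and no target-site
  accessibility.
- The progressive aligner is star-guided and suited only to closely related
  sequences.
- Published clade topologies and full similarity matrices are not
  reproduction targets; algorithmic properties and internally consistent
  printed values are.
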