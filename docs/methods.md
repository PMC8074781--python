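# Methods

`mitoforge` implements the bespoke computations of a mitogenome
hybrid-assembly and population-mitogenomics workflow: reference-assisted
k-mer walkthrough assembly of a circular mitochondrial genome carrying a
duplicated control region, NUMT discovery with an identity threshold
calibrated from a mitogenome panel, capture-bait tiling design and
consensus calling, alignment diversity statistics, and parsimony homoplasy
indices on fixed topologies. This note records the models, the defaults
and why, the numerical choices, and the limits of what the synthetic tests
demonstrate.

## The assembly model

The target molecule is a circular mitogenome (default 18 kb) whose chief
assembly obstacle is a pair of nearly identical control-region copies
(CR1/CR2), each containing an internally exact tandem-repeat (TR) tract.
In a de Bruijn graph built from short reads at k = 23, both features create
bifurcations: shared CR stretches longer than k let a path jump between
copies, and the TR tract forms a cycle whose copy number k-mers cannot
count.

The walkthrough automates a manual workflow:

1. **Count** canonical 23-mers in the whole-genome short reads.
2. **Classify** k-mers as mitochondrial versus autosomal by coverage: a
   k-mer is mito-class when its count reaches the geometric mean of the
   mitochondrial and autosomal coverage estimates (supplied, or inferred
   from the two modes of the log2 count histogram; a unimodal histogram is
   an error, never a guess).
3. **Seed** at the first 23-mer of a named reference feature (default
   "12S rRNA") with an exact mito-class match in the read table — a
   related species' annotated mitogenome serves as the reference; only the
   seed and the expected length are taken from it.
4. **Extend** base by base while exactly one successor k-mer passes. Two
   k-mer orders work together: the order-23 mito-class predicate, plus a
   read-support predicate at order 101 (bounded by the read length) that
   requires every extension window to occur verbatim in some read. The
   longer order suppresses copy-jumping paths that order-23 cannot see,
   exactly as paired context does in a real assembly review.
5. **Resolve forks** (≥ 2 passing successors) by enumerating candidate
   continuations breadth-first to `max_branch_depth` (default 2500 bp,
   enough to cross a CR copy plus diagnostic flank) and scoring each
   against three evidence classes:
   - **amplicon lengths** — every PCR product whose two primer sites land
     on the extended contig must imply a length within 10% (gel precision)
     of the expected product;
   - **paired-end reads** — mate placements must admit an insert within
     mean ± 4 sd (a single discordant pair is tolerated as a sampling
     tail; two or more reject), and every screened branch position must be
     covered by a read placed with zero mismatches — a chimeric base
     swapped in from the other CR copy leaves a hole no genuine read spans
     exactly (this screen presumes error-free or corrected short reads and
     can be disabled);
   - **long reads** — each read spanning the fork is anchored to the
     contig by a gapless sliding match of the pre-fork anchor (300 bp),
     disambiguated between repeat copies by a 1.2 kb backward comparison,
     and the branch must match the read past the anchor at offset-banded
     gapless identity ≥ 0.8 (permissive at 10–15% read error).

   The unique branch consistent with all informative classes is committed.
   Several consistent branches agreeing on a common prefix commit only the
   prefix; the residual ambiguity is revisited at the next fork with fresh
   lookahead. Otherwise the fork is **AMBIGUOUS**: the assembler stops and
   reports it (the automated analogue of "manual intervention required")
   unless `force_first` is set. When branch enumeration would explode —
   the TR cycle spawns one candidate per extra repeat unit — paths whose
   prefix already contradicts an anchored long read are pruned; without
   long reads the enumeration is truncated at the path cap and the
   evidence checks decide, which for a TR fork correctly ends in
   AMBIGUOUS.
6. **Circularize** when the frontier k-mer returns to the seed exactly;
   the assembly is reported in canonical form (lexicographically minimal
   rotation over both strands) and validated three ways: banded identity
   of each solidity-trimmed long read (median ≥ 0.8), amplicon implied
   lengths (all within tolerance), and k-mer coverage continuity (no
   zero-coverage start around the circle).

### Why offset-banded gapless long-read comparison

Fork arbitration must distinguish continuations that differ by a repeat
unit (≈ 50 bp shift). An unconstrained aligner absorbs such a shift with
one gap at ~1% identity cost — undetectable under noise — whereas a
narrow offset band turns it into a frame shift that collapses identity.
The cost of the band is intolerance to indels in the reads; the simulator
therefore uses substitution-only read errors, and real indel-rich long
reads should be error-corrected with standard tools before assembly (the
workflow this package automates did exactly that).

### An identifiability limit, and what the generator does about it

If the two CR copies are identical over a run at least as long as the
short-read length, the evidence cannot reject a "copy-middle swap": a path
that crosses between copies inside two such runs is supported by every
short read, shifts no amplicon, and differs from the truth by ~1–2% —
beneath any long-read identity floor that tolerates 10% read error. Exact
recovery there would require deeper, cleaner long-read coverage than the
three-read scenario provides. The generator therefore disperses the CR
substitutions (exactly one per equal-width window), which bounds identical
runs to roughly twice the mean spacing (~100 bp at 0.98 identity over a
1 kb CR): far above k = 23, so copy-jump and TR forks still occur and must
be resolved by evidence, but below the read length, so every read-length
window contains a diagnostic site. Real CR pairs homogenised by concerted
evolution can contain longer identical tracts; on such data the assembler
reports AMBIGUOUS rather than guessing, and passing synthetic tests do not
demonstrate otherwise.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions.

- **Mitogenome** (default 18,000 bp): 14 protein-coding features (13
  genes + 1 pseudogene), 23 tRNA features (22 + 1 pseudogene), 2 rRNAs in
  a parrot-like order; two ~1 kb CR copies at 0.98 identity separated by a
  short duplicated block, each CR carrying a 50 bp × 6 TR tract whose unit
  is mutated once between copies and repeated exactly (emulating
  within-copy homogenisation). Gene content is random sequence — ORF
  structure is not emulated, so annotation tests plant explicit ORFs.
- **NUMTs**: copies of mitogenome intervals planted at non-overlapping
  positions in a random nuclear background; lengths log-uniform over
  54–5499 bp (the right-skew real censuses show), target identities
  uniform over 0.648–0.952, divergence as substitutions plus single-base
  indels at 10:1. Because a minimum-edit alignment recovers fewer
  differences than were planted, the mutation load is calibrated against
  the measured identity (matches over all alignment columns) until the
  realised value is within ~0.01 of target.
- **Reads**: FR-oriented pairs (150 bp, insert N(500, 50²), wraparound
  supported) and long reads (N(3500, 300²) — the 3–4 kb band) with
  substitution-only errors at configured rates; `long_span` forces long
  reads to bridge a stated interval, emulating reads selected because they
  span the duplicated-CR block. Quality scores, chimeras and platform
  error profiles are not modelled.
- **Amplicons**: primer-pair positions with half-open expected lengths
  (wrapping the origin); the default tiling yields 2 kb products, inside
  the 0.5–3.1 kb long-range-PCR range.

## NUMT discovery

A BLASTN-style seed-and-extend search: exact 11-mer seeds, two-hit
triggering (two non-overlapping seeds on nearby diagonals within 1 kb — a
single chance ≥ 12 bp match seen through overlapping windows does not
trigger), windowed Smith–Waterman extension with affine gaps
(+2/−3, gap open 5, extend 2) via Biopython's `PairwiseAligner`, and
Karlin–Altschul e-values (λ = 0.625, K = 0.41 for that scheme) with
cutoff 1e-4. The mitogenome is searched doubled so origin-spanning
insertions are found once; near-duplicate window alignments collapse to
the best-scoring hit. The identity threshold separating true NUMTs from
misassembled mtDNA is calibrated as the largest pairwise identity in a
panel of complete mitogenomes (gap-excluded denominator); candidate hits
above it are discarded. Identical matches (same coordinates and strand)
count once — the stricter, checkable reading of duplicate collapsing.
Overlap-merging beyond exact duplicates is deliberately not applied;
low-complexity regions may yield several overlapping hits, as with
unfiltered BLASTN.

## Capture, consensus, diversity, parsimony

- **Baits**: length 80, 4× tiling → one probe every 20 bp around the
  circle; on a circumference divisible by the step every position is
  covered exactly four times.
- **Read placement** is exact-seeded and gapless (Hamming extension, 5%
  mismatch ceiling); ties between repeat copies are left unplaced rather
  than guessed, and indel-bearing individuals are out of the placer's
  scope (map externally and supply consensus FASTA).
- **Consensus**: per-position majority; depth < 3 or an exact tie → N
  (never IUPAC codes, so downstream difference counting stays binary).
- **Diversity**: per-pair difference lists (N-masked; gap-vs-base counted
  only on request), 100-column block density tracks (final partial block
  keeps its raw count; no per-bp normalisation; boundaries from column 0),
  nucleotide diversity π as the all-pairs mean of differences over
  comparable (both-ACGT) columns — pairwise deletion, the average-pairwise-
  difference estimator — and a percent identity matrix on the same
  comparable-column convention.
- **Parsimony**: Fitch small parsimony vectorised across sites on a fixed
  topology (polytomies arbitrarily resolved; score is rooting-invariant),
  with non-ACGT leaf states treated as the full state set and a
  complete-deletion flag as the alternative. CI = M/S, RI = (G−S)/(G−M),
  composite RC = CI·RI, computed over all sites or informative-only sites
  side by side, since published values appear in both conventions; S = 0
  leaves the indices undefined (None), never 0/0.

## Numerical and interface conventions

Coordinates are 0-based half-open everywhere; circular features may have
`end > length` (wraparound encoding, never more than one full turn).
Canonical k-mers are the lexicographic minimum of a k-mer and its reverse
complement (numeric minimum in the 2-bit packing); k-mers containing N are
skipped. Circular sequences are compared via the lexicographically
minimal rotation over both strands (Booth's algorithm). Global identities
use edlib; the gap-excluded denominator is reported for mitogenome panels,
while infix placements and NUMT-planting calibration use the all-columns
denominator because the gap-excluded convention saturates near 0.7 even
for unrelated sequences under a minimum-edit alignment. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
pipeline stages derive per-stage seeds from the global seed by hashing.

## Problem sizes in the shipped benchmarks

The replicated benchmarks use the generator defaults: 18 kb genomes at
100× paired coverage with 3 spanning long reads at 10% error (20
replicates, assembled with and without the long reads), and 200 kb nuclear
backgrounds with 10 planted copies each at 70–95% identity and 150–3000 bp
(20 replicates). The unit-test suite exercises the same machinery on a
reduced 4.3 kb genome with a 500 bp duplicated CR, which preserves every
structural challenge at a fraction of the cost.

## Known limitations

- The assembler presumes substitution-dominated (or pre-corrected) long
  reads and error-free or near-error-free short reads for the
  exact-support screen; both assumptions are stated fail-closed — on
  violation the outcome is AMBIGUOUS or a failed validation, not a wrong
  sequence silently returned.
- Copy-middle swaps between CR copies identical over read-length runs are
  unidentifiable from the modelled evidence (see above).
- The NUMT search is not a BLASTN clone: hit boundaries and counts depend
  on seeding and windowing; agreement with BLASTN is at the locus level,
  which is what the census statistics consume.
- The simple read placer is gapless; indels relative to the reference
  shift or unplace reads rather than producing gapped alignments.
- tRNA structure detection is not implemented; tRNA features reach a new
  assembly only by annotation transfer.
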