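# Methods

## Problem and approach

B-cell malignancies (myeloma, lymphoma, leukemia) carry a clone-specific
rearranged immunoglobulin heavy-chain (IGH) sequence created by V(D)J
recombination. Targeted FR1 amplicon sequencing of the IGH locus turns
clonality assessment and measurable-residual-disease (MRD) tracking into a
read-counting problem: how many reads in a FASTQ library match the
patient's diagnostic clonotype? `swigh` answers this with a deliberately
simple toolchain — quality filtering, exact-duplicate collapsing,
Smith-Waterman local alignment with a length-adjusted similarity, and
count-weighted summarisation — organised so that the expensive alignment
step parallelises over chunks of unique reads.

## Quality filtering

A read passes if it is at least `min_length` bases long (default 200 bp)
and its effective mean Phred quality is at least `min_mean_quality`
(default Q20, i.e. a 1 % base-calling error rate). Two averaging modes
exist: the naive arithmetic mean of the Phred scores, and the mean of the
per-base error probabilities `10^(-q/10)` mapped back to the Phred scale.
The second is the statistically faithful mean and, by Jensen's inequality,
never exceeds the naive mean. Threshold comparisons use `>=`; this choice
is documented because truncating shell prototypes often behave as `>`.
Only Phred+33 encoding is accepted; `N` bases carry their recorded quality
and no separate N-fraction filter is applied.

## Local alignment and similarity

The pairwise scoring matrix `H` (dimensions len1 × len2) follows the
classic local-alignment recurrence with linear gap cost:

    H[i][j] = max(0, H[i-1][j-1] + s(a_i, b_j), H[i-1][j] + g, H[i][j-1] + g)

with `s = match` if the bases are equal (N never matches anything,
including N) else `mismatch`. One traceback starts at the maximal cell —
the first such cell in row-major order on ties — and follows a single path
(diagonal preferred over up over left on equal predecessors) to the first
zero cell, even when co-optimal alignments exist. The similarity is

    similarity = score / (match * alignment_length)

with alignment length counting gap columns, clamped to [0, 1], so a
perfect hit is exactly 1 under any weights and a read fully containing
(or contained in) the clone scores 1.0 regardless of flanking sequence.

**Default weights: match = +1, mismatch = 0, gap = -1.** The base
comparison is binary: a mismatch simply fails to add score rather than
subtracting it. Under this scheme the similarity of a read to its true
template is approximately `1 - e` for per-base error rate `e` (each
substitution costs 1/L of similarity, each indel 2/L), which is what makes
the canonical thresholds meaningful across platforms: short-read data
(e ≲ 1 %) concentrates above the 0.98 clone-matching threshold, and
nanopore-grade data (e ≈ 10 %) lands in the 0.85–0.90 band, matching the
practice of lowering the threshold for long-read libraries. A penalising
scheme (mismatch = -1) would instead cost 2/L per substitution and push
1 %-error reads onto the 0.98 boundary, cutting the measured clonal
fraction roughly in half — inconsistent with how the thresholds are used.
All three weights are exposed (`--match/--mismatch/--gap`) for users who
want a penalising or custom scheme.

The fill and traceback are JIT-compiled (numba); a 350 × 350 alignment
costs ~0.4 ms, and the library collapses duplicates first, so cost scales
with *unique* reads. The full integer matrix is kept (reads ≤ ~1 kb, so
≤ a few MB per pair); alignment is forward-strand only, since FR1
amplicons have fixed orientation.

## Clonotyping

V and J genes are assigned by aligning the full read against every
germline segment and taking the argmax similarity per segment class (ties
broken by gene name); no similarity threshold is applied to the best-hit
assignment, and D genes are not called. Three discovery modes:

* **sequence** — clonotype one user-provided sequence.
* **amplicon** — collapse the library to unique reads with counts
  (`sort | uniq -c` semantics: exact string grouping, qualities ignored,
  descending count then lexicographic order) and clonotype the top unique
  read. Amplicon duplication makes this fast and accurate on low-error
  short-read data; at nanopore error rates exact duplicates vanish (every
  read is unique at count 1) and this mode degrades by design — use the
  random mode there.
* **random** — subsample n reads (default 1000) uniformly without
  replacement (matching `shuf -n` semantics) from a fixed seed, clonotype
  each, and report the modal (V, J) *pair* — joint, not marginal, to
  prevent chimeric V-of-one-clone/J-of-another calls. The modal pair's
  share of the subsample is an approximate clonal-fraction estimate; the
  clone sequence reported is the most frequent exact sequence among
  modal-pair reads. Assignment is computed once per unique subsampled
  sequence and broadcast back, which changes nothing mathematically.

## Library scoring and reporting

`score_library` collapses the (already filtered) library, partitions the
unique reads into contiguous chunks of near-equal size, scores each unique
against the clone in worker processes (default workers = logical cores −
1), and merges the results sorted by descending similarity, count,
sequence. The output is byte-identical for any worker count, and a worker
failure aborts the run rather than emitting partial output. Similarities
are written to 4 decimal places so threshold comparisons reproduce across
platforms.

The report computes the clonal fraction — count-weighted reads with
similarity ≥ threshold (default 0.98) over all retained reads — plus a
101-bin similarity histogram (width 0.01, matching the percent granularity
thresholds are quoted in). An optional dissimilarity floor (e.g. 0.25)
removes highly dissimilar reads from the denominator entirely: they are
treated as non-detected IGH material, which reconciles platforms whose
libraries carry different amounts of off-target noise. The floor can only
raise the fraction, and the fraction is non-increasing in the threshold.

## Spike-in MRD quantification

With a spike-in control of known cell-equivalent content (default 100
cells) added to the library, absolute quantification uses cell-equivalent
normalisation:

    clone_cells = spikein_cells * clone_reads / spikein_reads

where spike-in reads are counted by a second similarity pass against the
spike-in sequence at the same threshold. The spike-in must be
distinguishable from the clone (mutual similarity below the threshold);
this is verified at run time, and zero spike-in reads yields a flagged
non-finite estimate with a warning, never a silent infinity. Conversion to
cells per 100,000 leukocytes requires an explicit user-supplied total
leukocyte-equivalent denominator; the package does not guess one.

## Synthetic libraries

The generator emulates a dilution-series validation design: a clone
(chosen V + 5–25 bp random junction + chosen J) planted at a configured
fraction, a polyclonal background of distinct V/junction/J recombinants,
an optional random spike-in sequence at a configured fraction and
cell-equivalent content, per-base substitution/insertion/deletion errors,
and Phred strings jittered around a mean quality. Read counts per class
are one multinomial draw, recorded exactly in the ground truth, so
pipeline recovery can be checked read-for-read rather than in expectation.
Platform-like read-length profiles (`short_300`, `short_317`, `long_476`)
truncate or randomly flank reads around the platform median; the default
`amplicon` profile keeps the full recombinant, which the exact-collapse
checks rely on.

Two deliberate simplifications, and what they imply about test coverage:

* Background clonotypes exclude the clone's own V and J genes. Real
  repertoires draw from ~50 IGHV genes, so sharing is rare but nonzero; a
  background read sharing the clone's V aligns to it locally at similarity
  1.0 and would be counted as clonal. Excluding it makes the planted
  fraction exactly recoverable on error-free data; on real data the
  clonal fraction is correspondingly an upper-bound-leaning estimate when
  the background contains same-V rearrangements.
* Base errors are injected independently of the quality string, and
  qualities are Gaussian around the configured mean. This suffices for
  testing the filter predicate and threshold behaviour but does not model
  real instruments' quality/error correlation, homopolymer error
  structure, PCR bias or chimeras — passing tests demonstrate pipeline
  correctness on the stated error model, not platform realism.

Toy germline references are independent random sequences (V ≈ 290 bp,
J ≈ 50 bp) redrawn until all pairwise similarities are below 0.80; under
the binary scoring scheme unrelated sequences sit near 0.4–0.5 similarity,
so assignments and the 0.85–0.98 threshold band are unambiguous.

## Problem sizes and numerical choices

The validation suite runs at desk scale: diagnostic-regime libraries of
5,000–20,000 reads (clonal fraction 0.85), dilution libraries of 200,000
reads with planted fractions 1e-3/1e-4 checked within 3 Poisson standard
deviations and for a 10-fold ratio, a 50,000-read spike-in library
(100-cell spike-in, 20 planted cell equivalents), and 10-seed clonotype
recovery at substitution rates 0–10 % (amplicon mode at 0–1 %, the
duplicated regime it targets). Determinism: every stochastic step takes an
explicit seed; subsampling and chunking are deterministic; all tie-breaks
(max cell, traceback direction, equal counts, equal similarities) are
specified and lexicographic/row-major, so outputs are bit-reproducible
across runs and worker counts.

## Known limitations

Single dominant clonotype only (no oligoclonal reporting, CDR3 extraction
or somatic-hypermutation profiling); linear gap cost (no affine gaps);
forward strand only; cost O(len1·len2) per unique pair with no banding or
vectorised striping; no distributed execution.
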