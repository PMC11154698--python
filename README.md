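# swigh

Clonotyping and measurable-residual-disease (MRD) scoring of rearranged
immunoglobulin heavy-chain (IGH) amplicon sequencing reads.

B-cell malignancies carry a clone-specific rearranged IGH sequence
created by V(D)J recombination. Given targeted FR1 amplicon FASTQ data,
`swigh` identifies the dominant clonotype (its germline V and J gene and
clone sequence) and quantifies the clonal burden: the fraction of reads
matching the clone, and — with a spike-in control of known cell content —
an absolute estimate of clonal cells. It works across short-read
(MiSeq/Ion-type) and long-read (nanopore-type) error regimes.

## Method

The core is Smith-Waterman local alignment with a length-adjusted
similarity. For sequences *a*, *b* the scoring matrix follows

    H[i,j] = max(0, H[i-1,j-1] + s(a_i, b_j), H[i-1,j] + g, H[i,j-1] + g)

with binary base comparison (match +1, mismatch 0) and linear gap cost
g = −1 by default. A single traceback from the maximal cell yields the
alignment length L, and

    similarity = score / (match · L)  ∈ [0, 1]

so a read with per-base error rate *e* scores ≈ 1 − *e* against its true
template. Reads with similarity ≥ 0.98 to the clone are counted as clonal
(lower thresholds such as 0.85–0.90 suit high-error long reads); the
clonal fraction is their count-weighted share of all detected reads.
With a spike-in worth `spikein_cells` cells,

    clone_cells = spikein_cells · clone_reads / spikein_reads.

Pipeline stages: quality filtering (length ≥ 200 bp, mean Phred ≥ Q20 by
naive or error-probability averaging) → exact-duplicate collapsing →
chunked multi-process alignment of unique reads → threshold report with a
similarity histogram. Clonotype discovery offers three modes: a single
sequence, the most frequent unique read (amplicon mode), or the modal
(V, J) pair of a random subsample (robust at high error rates). See
`docs/methods.md` for the full model and design choices.

## Worked example

Simulate a library with a known clone planted at fraction 0.85 and 1 %
substitution errors, then run the pipeline:

```
$ swigh simulate --n-reads 10000 --clonal-fraction 0.85 --sub-rate 0.01 \
      --seed 42 -o lib.fastq --truth truth.tsv
simulated 10000 reads (clone 8514, background 1486, spikein 0)

$ swigh quality-filter lib.fastq -o filtered.fastq
10000/10000 reads passed

$ grep '^clone_sequence' truth.tsv | cut -f2 > clone.txt
$ printf '>clone\n%s\n' "$(cat clone.txt)" > clone.fasta
$ swigh score filtered.fastq --clone clone.fasta --workers 2 -o scored.tsv
scored 9512 unique reads

$ swigh report scored.tsv --threshold 0.98 -o report.tsv
clonal_fraction 0.8270
```

The ground truth planted 8,514 clone reads (fraction 0.8514); at the 98 %
similarity threshold the pipeline reports 8,270 of 10,000 reads as clonal
(fraction 0.8270). The gap is the expected effect of 1 % errors: a few
percent of clone reads accumulate enough errors to fall below 0.98. The
report file also contains a 101-bin similarity histogram.

Clonotyping against a reference set recovers the planted V/J genes:

```
$ swigh make-refs --n-v 5 --n-j 3 --seed 42 -o refs
$ swigh clonotype-amplicon filtered.fastq --v-refs refs/V.fasta --j-refs refs/J.fasta
# v_gene  v_pct   j_gene  j_pct   support clonal_fraction_estimate
toyV1     100.0   toyJ3   100.0   212     NA
$ swigh clonotype-random filtered.fastq --v-refs refs/V.fasta --j-refs refs/J.fasta \
      --n 1000 --seed 7 --workers 2
toyV1     100.0   toyJ3   100.0   857     0.8570
```

Amplicon mode finds the clone as the top unique read (212 identical
copies survived the 1 % error rate); random mode estimates the clonal
fraction at 0.857 from a 1,000-read subsample. For real data, point
`--v-refs/--j-refs` at your own IMGT germline FASTA download and use a
spike-in via `swigh report ... --clone clone.fasta --spikein spike.fasta
--spikein-cells 100`.

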