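"""Clonotype discovery: single-sequence, amplicon, and random-subsample modes.

A clonotype is reported as the best-matching germline V gene and J gene
(with their percent similarities) plus the clone sequence backing the
call.  Three strategies are implemented:

* sequence — clonotype one provided DNA sequence directly.
* amplicon — exploit amplicon duplication: collapse the library to unique
  reads with counts and clonotype the most frequent one.  Fast and exact
  on low-error short-read data, where the dominant clone yields many
  identical reads; not suited to high-error long-read libraries in which
  duplicates are rare.
* random — stochastically subsample n reads (default 1000), clonotype
  each, and take the modal (V, J) pair; its share of the subsample is an
  approximate clonal-fraction estimate.  Robust to per-read errors since
  every subsampled read votes.

The modal pair is taken jointly (not as independent V and J marginals),
which prevents chimeric calls combining the V of one clone with the J of
another.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .fastq_qc import SequencedRead
from .germline_refs import ReferenceSet
from .sw_core import AlignmentParams, percent_similarity, sw_similarity

__all__ = [
    "UniqueRead",
    "ClonotypeCall",
    "collapse_unique",
    "clonotype_sequence",
    "clonotype_amplicon",
    "clonotype_random",
    "assign_vj",
]


@dataclass(frozen=True)
class UniqueRead:
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class ClonotypeCall:
    v_gene: str
    v_pct: float
    j_gene: str
    j_pct: float
    clone_sequence: str
    support: int
    clonal_fraction_estimate: float | None = None


def _bases(read: SequencedRead | str) -> str:
    return read if isinstance(read, str) else read.bases


def collapse_unique(reads: Iterable[SequencedRead | str]) -> list[UniqueRead]:
    """Collapse exact-duplicate read strings to (sequence, count) pairs.

    Qualities are ignored; the result is ordered by descending count,
    ties broken by lexicographic sequence.  The total count always equals
    the number of input reads.
    """
    counts = Counter(_bases(r) for r in reads)
    return [
        UniqueRead(sequence=s, count=c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def assign_vj(
    seq: str, refs: ReferenceSet, params: AlignmentParams | None = None
) -> tuple[str, float, str, float]:
    """Best-hit V and J genes for one sequence, with percent similarities.

    Every reference segment is aligned locally against the full sequence;
    the argmax-similarity gene wins, ties broken by gene name.  No
    similarity threshold is applied — even a poor best hit is reported.
    """
    params = params or AlignmentParams()
    if not refs.v_genes or not refs.j_genes:
        raise ValueError("reference set must contain V and J genes")

    def best(genes) -> tuple[str, float]:
        scored = sorted(
            ((g.gene_name, sw_similarity(seq, g.sequence, params)) for g in genes),
            key=lambda kv: (-kv[1], kv[0]),
        )
        return scored[0]

    v_name, v_sim = best(refs.v_genes)
    j_name, j_sim = best(refs.j_genes)
    return v_name, percent_similarity(v_sim), j_name, percent_similarity(j_sim)


def clonotype_sequence(
    seq: str, refs: ReferenceSet, params: AlignmentParams | None = None
) -> ClonotypeCall:
    """Clonotype a single provided DNA sequence."""
    if not seq:
        raise ValueError("empty query sequence")
    v_name, v_pct, j_name, j_pct = assign_vj(seq, refs, params)
    return ClonotypeCall(
        v_gene=v_name,
        v_pct=v_pct,
        j_gene=j_name,
        j_pct=j_pct,
        clone_sequence=seq,
        support=1,
    )


def clonotype_amplicon(
    reads: Iterable[SequencedRead | str],
    refs: ReferenceSet,
    params: AlignmentParams | None = None,
) -> ClonotypeCall:
    """Clonotype the most frequent unique read of an amplicon library."""
    uniques = collapse_unique(reads)
    if not uniques:
        raise ValueError("empty read set: nothing to clonotype")
    top = uniques[0]
    call = clonotype_sequence(top.sequence, refs, params)
    return ClonotypeCall(
        v_gene=call.v_gene,
        v_pct=call.v_pct,
        j_gene=call.j_gene,
        j_pct=call.j_pct,
        clone_sequence=top.sequence,
        support=top.count,
    )


def clonotype_random(
    reads: Sequence[SequencedRead | str],
    refs: ReferenceSet,
    n: int = 1000,
    seed: int = 0,
    params: AlignmentParams | None = None,
    workers: int = 1,
) -> ClonotypeCall:
    """Clonotype a uniform random subsample and take the modal (V, J) pair.

    min(n, available) reads are drawn without replacement using ``seed``;
    each is assigned its best-hit V and J.  The modal joint pair is the
    call; the fraction of subsampled reads carrying it is the
    clonal-fraction estimate; the clone sequence is the most frequent
    exact sequence among modal-pair reads.  Bit-reproducible for a fixed
    seed, independent of ``workers``.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("empty read set: nothing to clonotype")
    rng = np.random.default_rng(seed)
    k = min(n, len(reads))
    idx = rng.choice(len(reads), size=k, replace=False)
    sample = [_bases(reads[i]) for i in idx]

    # assign once per unique sampled sequence (amplicon libraries are
    # heavily duplicated), then broadcast back to the sample
    unique_seqs = sorted(set(sample))
    if workers > 1:
        from .clone_scoring import parallel_map_chunks

        unique_assignments = parallel_map_chunks(
            _assign_chunk, unique_seqs, workers, refs=refs, params=params
        )
    else:
        unique_assignments = _assign_chunk(unique_seqs, refs=refs, params=params)
    by_seq = dict(zip(unique_seqs, unique_assignments))
    assignments = [by_seq[s] for s in sample]

    pair_counts = Counter((v, j) for v, _, j, _ in assignments)
    (modal_v, modal_j), modal_count = sorted(
        pair_counts.items(), key=lambda kv: (-kv[1], kv[0])
    )[0]
    modal_seqs = [
        s for s, (v, _, j, _) in zip(sample, assignments) if (v, j) == (modal_v, modal_j)
    ]
    clone_seq = sorted(Counter(modal_seqs).items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
    # percent similarities reported for the representative clone sequence
    v_name, v_pct, j_name, j_pct = assign_vj(clone_seq, refs, params)
    return ClonotypeCall(
        v_gene=modal_v,
        v_pct=v_pct if v_name == modal_v else _pct_for(clone_seq, refs, modal_v, params),
        j_gene=modal_j,
        j_pct=j_pct if j_name == modal_j else _pct_for(clone_seq, refs, modal_j, params),
        clone_sequence=clone_seq,
        support=modal_count,
        clonal_fraction_estimate=modal_count / k,
    )


def _assign_chunk(seqs, refs=None, params=None):
    return [assign_vj(s, refs, params) for s in seqs]


def _pct_for(seq: str, refs: ReferenceSet, gene_name: str, params) -> float:
    gene = refs.gene(gene_name)
    return percent_similarity(sw_similarity(seq, gene.sequence, params or AlignmentParams()))
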