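"""Library scoring against an identified clonotype sequence.

The scoring engine collapses a quality-filtered library to unique reads
with counts, partitions the uniques into contiguous chunks, scores every
unique sequence against the clone with the Smith-Waterman core in
worker processes, and merges the chunk results while preserving counts.
Because amplicon libraries are heavily duplicated, the alignment cost is
one alignment per *unique* sequence, not per raw read.

The output is invariant to the worker count: chunking is deterministic,
each unique is scored independently, and the merged result is sorted by
descending similarity, then descending count, then sequence.  A failing
worker aborts the whole run — there is no silent partial output.
"""

from __future__ import annotations

import multiprocessing as mp
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence, TypeVar

from .clonotyping import UniqueRead, collapse_unique
from .fastq_qc import SequencedRead
from .sw_core import AlignmentParams, reverse_complement, sw_similarity

__all__ = [
    "ScoredUnique",
    "ScoreRunConfig",
    "chunk_partition",
    "score_library",
    "parallel_map_chunks",
    "write_scored",
    "read_scored",
    "default_workers",
]

T = TypeVar("T")


def default_workers() -> int:
    """Available logical cores minus one, at least one."""
    return max(1, (os.cpu_count() or 2) - 1)


@dataclass(frozen=True)
class ScoredUnique:
    sequence: str
    count: int
    similarity: float

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError("similarity must be in [0, 1]")


@dataclass(frozen=True)
class ScoreRunConfig:
    workers: int = field(default_factory=default_workers)
    params: AlignmentParams = field(default_factory=AlignmentParams)
    threshold: float = 0.98
    floor: float | None = None
    # FR1 amplicons have fixed orientation, so forward-only by default;
    # enable for libraries of mixed strandedness
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        if self.floor is not None and not 0.0 <= self.floor < self.threshold:
            raise ValueError("floor must satisfy 0 <= floor < threshold")


def chunk_partition(items: Sequence[T], k: int) -> list[list[T]]:
    """Split a sequence into k contiguous chunks whose sizes differ by <= 1.

    Concatenating the chunks restores the input order; empty chunks are
    allowed when k exceeds the number of items.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(items)
    base, extra = divmod(n, k)
    chunks: list[list[T]] = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        chunks.append(list(items[start : start + size]))
        start += size
    return chunks


def _score_chunk(
    seqs: list[str], clone: str, params: AlignmentParams, both_strands: bool = False
) -> list[float]:
    if both_strands:
        rc = reverse_complement(clone)
        return [
            max(sw_similarity(s, clone, params), sw_similarity(s, rc, params))
            for s in seqs
        ]
    return [sw_similarity(s, clone, params) for s in seqs]


def parallel_map_chunks(
    fn: Callable[..., list],
    items: Sequence,
    workers: int,
    **kwargs,
) -> list:
    """Apply ``fn(chunk, **kwargs)`` over contiguous chunks, in processes.

    Results are concatenated in chunk order, so the output equals the
    single-process ``fn(items, **kwargs)`` whenever fn is elementwise.
    Worker exceptions propagate and abort the run.
    """
    chunks = [c for c in chunk_partition(items, workers) if c]
    if len(chunks) <= 1:
        return fn(list(items), **kwargs)
    ctx = mp.get_context("fork" if "fork" in mp.get_all_start_methods() else "spawn")
    with ctx.Pool(processes=len(chunks)) as pool:
        results = pool.starmap(_apply_kwargs, [(fn, c, kwargs) for c in chunks])
    return [x for chunk_result in results for x in chunk_result]


def _apply_kwargs(fn, chunk, kwargs):
    return fn(chunk, **kwargs)


def score_library(
    reads: Iterable[SequencedRead | str],
    clone: str,
    cfg: ScoreRunConfig | None = None,
) -> list[ScoredUnique]:
    """Collapse a library and score every unique read against the clone.

    ``reads`` are assumed already quality-filtered.  Returns ScoredUnique
    records ordered by descending similarity, then descending count, then
    sequence; the summed counts equal the number of input reads.  The
    result is identical for any worker count.
    """
    if not clone:
        raise ValueError("clone sequence must be non-empty")
    cfg = cfg or ScoreRunConfig()
    uniques = collapse_unique(reads)
    if not uniques:
        warnings.warn("score_library: empty input library", stacklevel=2)
        return []
    seqs = [u.sequence for u in uniques]
    sims = parallel_map_chunks(
        _score_chunk,
        seqs,
        cfg.workers,
        clone=clone,
        params=cfg.params,
        both_strands=cfg.both_strands,
    )
    scored = [
        ScoredUnique(sequence=u.sequence, count=u.count, similarity=sim)
        for u, sim in zip(uniques, sims)
    ]
    scored.sort(key=lambda s: (-s.similarity, -s.count, s.sequence))
    return scored


def write_scored(scored: Iterable[ScoredUnique], path: str | Path) -> None:
    """TSV: sequence, count, similarity (4 decimal places)."""
    with open(path, "wt") as out:
        out.write("# sequence\tcount\tsimilarity\n")
        for s in scored:
            out.write(f"{s.sequence}\t{s.count}\t{s.similarity:.4f}\n")


def read_scored(path: str | Path) -> list[ScoredUnique]:
    scored = []
    with open(path, "rt") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            seq, count, sim = line.split("\t")
            scored.append(ScoredUnique(seq, int(count), float(sim)))
    return scored
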