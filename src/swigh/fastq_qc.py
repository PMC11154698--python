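"""FASTQ ingestion and quality filtering.

Reads are kept if they are at least ``min_length`` bases long and their
effective mean Phred quality reaches ``min_mean_quality`` (default Q20,
i.e. a 1 % base-calling error rate).  Two averaging modes are provided:

* ``naive_mean`` — the arithmetic mean of the per-base Phred scores.
* ``error_prob_mean`` — the mean of the per-base error probabilities
  10^(-q/10), mapped back to the Phred scale.  This is the statistically
  faithful average (a single terrible base drags it down much more than
  the naive mean) and is never larger than the naive mean.

Only Phred+33 (Sanger) encoding is accepted; offset-64 files are an
obsolete format and are rejected rather than silently misdecoded.
Gzipped input is handled transparently.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequencedRead",
    "QualityMode",
    "QualityFilterConfig",
    "FilterStats",
    "FastqParseError",
    "parse_fastq",
    "write_fastq",
    "mean_quality",
    "quality_filter",
]


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records, naming the failing record index."""


class QualityMode(str, Enum):
    naive_mean = "naive_mean"
    error_prob_mean = "error_prob_mean"


@dataclass(frozen=True, eq=False)
class SequencedRead:
    """One FASTQ record: identifier, bases, per-base Phred scores."""

    read_id: str
    bases: str
    quals: np.ndarray  # int array, same length as bases

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequencedRead):
            return NotImplemented
        return (
            self.read_id == other.read_id
            and self.bases == other.bases
            and np.array_equal(self.quals, other.quals)
        )

    def __hash__(self) -> int:
        return hash((self.read_id, self.bases))

    def __post_init__(self) -> None:
        q = np.asarray(self.quals, dtype=np.int16)
        object.__setattr__(self, "quals", q)
        if len(q) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but {len(q)} quality scores"
            )
        if len(q) and q.min() < 0:
            raise ValueError(f"read {self.read_id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class QualityFilterConfig:
    min_length: int = 200
    min_mean_quality: float = 20.0
    mode: QualityMode = QualityMode.naive_mean

    def __post_init__(self) -> None:
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")
        if self.min_mean_quality < 0:
            raise ValueError("min_mean_quality must be >= 0")


@dataclass
class FilterStats:
    input: int = 0
    passed: int = 0
    failed_length: int = 0
    failed_quality: int = 0

    @property
    def failed(self) -> int:
        return self.failed_length + self.failed_quality


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_fastq(path: str | Path) -> Iterator[SequencedRead]:
    """Stream SequencedRead objects from a (possibly gzipped) FASTQ file.

    Quality characters are decoded as Phred+33.  Malformed records raise
    FastqParseError carrying the 0-based record index.
    """
    handle = _open_text(path)
    index = 0
    try:
        for title, seq, qual in FastqGeneralIterator(handle):
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"record {index} ({title.split()[0] if title else '?'}): "
                    f"{len(seq)} bases but {len(qual)} quality characters"
                )
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
            if len(quals) and quals.min() < 0:
                raise FastqParseError(
                    f"record {index}: quality character below '!' — not Phred+33"
                )
            yield SequencedRead(read_id=title, bases=seq.upper(), quals=quals)
            index += 1
    except ValueError as exc:
        if isinstance(exc, FastqParseError):
            raise
        raise FastqParseError(f"record {index}: {exc}") from exc
    finally:
        handle.close()


def write_fastq(reads: Iterable[SequencedRead], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for read in reads:
            qual = "".join(chr(int(q) + 33) for q in read.quals)
            out.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    return n


def mean_quality(read: SequencedRead, mode: QualityMode = QualityMode.naive_mean) -> float:
    """Effective mean Phred quality of a read under the chosen mode.

    naive_mean: arithmetic mean of the scores.  error_prob_mean:
    -10*log10 of the mean per-base error probability 10^(-q/10).
    """
    if len(read) == 0:
        raise ValueError(f"read {read.read_id!r} is empty: mean quality undefined")
    q = read.quals.astype(np.float64)
    if QualityMode(mode) is QualityMode.naive_mean:
        return float(q.mean())
    p_err = np.power(10.0, -q / 10.0)
    return float(-10.0 * math.log10(p_err.mean()))


def quality_filter(
    reads: Iterable[SequencedRead], cfg: QualityFilterConfig | None = None
) -> tuple[list[SequencedRead], FilterStats]:
    """Apply the length + mean-quality predicate; order is preserved.

    A read passes iff len >= min_length AND mean_quality >= min_mean_quality
    (threshold comparisons are >=).  Returns the passing reads and the
    count bookkeeping (input = passed + failed always holds).
    """
    cfg = cfg or QualityFilterConfig()
    stats = FilterStats()
    passed: list[SequencedRead] = []
    for read in reads:
        stats.input += 1
        if len(read) < cfg.min_length:
            stats.failed_length += 1
            continue
        if len(read) and mean_quality(read, cfg.mode) < cfg.min_mean_quality:
            stats.failed_quality += 1
            continue
        stats.passed += 1
        passed.append(read)
    return passed, stats


def write_filter_stats(stats: FilterStats, cfg: QualityFilterConfig, path: str | Path) -> None:
    """3-column TSV: metric, value, mode."""
    mode = QualityMode(cfg.mode).value
    rows = [
        ("input_reads", stats.input),
        ("passed_reads", stats.passed),
        ("failed_length", stats.failed_length),
        ("failed_quality", stats.failed_quality),
    ]
    with open(path, "wt") as out:
        out.write("# metric\tvalue\tmode\n")
        for name, value in rows:
            out.write(f"{name}\t{value}\t{mode}\n")
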