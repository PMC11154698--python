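"""Summaries of scored libraries: similarity distribution, clonal fraction,
and spike-in based absolute MRD quantification.

The clonal fraction is the relative fraction of clonally rearranged reads
— count-weighted unique reads whose similarity to the clone reaches the
threshold (default 0.98) — among all detected reads.  An optional
dissimilarity floor (e.g. 0.25) removes highly dissimilar reads from the
denominator: such reads are treated as non-detected IGH material rather
than polyclonal background, which reconciles platforms whose libraries
carry different amounts of off-target noise.

Absolute quantification uses a spike-in control of known cell-equivalent
content (default 100 cells): clone cells = spikein_cells * clone_reads /
spikein_reads.  Dividing by a user-supplied total leukocyte-equivalent
count converts this to the conventional cells-per-100,000 scale; the
denominator is an explicit input, never guessed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .clone_scoring import ScoredUnique
from .sw_core import AlignmentParams, sw_similarity

__all__ = [
    "ScoreReport",
    "MRDEstimate",
    "build_report",
    "estimate_mrd",
    "write_report",
    "parse_report",
]

N_BINS = 101  # similarity histogram: bins of width 0.01 over [0, 1]


@dataclass(frozen=True)
class ScoreReport:
    total_reads: int  # count-weighted reads in the denominator (after floor)
    clone_reads: int  # count-weighted reads with similarity >= threshold
    clonal_fraction: float
    histogram: tuple[int, ...]  # N_BINS counts, bin i = similarity round(i/100, 2)
    threshold: float
    floor_applied: float | None = None


@dataclass(frozen=True)
class MRDEstimate:
    clone_reads: int
    spikein_reads: int
    spikein_cells: int
    clone_cells: float  # spikein_cells * clone_reads / spikein_reads
    cells_per_1e5: float | None = None

    @property
    def finite(self) -> bool:
        return math.isfinite(self.clone_cells)


def _bin_index(similarity: float) -> int:
    return min(N_BINS - 1, max(0, int(round(similarity * 100))))


def build_report(
    scored: Sequence[ScoredUnique],
    threshold: float = 0.98,
    floor: float | None = None,
) -> ScoreReport:
    """Summarise a scored library at a similarity threshold.

    Reads below ``floor`` (when given) leave the denominator entirely;
    the histogram covers the retained reads, so its mass equals
    total_reads.
    """
    if not scored:
        raise ValueError("cannot report on an empty scored library")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if floor is not None and floor >= threshold:
        raise ValueError("floor must be below threshold")
    hist = [0] * N_BINS
    total = 0
    clone = 0
    for s in scored:
        if floor is not None and s.similarity < floor:
            continue
        total += s.count
        hist[_bin_index(s.similarity)] += s.count
        if s.similarity >= threshold:
            clone += s.count
    fraction = clone / total if total else 0.0
    return ScoreReport(
        total_reads=total,
        clone_reads=clone,
        clonal_fraction=fraction,
        histogram=tuple(hist),
        threshold=threshold,
        floor_applied=floor,
    )


def estimate_mrd(
    scored: Sequence[ScoredUnique],
    clone: str,
    spikein: str,
    threshold: float = 0.98,
    spikein_cells: int = 100,
    total_leukocyte_equivalents: int | None = None,
    params: AlignmentParams | None = None,
) -> MRDEstimate:
    """Absolute clone-cell estimate from a spike-in control.

    ``scored`` must hold similarities against ``clone``; a second pass
    scores every unique sequence against the spike-in at the same
    threshold.  The spike-in must be distinguishable from the clone
    (mutual similarity below the threshold) — this is verified, not
    assumed.
    """
    params = params or AlignmentParams()
    mutual = sw_similarity(clone, spikein, params)
    if mutual >= threshold:
        raise ValueError(
            f"spike-in and clone are confusable: similarity {mutual:.4f} >= "
            f"threshold {threshold}"
        )
    clone_reads = sum(s.count for s in scored if s.similarity >= threshold)
    spikein_reads = sum(
        s.count
        for s in scored
        if sw_similarity(s.sequence, spikein, params) >= threshold
    )
    if spikein_reads == 0:
        warnings.warn(
            "no reads matched the spike-in control: absolute estimate is undefined",
            stacklevel=2,
        )
        clone_cells = 0.0 if clone_reads == 0 else math.nan
    else:
        clone_cells = spikein_cells * clone_reads / spikein_reads
    cells_per_1e5 = None
    if total_leukocyte_equivalents is not None and math.isfinite(clone_cells):
        cells_per_1e5 = clone_cells / total_leukocyte_equivalents * 1e5
    return MRDEstimate(
        clone_reads=clone_reads,
        spikein_reads=spikein_reads,
        spikein_cells=spikein_cells,
        clone_cells=clone_cells,
        cells_per_1e5=cells_per_1e5,
    )


def write_report(
    report: ScoreReport, path: str | Path, mrd: MRDEstimate | None = None
) -> None:
    """Mixed tabulated output: key-value header block, then the
    101-row similarity histogram."""
    with open(path, "wt") as out:
        out.write("# swigh report\n")
        out.write(f"total_reads\t{report.total_reads}\n")
        out.write(f"clone_reads\t{report.clone_reads}\n")
        out.write(f"clonal_fraction\t{report.clonal_fraction:.4f}\n")
        out.write(f"threshold\t{report.threshold:.4f}\n")
        if report.floor_applied is not None:
            out.write(f"floor\t{report.floor_applied:.4f}\n")
        if mrd is not None:
            out.write(f"mrd_clone_reads\t{mrd.clone_reads}\n")
            out.write(f"mrd_spikein_reads\t{mrd.spikein_reads}\n")
            out.write(f"mrd_spikein_cells\t{mrd.spikein_cells}\n")
            out.write(f"mrd_clone_cells\t{mrd.clone_cells:.4f}\n")
            if mrd.cells_per_1e5 is not None:
                out.write(f"mrd_cells_per_1e5\t{mrd.cells_per_1e5:.4f}\n")
        out.write("# similarity_bin\tread_count\n")
        for i, count in enumerate(report.histogram):
            out.write(f"{i / 100:.2f}\t{count}\n")


def parse_report(path: str | Path) -> tuple[ScoreReport, MRDEstimate | None]:
    """Round-trip parser for write_report output."""
    kv: dict[str, str] = {}
    hist = [0] * N_BINS
    with open(path, "rt") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            key, value = line.split("\t")
            try:
                bin_val = float(key)
            except ValueError:
                kv[key] = value
                continue
            hist[_bin_index(bin_val)] = int(value)
    report = ScoreReport(
        total_reads=int(kv["total_reads"]),
        clone_reads=int(kv["clone_reads"]),
        clonal_fraction=float(kv["clonal_fraction"]),
        histogram=tuple(hist),
        threshold=float(kv["threshold"]),
        floor_applied=float(kv["floor"]) if "floor" in kv else None,
    )
    mrd = None
    if "mrd_clone_cells" in kv:
        mrd = MRDEstimate(
            clone_reads=int(kv["mrd_clone_reads"]),
            spikein_reads=int(kv["mrd_spikein_reads"]),
            spikein_cells=int(kv["mrd_spikein_cells"]),
            clone_cells=float(kv["mrd_clone_cells"]),
            cells_per_1e5=(
                float(kv["mrd_cells_per_1e5"]) if "mrd_cells_per_1e5" in kv else None
            ),
        )
    return report, mrd
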