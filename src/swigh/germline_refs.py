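"""Germline IGHV / IGHJ reference handling.

V and J gene assignment needs a reference set of germline segment
sequences, typically an IMGT/GENE-DB download the user supplies (those
sequences are not redistributed here).  Headers in the pipe-delimited
IMGT FASTA format (">X92287|IGHV3-11*06|Homo sapiens|...") yield the
allele token as the gene name; plain headers use the first word.  IMGT
alignment gap dots are stripped, since all downstream alignment is local.

``make_toy_references`` builds a small synthetic reference set with
strongly divergent segments so that best-hit V/J assignment on simulated
data is unambiguous — this keeps the whole test suite download-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .sw_core import AlignmentParams, sw_similarity

__all__ = [
    "Segment",
    "GermlineGene",
    "ReferenceSet",
    "load_references",
    "write_references",
    "make_toy_references",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class Segment(str, Enum):
    V = "V"
    J = "J"


@dataclass(frozen=True)
class GermlineGene:
    """A named germline V or J segment sequence (e.g. IGHV3-11*06)."""

    gene_name: str
    segment: Segment
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"gene {self.gene_name!r} has an empty sequence")


@dataclass(frozen=True)
class ReferenceSet:
    v_genes: tuple[GermlineGene, ...]
    j_genes: tuple[GermlineGene, ...]

    def __post_init__(self) -> None:
        for label, genes in (("V", self.v_genes), ("J", self.j_genes)):
            names = [g.gene_name for g in genes]
            dupes = sorted({n for n in names if names.count(n) > 1})
            if dupes:
                raise ValueError(f"duplicate {label} gene names: {dupes}")

    def gene(self, name: str) -> GermlineGene:
        for g in (*self.v_genes, *self.j_genes):
            if g.gene_name == name:
                return g
        raise KeyError(name)


def _parse_header(description: str) -> str:
    if "|" in description:
        fields = description.split("|")
        # IMGT format: accession|allele|species|...
        if len(fields) >= 2 and fields[1]:
            return fields[1].strip()
    return description.split()[0]


def _load_segment(path: str | Path, segment: Segment) -> tuple[GermlineGene, ...]:
    genes = []
    for record in SeqIO.parse(str(path), "fasta"):
        name = _parse_header(record.description)
        seq = str(record.seq).upper().replace(".", "")
        genes.append(GermlineGene(gene_name=name, segment=segment, sequence=seq))
    if not genes:
        raise ValueError(f"no FASTA records in {path}")
    return tuple(genes)


def load_references(v_fasta: str | Path, j_fasta: str | Path) -> ReferenceSet:
    """Load V and J germline FASTA files into a ReferenceSet."""
    return ReferenceSet(
        v_genes=_load_segment(v_fasta, Segment.V),
        j_genes=_load_segment(j_fasta, Segment.J),
    )


def write_references(refs: ReferenceSet, v_fasta: str | Path, j_fasta: str | Path) -> None:
    for path, genes in ((v_fasta, refs.v_genes), (j_fasta, refs.j_genes)):
        with open(path, "wt") as out:
            for g in genes:
                out.write(f">{g.gene_name}\n{g.sequence}\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def make_toy_references(
    n_v: int,
    n_j: int,
    seed: int,
    v_length: int = 290,
    j_length: int = 50,
    max_pairwise_similarity: float = 0.80,
) -> ReferenceSet:
    """Deterministic synthetic reference set with unambiguous segments.

    Segments are drawn independently at random and re-drawn until every
    pair within a segment class stays below ``max_pairwise_similarity``
    (length-adjusted local similarity), so best-hit assignment cannot be
    ambiguous.  Pure function of its arguments.
    """
    if n_v < 1 or n_j < 1:
        raise ValueError("need at least one V and one J gene")
    rng = np.random.default_rng(seed)
    params = AlignmentParams()

    def draw(n: int, length: int) -> list[str]:
        seqs: list[str] = []
        while len(seqs) < n:
            cand = _random_seq(rng, length)
            if all(sw_similarity(cand, s, params) < max_pairwise_similarity for s in seqs):
                seqs.append(cand)
        return seqs

    v = [
        GermlineGene(f"toyV{i + 1}", Segment.V, s)
        for i, s in enumerate(draw(n_v, v_length))
    ]
    j = [
        GermlineGene(f"toyJ{i + 1}", Segment.J, s)
        for i, s in enumerate(draw(n_j, j_length))
    ]
    return ReferenceSet(v_genes=tuple(v), j_genes=tuple(j))
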