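"""Synthetic IGH amplicon libraries with recorded ground truth.

The generator emulates the validation design of a clonality assay: a
dominant clonal V-junction-J recombinant planted at a configurable
fraction inside a polyclonal background of distinct recombinants, an
optional spike-in control sequence of known cell-equivalent content,
per-base substitution/insertion/deletion errors, platform-like read
lengths, and realistic Phred quality strings.  Every draw flows from the
config seed, and the exact multinomial label counts are recorded, so a
pipeline can be checked against the planted truth read-for-read.

Background clonotypes draw their V and J segments from the reference set
*excluding* the clone's own genes, mimicking a diverse repertoire in
which the malignant clone's exact rearrangement is unique; this is what
makes the planted clonal fraction exactly recoverable on error-free data
(a background read sharing the clone's V would align to it locally at
similarity 1.0).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .fastq_qc import SequencedRead, write_fastq
from .germline_refs import ReferenceSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedLibrary",
    "DilutionLibrary",
    "simulate_library",
    "simulate_dilution_series",
    "write_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# read-length profiles: (median, jitter sd); "amplicon" keeps the full
# recombinant untouched
LENGTH_PROFILES = {
    "amplicon": None,
    "short_300": (301, 8.0),
    "short_317": (317, 10.0),
    "long_476": (476, 25.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    n_reads: int
    refs: ReferenceSet
    clonal_fraction: float = 0.85
    clone_v: str = "auto"
    clone_j: str = "auto"
    n_background_clonotypes: int = 50
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    read_length_profile: str = "amplicon"
    spikein_fraction: float = 0.0
    spikein_cells: int = 100
    mean_quality: float = 30.0
    junction_min: int = 5
    junction_max: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.25:
                raise ValueError(f"{name} must be in [0, 0.25], got {rate}")
        if not 0.0 <= self.clonal_fraction <= 1.0:
            raise ValueError("clonal_fraction must be in [0, 1]")
        if not 0.0 <= self.spikein_fraction <= 1.0:
            raise ValueError("spikein_fraction must be in [0, 1]")
        if self.clonal_fraction + self.spikein_fraction > 1.0:
            raise ValueError("clonal_fraction + spikein_fraction must not exceed 1")
        if self.read_length_profile not in LENGTH_PROFILES:
            raise ValueError(
                f"unknown read_length_profile {self.read_length_profile!r}; "
                f"choose from {sorted(LENGTH_PROFILES)}"
            )
        if not 1 <= self.junction_min <= self.junction_max:
            raise ValueError("need 1 <= junction_min <= junction_max")


@dataclass(frozen=True)
class GroundTruth:
    clone_sequence: str
    spikein_sequence: str
    clone_v: str
    clone_j: str
    labels: tuple[str, ...]  # per emitted read: clone | background | spikein
    clone_count: int
    background_count: int
    spikein_count: int
    spikein_cells: int

    @property
    def n_reads(self) -> int:
        return self.clone_count + self.background_count + self.spikein_count

    @property
    def true_clonal_fraction(self) -> float:
        return self.clone_count / self.n_reads

    @property
    def true_clone_cells(self) -> float | None:
        """Cell-equivalents of the clone implied by the planted read ratio."""
        if self.spikein_count == 0:
            return None
        return self.spikein_cells * self.clone_count / self.spikein_count


@dataclass(frozen=True)
class SimulatedLibrary:
    reads: tuple[SequencedRead, ...]
    truth: GroundTruth


@dataclass(frozen=True)
class DilutionLibrary:
    dilution: float
    replicate: int
    library: SimulatedLibrary


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def _mutate(seq: str, sub: float, ins: float, dele: float, rng: np.random.Generator) -> str:
    """Apply per-base substitution/insertion/deletion errors."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = np.zeros(arr.shape[0], dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        codes[arr == b] = i
    if dele > 0:
        codes = codes[rng.random(codes.shape[0]) >= dele]
    if sub > 0 and codes.shape[0]:
        mask = rng.random(codes.shape[0]) < sub
        n_sub = int(mask.sum())
        if n_sub:
            # shift by 1..3 mod 4: always a *different* base
            codes[mask] = (codes[mask] + rng.integers(1, 4, size=n_sub)) % 4
    if ins > 0 and codes.shape[0]:
        mask = rng.random(codes.shape[0]) < ins
        pos = np.flatnonzero(mask)
        if pos.shape[0]:
            codes = np.insert(codes, pos + 1, rng.integers(0, 4, size=pos.shape[0]))
    return bytes(_BASES[codes]).decode("ascii")


def _apply_length_profile(seq: str, profile: str, rng: np.random.Generator) -> str:
    profile_params = LENGTH_PROFILES[profile]
    if profile_params is None:
        return seq
    median, sd = profile_params
    target = max(50, int(round(rng.normal(median, sd))))
    if target < len(seq):
        return seq[:target]
    if target > len(seq):
        # pad with adapter-like random flanks, split between the two ends
        pad = target - len(seq)
        left = int(rng.integers(0, pad + 1))
        return _random_seq(rng, left) + seq + _random_seq(rng, pad - left)
    return seq


def _quality_string(length: int, mean_quality: float, rng: np.random.Generator) -> np.ndarray:
    read_mean = mean_quality + float(np.clip(rng.normal(0.0, 1.5), -4.0, 4.0))
    quals = np.rint(rng.normal(read_mean, 3.0, size=length))
    return np.clip(quals, 2, 41).astype(np.int16)


def _recombine(
    rng: np.random.Generator,
    v_seq: str,
    j_seq: str,
    cfg: SimulationConfig,
) -> str:
    jlen = int(rng.integers(cfg.junction_min, cfg.junction_max + 1))
    return v_seq + _random_seq(rng, jlen) + j_seq


def simulate_library(cfg: SimulationConfig) -> SimulatedLibrary:
    """Generate one library, fully determined by ``cfg`` (incl. seed)."""
    rng = np.random.default_rng(cfg.seed)
    v_genes = list(cfg.refs.v_genes)
    j_genes = list(cfg.refs.j_genes)

    clone_v = (
        v_genes[int(rng.integers(0, len(v_genes)))]
        if cfg.clone_v == "auto"
        else cfg.refs.gene(cfg.clone_v)
    )
    clone_j = (
        j_genes[int(rng.integers(0, len(j_genes)))]
        if cfg.clone_j == "auto"
        else cfg.refs.gene(cfg.clone_j)
    )
    clone_seq = _recombine(rng, clone_v.sequence, clone_j.sequence, cfg)

    bg_v = [g for g in v_genes if g.gene_name != clone_v.gene_name] or v_genes
    bg_j = [g for g in j_genes if g.gene_name != clone_j.gene_name] or j_genes
    backgrounds: list[str] = []
    seen = {clone_seq}
    while len(backgrounds) < cfg.n_background_clonotypes:
        v = bg_v[int(rng.integers(0, len(bg_v)))]
        j = bg_j[int(rng.integers(0, len(bg_j)))]
        seq = _recombine(rng, v.sequence, j.sequence, cfg)
        if seq not in seen:
            seen.add(seq)
            backgrounds.append(seq)

    spikein_seq = _random_seq(rng, len(clone_seq))

    p_bg = max(0.0, 1.0 - cfg.clonal_fraction - cfg.spikein_fraction)
    counts = rng.multinomial(cfg.n_reads, [cfg.clonal_fraction, cfg.spikein_fraction, p_bg])
    n_clone, n_spike, n_bg = (int(c) for c in counts)
    if n_bg > 0 and not backgrounds:
        raise ValueError(
            "background reads requested but n_background_clonotypes is 0"
        )

    templates = (
        [clone_seq] * n_clone
        + [spikein_seq] * n_spike
        + [backgrounds[i] for i in rng.integers(0, max(1, len(backgrounds)), size=n_bg)]
    )
    labels = ["clone"] * n_clone + ["spikein"] * n_spike + ["background"] * n_bg
    order = rng.permutation(cfg.n_reads)

    has_errors = cfg.sub_rate > 0 or cfg.ins_rate > 0 or cfg.del_rate > 0
    reads = []
    out_labels = []
    for k, idx in enumerate(order):
        seq = templates[idx]
        if has_errors:
            seq = _mutate(seq, cfg.sub_rate, cfg.ins_rate, cfg.del_rate, rng)
        seq = _apply_length_profile(seq, cfg.read_length_profile, rng)
        quals = _quality_string(len(seq), cfg.mean_quality, rng)
        reads.append(
            SequencedRead(read_id=f"sim_{k}_{labels[idx]}", bases=seq, quals=quals)
        )
        out_labels.append(labels[idx])

    truth = GroundTruth(
        clone_sequence=clone_seq,
        spikein_sequence=spikein_seq,
        clone_v=clone_v.gene_name,
        clone_j=clone_j.gene_name,
        labels=tuple(out_labels),
        clone_count=n_clone,
        background_count=n_bg,
        spikein_count=n_spike,
        spikein_cells=cfg.spikein_cells,
    )
    return SimulatedLibrary(reads=tuple(reads), truth=truth)


def simulate_dilution_series(
    base_cfg: SimulationConfig,
    dilutions: Sequence[float],
    replicates: int,
    seed: int,
) -> list[DilutionLibrary]:
    """One library per (dilution, replicate): the base clonal fraction is
    scaled by each dilution factor; seeds derive from the master seed."""
    for d in dilutions:
        if not 0.0 < d <= 1.0:
            raise ValueError(f"dilution must be in (0, 1], got {d}")
    rng = np.random.default_rng(seed)
    out = []
    for dilution in dilutions:
        for rep in range(replicates):
            child_seed = int(rng.integers(0, 2**31 - 1))
            cfg = dataclasses.replace(
                base_cfg,
                clonal_fraction=base_cfg.clonal_fraction * dilution,
                seed=child_seed,
            )
            out.append(
                DilutionLibrary(dilution=dilution, replicate=rep, library=simulate_library(cfg))
            )
    return out


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Key-value header plus one label row per read."""
    with open(path, "wt") as out:
        out.write("# swigh simulated ground truth\n")
        out.write(f"clone_sequence\t{truth.clone_sequence}\n")
        out.write(f"spikein_sequence\t{truth.spikein_sequence}\n")
        out.write(f"clone_v\t{truth.clone_v}\n")
        out.write(f"clone_j\t{truth.clone_j}\n")
        out.write(f"clone_count\t{truth.clone_count}\n")
        out.write(f"background_count\t{truth.background_count}\n")
        out.write(f"spikein_count\t{truth.spikein_count}\n")
        out.write(f"spikein_cells\t{truth.spikein_cells}\n")
        out.write("# read_index\tlabel\n")
        for i, label in enumerate(truth.labels):
            out.write(f"{i}\t{label}\n")


def write_library(lib: SimulatedLibrary, fastq_path: str | Path, truth_path: str | Path) -> None:
    write_fastq(lib.reads, fastq_path)
    write_truth(lib.truth, truth_path)
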