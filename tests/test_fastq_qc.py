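"""FASTQ parsing and the two quality-filter modes."""

import gzip
import math

import numpy as np
import pytest
from oracle import naive_mean_ok

from swigh import (
    QualityFilterConfig,
    QualityMode,
    SequencedRead,
    SimulationConfig,
    mean_quality,
    parse_fastq,
    quality_filter,
    simulate_library,
    write_fastq,
)
from swigh.fastq_qc import FastqParseError, write_filter_stats


def _read(bases, quals, read_id="r"):
    return SequencedRead(read_id=read_id, bases=bases, quals=np.asarray(quals))


class TestParsing:
    def test_phred33_decoding(self, tmp_path):
        p = tmp_path / "a.fastq"
        p.write_text("@r1\nACGT\n+\nIIII\n")
        reads = list(parse_fastq(p))
        assert len(reads) == 1
        assert reads[0].bases == "ACGT"
        assert list(reads[0].quals) == [40, 40, 40, 40]

    def test_empty_file_is_empty_stream(self, tmp_path):
        p = tmp_path / "empty.fastq"
        p.write_text("")
        assert list(parse_fastq(p)) == []

    def test_lowercase_bases_uppercased(self, tmp_path):
        p = tmp_path / "a.fastq"
        p.write_text("@r1\nacgt\n+\nIIII\n")
        assert next(iter(parse_fastq(p))).bases == "ACGT"

    def test_quality_length_mismatch_names_record(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\nII\n")
        with pytest.raises(FastqParseError, match="record 1"):
            list(parse_fastq(p))

    def test_missing_at_line_rejected(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("r1\nACGT\n+\nIIII\n")
        with pytest.raises(FastqParseError):
            list(parse_fastq(p))

    def test_sub_phred33_character_rejected(self, tmp_path):
        # a space (ASCII 32) is below '!': cannot be Phred+33
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\nII I\n")
        with pytest.raises(FastqParseError):
            list(parse_fastq(p))

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "a.fastq.gz"
        with gzip.open(p, "wt") as out:
            out.write("@r1\nACGT\n+\nIIII\n")
        reads = list(parse_fastq(p))
        assert reads[0].bases == "ACGT"

    def test_write_parse_round_trip(self, tmp_path):
        reads = [_read("ACGTN", [10, 20, 30, 40, 2], "x"), _read("GG", [5, 6], "y")]
        p = tmp_path / "rt.fastq"
        assert write_fastq(reads, p) == 2
        back = list(parse_fastq(p))
        assert [(r.read_id, r.bases, list(r.quals)) for r in back] == [
            (r.read_id, r.bases, list(r.quals)) for r in reads
        ]

    def test_length_mismatch_at_construction(self):
        with pytest.raises(ValueError):
            _read("ACGT", [1, 2])


class TestMeanQuality:
    def test_constant_q20_both_modes(self):
        read = _read("A" * 10, [20] * 10)
        assert mean_quality(read, QualityMode.naive_mean) == 20.0
        # Q20 corresponds to exactly 1% error probability
        assert mean_quality(read, QualityMode.error_prob_mean) == pytest.approx(20.0)

    def test_mixed_qualities_closed_form(self):
        read = _read("ACG", [10, 20, 30])
        assert mean_quality(read, QualityMode.naive_mean) == pytest.approx(20.0)
        expected = -10 * math.log10((0.1 + 0.01 + 0.001) / 3)
        assert mean_quality(read, QualityMode.error_prob_mean) == pytest.approx(expected)
        assert expected == pytest.approx(14.31, abs=0.01)

    def test_errprob_mean_never_exceeds_naive_mean(self, rng):
        # Jensen's inequality on the convex map q -> 10^(-q/10)
        for _ in range(1000):
            n = int(rng.integers(1, 50))
            read = _read("A" * n, rng.integers(2, 42, size=n))
            naive = mean_quality(read, QualityMode.naive_mean)
            errp = mean_quality(read, QualityMode.error_prob_mean)
            assert errp <= naive + 1e-9

    def test_constant_quality_identical_in_both_modes(self, rng):
        for q in (2, 15, 33, 41):
            read = _read("ACGT", [q] * 4)
            assert mean_quality(read, QualityMode.naive_mean) == pytest.approx(q)
            assert mean_quality(read, QualityMode.error_prob_mean) == pytest.approx(q)

    def test_empty_read_undefined(self):
        with pytest.raises(ValueError):
            mean_quality(_read("", []))


class TestQualityFilter:
    def test_all_pass_defaults(self):
        reads = [_read("A" * 300, [30] * 300, f"r{i}") for i in range(10)]
        passed, stats = quality_filter(reads)
        assert len(passed) == 10
        assert stats.input == stats.passed == 10

    def test_short_read_fails_length(self):
        passed, stats = quality_filter([_read("A" * 150, [40] * 150)])
        assert passed == []
        assert stats.failed_length == 1

    def test_zero_thresholds_pass_everything(self):
        cfg = QualityFilterConfig(min_length=0, min_mean_quality=0)
        reads = [_read("A", [2]), _read("ACGT" * 100, [2] * 400)]
        passed, stats = quality_filter(reads, cfg)
        assert len(passed) == 2 and stats.failed == 0

    def test_conservation_and_order(self, rng):
        reads = []
        for i in range(200):
            n = int(rng.integers(50, 400))
            reads.append(_read("A" * n, rng.integers(5, 40, size=n), f"r{i}"))
        passed, stats = quality_filter(reads)
        assert stats.input == stats.passed + stats.failed == 200
        ids = [r.read_id for r in reads]
        assert [r.read_id for r in passed] == [i for i in ids if i in {r.read_id for r in passed}]

    @pytest.mark.parametrize("mode", list(QualityMode))
    def test_filter_matches_brute_force_oracle(self, mode, toy_refs):
        lib = simulate_library(
            SimulationConfig(
                n_reads=800, refs=toy_refs, clonal_fraction=0.5, mean_quality=21.0, seed=5
            )
        )
        cfg = QualityFilterConfig(min_length=200, min_mean_quality=20.0, mode=mode)
        passed, stats = quality_filter(lib.reads, cfg)
        errprob = mode is QualityMode.error_prob_mean
        expected = sum(
            naive_mean_ok(r.bases, r.quals, 200, 20.0, errprob) for r in lib.reads
        )
        assert stats.passed == len(passed) == expected
        assert 0 < expected  # the fixture straddles the threshold meaningfully

    def test_idempotent(self, toy_refs):
        lib = simulate_library(
            SimulationConfig(
                n_reads=300, refs=toy_refs, clonal_fraction=0.5, mean_quality=21.0, seed=6
            )
        )
        passed, _ = quality_filter(lib.reads)
        again, stats = quality_filter(passed)
        assert again == passed
        assert stats.failed == 0

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            QualityFilterConfig(min_length=-1)

    def test_stats_tsv(self, tmp_path):
        passed, stats = quality_filter([_read("A" * 300, [30] * 300)])
        out = tmp_path / "stats.tsv"
        write_filter_stats(stats, QualityFilterConfig(), out)
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        parsed = {l.split("\t")[0]: l.split("\t")[1:] for l in lines}
        assert parsed["passed_reads"] == ["1", "naive_mean"]
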