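import gzip
import itertools
import random

import pytest

from conftest import PLETH_F, PLETH_R
from taggimatrix.demux import (
    AMBIGUOUS,
    NO_TAG,
    UNEXPECTED,
    DemuxOptions,
    ReadPair,
    SampleSheet,
    demux_pair,
    match_tag,
    open_maybe_gzip,
    read_fastq_pairs,
    run_demux,
    trim_locus_primer,
)
from taggimatrix.index_kit import IndexTag


def _pair(r1, r2, read_id="r1"):
    return ReadPair(read_id, r1, "F" * len(r1), r2, "F" * len(r2))


class TestMatchTag:
    def test_exact_match(self, default_set):
        m = match_tag("GGTAC" + PLETH_F, default_set.forward_tags)
        assert (m.label, m.distance) == ("A", 0)

    def test_single_substitution_corrected(self, default_set):
        # GGTAC -> GGAAC, one substitution in tag A
        m = match_tag("GGAAC" + PLETH_F, default_set.forward_tags, max_dist=1)
        assert (m.label, m.distance) == ("A", 1)

    def test_garbage_prefix_unmatched(self, default_set):
        m = match_tag("T" * 30, default_set.forward_tags, max_dist=1)
        assert m.label is None and m.status == "no_tag"

    def test_read_shorter_than_all_candidates(self, default_set):
        m = match_tag("GGT", default_set.forward_tags)
        assert m.status == "no_tag"

    def test_tie_is_ambiguous(self):
        candidates = [
            IndexTag("X", "", "AAAAA", "forward", 1),
            IndexTag("Y", "", "AAAAT", "forward", 1),
        ]
        m = match_tag("AAAAC" + "G" * 10, candidates, max_dist=1)
        assert m.label is None and m.status == "ambiguous"

    def test_zero_tolerance_rejects_single_error(self, default_set):
        m = match_tag("GGAAC" + PLETH_F, default_set.forward_tags, max_dist=0)
        assert m.status == "no_tag"

    def test_no_single_substitution_reaches_wrong_tag(self, default_set):
        """Exhaustively mutate every base of every tag in its read context:
        the matcher must never return a different tag. Because the true tag
        stays within distance 1, the outcome is either a correction or — when
        a longer candidate's window (which spills into primer bases) ties at
        the same distance — a safe ambiguity, never a wrong label and never
        a silent drop."""
        n_ambiguous = n_total = 0
        for role, pool, primer in (
            ("forward", default_set.forward_tags, PLETH_F),
            ("reverse", default_set.reverse_tags, PLETH_R),
        ):
            for tag in pool:
                context = tag.full_sequence + primer
                for pos, alt in itertools.product(
                    range(len(tag.full_sequence)), "ACGT"
                ):
                    if context[pos] == alt:
                        continue
                    mutated = context[:pos] + alt + context[pos + 1:]
                    m = match_tag(mutated, pool, max_dist=1)
                    n_total += 1
                    assert m.status in ("matched", "ambiguous"), (role, tag.label, pos, alt)
                    assert m.label in (tag.label, None), (role, tag.label, pos, alt)
                    n_ambiguous += m.status == "ambiguous"
        # cross-length ties are a rare edge of the variable-length design
        assert n_ambiguous < 0.05 * n_total


class TestTrimLocusPrimer:
    def test_iupac_degenerate_match(self):
        seq = "GTGCCAGCAGCCGCGGTAA" + "TTTT"
        trimmed, _, ok = trim_locus_primer(seq, "GTGCCAGCMGCCGCGGTAA")
        assert ok and trimmed == "TTTT"

    def test_unrelated_sequence_unchanged(self):
        seq = "C" * 30
        trimmed, _, ok = trim_locus_primer(seq, "GTGCCAGCMGCCGCGGTAA")
        assert not ok and trimmed == seq

    def test_one_mismatch_within_tolerance(self):
        primer = "GTGCCAGCMGCCGCGGTAA"
        seq = "TTGCCAGCAGCCGCGGTAA" + "AAAA"  # one mismatch at position 0
        trimmed, qual, ok = trim_locus_primer(seq, primer, max_mismatch=2, quality="F" * len(seq))
        assert ok and trimmed == "AAAA" and qual == "FFFF"

    def test_empty_primer_rejected(self):
        with pytest.raises(ValueError):
            trim_locus_primer("ACGT", "")


class TestDemuxPair:
    def test_assignment_and_trimming(self, full_plate_sheet):
        pair = _pair("GGTAC" + PLETH_F + "C" * 20, "AGGAA" + PLETH_R + "G" * 20)
        assignment, trimmed = demux_pair(pair, full_plate_sheet)
        assert assignment.category == "S_A1"
        assert trimmed.r1_sequence == PLETH_F + "C" * 20
        assert trimmed.r2_sequence == PLETH_R + "G" * 20
        assert len(trimmed.r1_quality) == len(trimmed.r1_sequence)

    def test_variable_length_tag_trimmed_fully(self, full_plate_sheet):
        # forward D: tcg+GTCAA (8 nt); reverse 4: ttc+TCAGC (8 nt)
        pair = _pair("TCGGTCAA" + PLETH_F + "C" * 20, "TTCTCAGC" + PLETH_R + "G" * 20)
        assignment, trimmed = demux_pair(pair, full_plate_sheet)
        assert assignment.category == "S_D4"
        assert trimmed.r1_sequence.startswith(PLETH_F)
        assert trimmed.r2_sequence.startswith(PLETH_R)

    def test_unexpected_combination_flagged(self, diagonal_sheet):
        # tags (A, 2): both known, pair not on the diagonal sheet
        pair = _pair("GGTAC" + PLETH_F + "C" * 20, "GAGTGG" + PLETH_R + "G" * 20)
        assignment, _ = demux_pair(pair, diagonal_sheet)
        assert assignment.category == UNEXPECTED
        assert (assignment.fwd_tag, assignment.rev_tag) == ("A", "2")

    def test_single_error_in_each_tag_still_assigned(self, full_plate_sheet):
        pair = _pair("GGAAC" + PLETH_F + "C" * 20, "ACGAA" + PLETH_R + "G" * 20)
        assignment, _ = demux_pair(pair, full_plate_sheet, DemuxOptions(max_dist=1))
        assert assignment.category == "S_A1"
        assert assignment.fwd_distance == 1 and assignment.rev_distance == 1

    def test_primer_trimming_option(self, full_plate_sheet):
        pair = _pair("GGTAC" + PLETH_F + "C" * 20, "AGGAA" + PLETH_R + "G" * 20)
        _, trimmed = demux_pair(
            pair, full_plate_sheet, DemuxOptions(trim_primers=True)
        )
        assert trimmed.r1_sequence == "C" * 20
        assert trimmed.r2_sequence == "G" * 20


class TestSampleSheet:
    def test_csv_loading(self, tmp_path, default_set):
        path = tmp_path / "sheet.csv"
        path.write_text(
            "sample_id,fwd_tag,rev_tag,i5,i7\nS1,A,1,iTru5_01,iTru7_01\nS2,B,2,,\n"
        )
        sheet = SampleSheet.from_csv(path, default_set)
        assert sheet.entries == {("A", "1"): "S1", ("B", "2"): "S2"}
        assert sheet.outer == {("A", "1"): ("iTru5_01", "iTru7_01")}

    def test_unknown_tag_label_rejected(self, default_set):
        with pytest.raises(ValueError, match="unknown forward tag"):
            SampleSheet({("Z", "1"): "S1"}, default_set)

    def test_duplicate_sample_ids_rejected(self, default_set):
        with pytest.raises(ValueError, match="unique"):
            SampleSheet({("A", "1"): "S1", ("A", "2"): "S1"}, default_set)


def _write_fastq(path, records, gz=False):
    opener = gzip.open if gz else open
    with opener(path, "wt") as handle:
        for rid, seq in records:
            handle.write(f"@{rid}\n{seq}\n+\n{'F' * len(seq)}\n")


class TestRunDemux:
    def test_empty_inputs(self, tmp_path, full_plate_sheet):
        r1, r2 = tmp_path / "e1.fastq", tmp_path / "e2.fastq"
        r1.write_text("")
        r2.write_text("")
        stats = run_demux(r1, r2, full_plate_sheet, tmp_path / "out")
        assert stats.total == 0 and stats.conserved()

    def test_gzip_detected_by_magic_bytes(self, tmp_path, full_plate_sheet):
        # gzipped content behind a non-.gz name must still be readable
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        _write_fastq(r1, [("p1", "GGTAC" + PLETH_F + "C" * 30)], gz=True)
        _write_fastq(r2, [("p1", "AGGAA" + PLETH_R + "G" * 30)], gz=True)
        stats = run_demux(r1, r2, full_plate_sheet, tmp_path / "out")
        assert stats.per_sample == {"S_A1": 1}

    def test_mate_desynchronization_fatal(self, tmp_path, full_plate_sheet):
        r1, r2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        _write_fastq(r1, [("x", "A" * 40)])
        _write_fastq(r2, [("y", "A" * 40)])
        with pytest.raises(ValueError, match="desynchronization"):
            run_demux(r1, r2, full_plate_sheet, tmp_path / "out")

    def test_conservation_under_fuzz(self, tmp_path, full_plate_sheet, default_set):
        """Every input pair lands in exactly one output category."""
        rng = random.Random(99)
        records1, records2 = [], []
        for i in range(300):
            kind = rng.random()
            rid = f"fz{i}"
            if kind < 0.4:  # valid pair with random tags
                ft = rng.choice(default_set.forward_tags)
                rt = rng.choice(default_set.reverse_tags)
                records1.append((rid, ft.full_sequence + PLETH_F + "C" * 20))
                records2.append((rid, rt.full_sequence + PLETH_R + "G" * 20))
            else:  # random garbage of random length
                n1, n2 = rng.randint(0, 60), rng.randint(0, 60)
                records1.append((rid, "".join(rng.choice("ACGT") for _ in range(n1))))
                records2.append((rid, "".join(rng.choice("ACGT") for _ in range(n2))))
        r1, r2 = tmp_path / "fz1.fastq", tmp_path / "fz2.fastq"
        _write_fastq(r1, records1)
        _write_fastq(r2, records2)
        out = tmp_path / "out"
        stats = run_demux(r1, r2, full_plate_sheet, out, gzip_output=False)
        assert stats.total == 300
        assert stats.conserved()
        written = sum(
            sum(1 for line in path.open() if line.startswith("@"))
            for path in out.glob("*_R1.fastq")
        )
        assert written == 300

    def test_order_invariance(self, tmp_path, full_plate_sheet, default_set):
        rng = random.Random(5)
        records = []
        for i in range(50):
            ft = rng.choice(default_set.forward_tags)
            rt = rng.choice(default_set.reverse_tags)
            records.append(
                (f"o{i}", ft.full_sequence + PLETH_F + "C" * 10,
                 rt.full_sequence + PLETH_R + "G" * 10)
            )
        stats = []
        for tag, order in (("fwd", records), ("rev", records[::-1])):
            r1, r2 = tmp_path / f"{tag}1.fastq", tmp_path / f"{tag}2.fastq"
            _write_fastq(r1, [(r[0], r[1]) for r in order])
            _write_fastq(r2, [(r[0], r[2]) for r in order])
            stats.append(run_demux(r1, r2, full_plate_sheet, tmp_path / f"out_{tag}"))
        assert stats[0].per_sample == stats[1].per_sample
        assert stats[0].per_category == stats[1].per_category

    def test_outer_index_filtering(self, tmp_path, default_set):
        sheet = SampleSheet(
            {("A", "1"): "S1"}, default_set,
            outer={("A", "1"): ("iTru5_01", "iTru7_01")},
            forward_primer=PLETH_F, reverse_primer=PLETH_R,
        )
        r1, r2 = tmp_path / "o1.fastq", tmp_path / "o2.fastq"
        seq1 = "GGTAC" + PLETH_F + "C" * 20
        seq2 = "AGGAA" + PLETH_R + "G" * 20
        r1.write_text(
            f"@p1 i5=iTru5_01 i7=iTru7_01\n{seq1}\n+\n{'F'*len(seq1)}\n"
            f"@p2 i5=iTru5_99 i7=iTru7_99\n{seq1}\n+\n{'F'*len(seq1)}\n"
        )
        r2.write_text(
            f"@p1 i5=iTru5_01 i7=iTru7_01\n{seq2}\n+\n{'F'*len(seq2)}\n"
            f"@p2 i5=iTru5_99 i7=iTru7_99\n{seq2}\n+\n{'F'*len(seq2)}\n"
        )
        stats = run_demux(r1, r2, sheet, tmp_path / "out",
                          DemuxOptions(require_outer=True))
        assert stats.per_sample == {"S1": 1}
        assert stats.per_category[UNEXPECTED] == 1
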