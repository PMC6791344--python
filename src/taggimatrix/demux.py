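"""Demultiplex paired-end reads by their internal variable-length tags.

After the sequencing facility has split reads on the outer i5/i7 indexes,
each mate of a pair still begins with an inline identifier: a 0-3 nt
heterogeneity spacer followed by a 5 nt index, then the locus-specific
primer. This module assigns read pairs to samples from the (forward tag,
reverse tag) combination, trims the tag (and optionally the primer) off both
mates, writes per-sample FASTQ, and reports statistics — including
"tag jumps": reads whose two tags both match known tags but in a combination
never assigned to any sample (e.g., PCR chimeras).

Matching is by Hamming distance on fixed-length prefixes, each candidate
compared at its own spacer+index length. Because every pair of tags in a
valid set is at edit distance >= 3, one substitution can never move a read
within distance 1 of the wrong tag, so the default tolerance of one
mismatch corrects single errors without risking misassignment; ties between
candidates at the minimum distance are deliberately left ambiguous rather
than guessed.
"""

from __future__ import annotations

import csv
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .index_kit import IndexSet, IndexTag, load_default_set
from .primer_forge import IUPAC_CODES

__all__ = [
    "SampleSheet",
    "ReadPair",
    "TagMatch",
    "Assignment",
    "DemuxStats",
    "DemuxOptions",
    "match_tag",
    "demux_pair",
    "run_demux",
    "trim_locus_primer",
    "open_maybe_gzip",
    "read_fastq_pairs",
]

NO_TAG = "unassigned_no_tag"
AMBIGUOUS = "unassigned_ambiguous"
UNEXPECTED = "unexpected_combination"
CATEGORIES = (NO_TAG, AMBIGUOUS, UNEXPECTED)


@dataclass
class SampleSheet:
    """Mapping from (forward tag label, reverse tag label) to sample ID.

    ``outer`` optionally records the expected (i5, i7) labels per tag pair;
    when present and outer filtering is enabled, reads whose FASTQ header
    comment carries different labels are rejected.
    """

    entries: dict[tuple[str, str], str]
    index_set: IndexSet
    outer: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    forward_primer: str | None = None
    reverse_primer: str | None = None

    def __post_init__(self) -> None:
        samples = list(self.entries.values())
        if len(samples) != len(set(samples)):
            raise ValueError("sample IDs must be unique")
        fwd_labels = {t.label for t in self.index_set.forward_tags}
        rev_labels = {t.label for t in self.index_set.reverse_tags}
        for fwd, rev in self.entries:
            if fwd not in fwd_labels:
                raise ValueError(f"unknown forward tag label {fwd!r} in samplesheet")
            if rev not in rev_labels:
                raise ValueError(f"unknown reverse tag label {rev!r} in samplesheet")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        index_set: IndexSet | None = None,
        forward_primer: str | None = None,
        reverse_primer: str | None = None,
    ) -> "SampleSheet":
        """Load a samplesheet CSV with columns sample_id, fwd_tag, rev_tag[, i5, i7]."""
        index_set = index_set or load_default_set()
        entries: dict[tuple[str, str], str] = {}
        outer: dict[tuple[str, str], tuple[str, str]] = {}
        with Path(path).open(newline="") as handle:
            sniff = handle.read(4096)
            handle.seek(0)
            delim = "\t" if "\t" in sniff.splitlines()[0] else ","
            for row in csv.DictReader(handle, delimiter=delim):
                key = (row["fwd_tag"].strip(), row["rev_tag"].strip())
                if key in entries:
                    raise ValueError(f"duplicate tag pair {key} in samplesheet")
                entries[key] = row["sample_id"].strip()
                if row.get("i5") and row.get("i7"):
                    outer[key] = (row["i5"].strip(), row["i7"].strip())
        return cls(entries, index_set, outer, forward_primer, reverse_primer)


class ReadPair(NamedTuple):
    id: str
    r1_sequence: str
    r1_quality: str
    r2_sequence: str
    r2_quality: str


class TagMatch(NamedTuple):
    """Result of matching one read prefix against a candidate tag list.

    ``label`` is None when no candidate qualifies; ``status`` then says
    whether nothing was close enough ("no_tag") or several candidates tied
    ("ambiguous").
    """

    label: str | None
    distance: int | None
    status: str  # "matched" | "no_tag" | "ambiguous"


@dataclass
class Assignment:
    category: str  # sample ID or one of CATEGORIES
    fwd_tag: str | None = None
    rev_tag: str | None = None
    fwd_distance: int | None = None
    rev_distance: int | None = None

    @property
    def is_sample(self) -> bool:
        return self.category not in CATEGORIES


@dataclass
class DemuxStats:
    total: int = 0
    per_sample: dict[str, int] = field(default_factory=dict)
    per_category: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})
    tag_pair_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    malformed: int = 0

    def record(self, assignment: Assignment) -> None:
        self.total += 1
        if assignment.is_sample:
            self.per_sample[assignment.category] = (
                self.per_sample.get(assignment.category, 0) + 1
            )
        else:
            self.per_category[assignment.category] += 1
        if assignment.fwd_tag and assignment.rev_tag:
            key = (assignment.fwd_tag, assignment.rev_tag)
            self.tag_pair_counts[key] = self.tag_pair_counts.get(key, 0) + 1

    @property
    def assigned(self) -> int:
        return sum(self.per_sample.values())

    def conserved(self) -> bool:
        return self.assigned + sum(self.per_category.values()) == self.total

    def to_json(self) -> str:
        return json.dumps(
            {
                "total": self.total,
                "assigned": self.assigned,
                "malformed": self.malformed,
                "per_sample": dict(sorted(self.per_sample.items())),
                "per_category": self.per_category,
                "tag_pair_counts": {
                    f"{f}:{r}": n for (f, r), n in sorted(self.tag_pair_counts.items())
                },
            },
            indent=2,
        )


@dataclass
class DemuxOptions:
    max_dist: int = 1
    trim_primers: bool = False
    primer_max_mismatch: int = 2
    min_len: int = 0
    require_outer: bool = False


def match_tag(
    read_prefix: str, candidates: Iterable[IndexTag], max_dist: int = 1
) -> TagMatch:
    """Match a read's 5' prefix against candidate tags by Hamming distance.

    Each candidate is compared at its own full-sequence (spacer+index)
    length, so variable-length sets need no spacer-length guessing. The
    unique candidate at minimum distance <= ``max_dist`` wins; a tie at the
    minimum — including ties across different lengths — is ambiguous.
    """
    best: list[str] = []
    best_dist: int | None = None
    read_prefix = read_prefix.upper()
    any_comparable = False
    for tag in candidates:
        full = tag.full_sequence
        if len(read_prefix) < len(full):
            continue
        any_comparable = True
        dist = sum(1 for a, b in zip(full, read_prefix) if a != b)
        if dist > max_dist:
            continue
        if best_dist is None or dist < best_dist:
            best, best_dist = [tag.label], dist
        elif dist == best_dist:
            best.append(tag.label)
    if not any_comparable:
        return TagMatch(None, None, "no_tag")
    if best_dist is None:
        return TagMatch(None, None, "no_tag")
    if len(best) > 1:
        return TagMatch(None, best_dist, "ambiguous")
    return TagMatch(best[0], best_dist, "matched")


def _expand(code: str) -> frozenset[str]:
    return IUPAC_CODES.get(code.upper(), frozenset())


def trim_locus_primer(
    sequence: str, primer: str, max_mismatch: int = 2, quality: str | None = None
) -> tuple[str, str | None, bool]:
    """Strip a locus primer from the 5' end if it matches within tolerance.

    The primer may contain IUPAC degeneracy codes; a read base matches when
    it is among the code's allowed bases. Returns (sequence, quality,
    trimmed?); on no match the inputs come back unchanged with a False flag.
    """
    if not primer:
        raise ValueError("primer must be non-empty")
    if len(sequence) < len(primer):
        return sequence, quality, False
    mismatches = sum(
        1
        for p, b in zip(primer.upper(), sequence[: len(primer)].upper())
        if b not in _expand(p)
    )
    if mismatches <= max_mismatch:
        n = len(primer)
        return sequence[n:], (quality[n:] if quality is not None else None), True
    return sequence, quality, False


def demux_pair(
    pair: ReadPair, sheet: SampleSheet, options: DemuxOptions | None = None,
    outer_labels: tuple[str, str] | None = None,
) -> tuple[Assignment, ReadPair]:
    """Assign one read pair and trim the identifying bases off both mates.

    R1 is matched against forward tags, R2 against reverse tags. Both
    matched and the pair on the sheet -> sample; both matched but the pair
    absent -> unexpected combination (a candidate tag jump); otherwise the
    read is unassigned (no tag / ambiguous, with no-tag taking precedence).
    Quality strings are trimmed in lockstep with the sequences.
    """
    options = options or DemuxOptions()
    fwd = match_tag(pair.r1_sequence, sheet.index_set.forward_tags, options.max_dist)
    rev = match_tag(pair.r2_sequence, sheet.index_set.reverse_tags, options.max_dist)

    if fwd.status == "no_tag" or rev.status == "no_tag":
        return Assignment(NO_TAG, fwd.label, rev.label, fwd.distance, rev.distance), pair
    if fwd.status == "ambiguous" or rev.status == "ambiguous":
        return Assignment(AMBIGUOUS, fwd.label, rev.label, fwd.distance, rev.distance), pair

    key = (fwd.label, rev.label)
    assignment = Assignment(
        sheet.entries.get(key, UNEXPECTED), fwd.label, rev.label, fwd.distance, rev.distance
    )
    if assignment.is_sample and options.require_outer and key in sheet.outer:
        if outer_labels != sheet.outer[key]:
            assignment = Assignment(UNEXPECTED, fwd.label, rev.label, fwd.distance, rev.distance)
    if not assignment.is_sample:
        return assignment, pair

    n1 = len(sheet.index_set.tag("forward", fwd.label))
    n2 = len(sheet.index_set.tag("reverse", rev.label))
    r1_seq, r1_q = pair.r1_sequence[n1:], pair.r1_quality[n1:]
    r2_seq, r2_q = pair.r2_sequence[n2:], pair.r2_quality[n2:]
    if options.trim_primers:
        if sheet.forward_primer:
            r1_seq, r1_q, _ = trim_locus_primer(
                r1_seq, sheet.forward_primer, options.primer_max_mismatch, r1_q
            )
        if sheet.reverse_primer:
            r2_seq, r2_q, _ = trim_locus_primer(
                r2_seq, sheet.reverse_primer, options.primer_max_mismatch, r2_q
            )
    return assignment, ReadPair(pair.id, r1_seq, r1_q, r2_seq, r2_q)


# ---------------------------------------------------------------------------
# FASTQ streaming


def open_maybe_gzip(path: str | Path, mode: str = "rt") -> TextIO:
    """Open plain or gzip text transparently, sniffing the gzip magic bytes."""
    path = Path(path)
    if "r" in mode:
        with path.open("rb") as probe:
            magic = probe.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)  # type: ignore[return-value]
        return path.open(mode)
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)  # type: ignore[return-value]
    return path.open(mode)


def _core_id(header: str) -> str:
    head = header.split(None, 1)[0]
    return head[:-2] if head.endswith(("/1", "/2")) else head


def _outer_from_header(header: str) -> tuple[str, str] | None:
    i5 = i7 = None
    for token in header.split()[1:]:
        if token.startswith("i5="):
            i5 = token[3:]
        elif token.startswith("i7="):
            i7 = token[3:]
    return (i5, i7) if i5 is not None and i7 is not None else None


def read_fastq_pairs(
    fastq_r1: str | Path, fastq_r2: str | Path
) -> Iterator[tuple[ReadPair, tuple[str, str] | None]]:
    """Stream mate pairs in lockstep, yielding (pair, outer i5/i7 labels)."""
    with open_maybe_gzip(fastq_r1) as h1, open_maybe_gzip(fastq_r2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2):
            id1, id2 = _core_id(t1), _core_id(t2)
            if id1 != id2:
                raise ValueError(f"mate desynchronization at records {id1!r} vs {id2!r}")
            yield ReadPair(id1, s1, q1, s2, q2), _outer_from_header(t1)
        for leftover in (it1, it2):
            try:
                next(leftover)
            except StopIteration:
                continue
            raise ValueError("mate files have unequal record counts")


class _FastqWriter:
    """Lazily opened per-sample FASTQ pair writers."""

    def __init__(self, out_dir: Path, gzip_output: bool = True):
        self.out_dir = out_dir
        self.suffix = ".fastq.gz" if gzip_output else ".fastq"
        self._handles: dict[str, tuple[TextIO, TextIO]] = {}

    def _open(self, stem: str) -> tuple[TextIO, TextIO]:
        if stem not in self._handles:
            r1 = open_maybe_gzip(self.out_dir / f"{stem}_R1{self.suffix}", "wt")
            r2 = open_maybe_gzip(self.out_dir / f"{stem}_R2{self.suffix}", "wt")
            self._handles[stem] = (r1, r2)
        return self._handles[stem]

    def write(self, stem: str, pair: ReadPair) -> None:
        h1, h2 = self._open(stem)
        h1.write(f"@{pair.id}\n{pair.r1_sequence}\n+\n{pair.r1_quality}\n")
        h2.write(f"@{pair.id}\n{pair.r2_sequence}\n+\n{pair.r2_quality}\n")

    def close(self) -> None:
        for h1, h2 in self._handles.values():
            h1.close()
            h2.close()


def run_demux(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    sheet: SampleSheet,
    out_dir: str | Path,
    options: DemuxOptions | None = None,
    gzip_output: bool = True,
) -> DemuxStats:
    """Stream all pairs through :func:`demux_pair` and write outputs.

    Writes one FASTQ pair per sample plus ``unassigned_*`` files for every
    category (unassigned reads are preserved untrimmed, never dropped), a
    per-sample TSV and a JSON report including the observed tag-pair matrix.
    Every input pair lands in exactly one output pair of files.
    """
    options = options or DemuxOptions()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stats = DemuxStats()
    writer = _FastqWriter(out_dir, gzip_output=gzip_output)
    try:
        for pair, outer in read_fastq_pairs(fastq_r1, fastq_r2):
            if len(pair.r1_sequence) != len(pair.r1_quality) or len(
                pair.r2_sequence
            ) != len(pair.r2_quality):
                stats.malformed += 1
                stats.total += 1
                stats.per_category.setdefault(NO_TAG, 0)
                stats.per_category[NO_TAG] += 1
                writer.write(NO_TAG, pair)
                continue
            assignment, trimmed = demux_pair(pair, sheet, options, outer)
            if assignment.is_sample and options.min_len and (
                len(trimmed.r1_sequence) < options.min_len
                or len(trimmed.r2_sequence) < options.min_len
            ):
                assignment = Assignment(
                    NO_TAG, assignment.fwd_tag, assignment.rev_tag,
                    assignment.fwd_distance, assignment.rev_distance,
                )
                trimmed = pair
            stats.record(assignment)
            writer.write(assignment.category, trimmed)
    finally:
        writer.close()

    with (out_dir / "demux_stats.tsv").open("w") as handle:
        handle.write("sample\treads\n")
        for sample, count in sorted(stats.per_sample.items()):
            handle.write(f"{sample}\t{count}\n")
        for category, count in stats.per_category.items():
            handle.write(f"{category}\t{count}\n")
    (out_dir / "demux_stats.json").write_text(stats.to_json() + "\n")
    return stats
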