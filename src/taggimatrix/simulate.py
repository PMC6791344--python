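"""Synthetic quadruple-indexed amplicon libraries with known ground truth.

Builds full-length library molecules in silico — adapter tail, inline tag
(heterogeneity spacer + index), locus primer, insert, and their reverse-strand
mirror — and emits paired-end FASTQ exactly as an instrument would deliver it
after outer-index demultiplexing: R1 starts at the base after the Read1
sequencing-primer site (so the forward spacer+index comes first), R2 starts
after Read2 on the opposite strand (reverse spacer+index first). A truth
table records every read's sample of origin, tags, insert coordinates and
injected error positions, so demultiplexer output can be scored exactly.

The error model is substitution-only at a constant per-base rate with flat
Q37 qualities: enough to exercise a Hamming-distance matcher, which is the
point; real quality profiles, indels and chimeras are not emulated (a
tag-jump rate that swaps one mate's tag is available to mimic unexpected
combinations).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .demux import SampleSheet, open_maybe_gzip
from .primer_forge import IUPAC_CODES, tail_for

__all__ = ["TruthEntry", "TruthTable", "SimulatedRun", "simulate_reads",
           "score_demux", "assignments_from_dir"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

QUALITY_CHAR = "F"  # Q37, Phred+33


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TruthEntry:
    read_id: str
    sample_id: str
    fwd_tag: str  # label actually embedded in R1
    rev_tag: str  # label actually embedded in R2 (post tag-jump, if any)
    insert_span_r1: tuple[int, int]  # 0-based half-open, R1 coordinates, clipped
    r1_errors: tuple[int, ...]
    r2_errors: tuple[int, ...]
    tag_jumped: bool = False


@dataclass
class TruthTable:
    entries: dict[str, TruthEntry] = field(default_factory=dict)

    def add(self, entry: TruthEntry) -> None:
        if entry.read_id in self.entries:
            raise ValueError(f"duplicate read ID {entry.read_id!r}")
        self.entries[entry.read_id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            handle.write(
                "read_id\tsample_id\tfwd_tag\trev_tag\tinsert_start\tinsert_end"
                "\tr1_errors\tr2_errors\ttag_jumped\n"
            )
            for e in self.entries.values():
                handle.write(
                    f"{e.read_id}\t{e.sample_id}\t{e.fwd_tag}\t{e.rev_tag}"
                    f"\t{e.insert_span_r1[0]}\t{e.insert_span_r1[1]}"
                    f"\t{','.join(map(str, e.r1_errors))}"
                    f"\t{','.join(map(str, e.r2_errors))}"
                    f"\t{int(e.tag_jumped)}\n"
                )


@dataclass
class SimulatedRun:
    r1_path: Path
    r2_path: Path
    truth: TruthTable
    params: dict


def _resolve_iupac(seq: str, rng: random.Random) -> str:
    return "".join(
        b if b in "ACGT" else rng.choice(sorted(IUPAC_CODES[b])) for b in seq.upper()
    )


def _inject_errors(
    seq: str, rng: random.Random, error_rate: float,
    forced_region: tuple[int, int] | None = None, forced_count: int = 0,
) -> tuple[str, tuple[int, ...]]:
    """Substitute bases iid at error_rate; optionally force exactly
    ``forced_count`` substitutions uniformly inside ``forced_region``."""
    bases = list(seq)
    positions: set[int] = set()
    if forced_region is not None and forced_count > 0:
        lo, hi = forced_region
        positions.update(rng.sample(range(lo, hi), forced_count))
    if error_rate > 0:
        for i in range(len(bases)):
            if i in positions:
                continue
            if rng.random() < error_rate:
                positions.add(i)
    for i in positions:
        bases[i] = rng.choice([b for b in "ACGT" if b != bases[i]])
    return "".join(bases), tuple(sorted(positions))


def simulate_reads(
    sheet: SampleSheet,
    inserts: list[str] | None,
    reads_per_sample: int,
    read_length: int = 250,
    error_rate: float = 0.0,
    seed: int = 0,
    out_dir: str | Path = ".",
    chemistry: str = "TruSeq",
    insert_length: int = 150,
    errors_per_tag: int = 0,
    tag_jump_rate: float = 0.0,
    gzip_output: bool = True,
    prefix: str = "sim",
) -> SimulatedRun:
    """Simulate a sequencing run for every entry of a samplesheet.

    ``inserts`` defaults to seeded-random sequences of ``insert_length`` bp,
    one drawn per read. ``errors_per_tag`` forces exactly that many
    substitutions uniformly inside each mate's tag region (on top of the iid
    ``error_rate`` elsewhere); ``tag_jump_rate`` swaps the reverse tag of a
    pair for another reverse tag, emulating chimera-style unexpected
    combinations. Deterministic for a fixed seed. Outer i5/i7 labels from the
    sheet are written as ``i5=... i7=...`` header comments, never as bases.
    """
    if not sheet.entries:
        raise ValueError("samplesheet has no entries")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    if not sheet.forward_primer or not sheet.reverse_primer:
        raise ValueError("simulation requires forward and reverse locus primers on the sheet")

    rng = random.Random(seed)
    fwd_primer = sheet.forward_primer.upper()
    rev_primer = sheet.reverse_primer.upper()
    read2_tail = tail_for(chemistry, 2).sequence  # type: ignore[arg-type]
    read1_tail = tail_for(chemistry, 1).sequence  # type: ignore[arg-type]

    longest_tag = max(len(t) for t in sheet.index_set.all_tags)
    if read_length < longest_tag + len(fwd_primer) + 1:
        raise ValueError(
            f"read_length {read_length} too short: need > tag ({longest_tag}) "
            f"+ primer ({len(fwd_primer)})"
        )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    r1_path = out_dir / f"{prefix}_R1{suffix}"
    r2_path = out_dir / f"{prefix}_R2{suffix}"
    truth = TruthTable()
    rev_tags = sheet.index_set.reverse_tags

    with open_maybe_gzip(r1_path, "wt") as h1, open_maybe_gzip(r2_path, "wt") as h2:
        serial = 0
        for (fwd_label, rev_label), sample_id in sheet.entries.items():
            fwd_tag = sheet.index_set.tag("forward", fwd_label)
            rev_tag = sheet.index_set.tag("reverse", rev_label)
            outer = sheet.outer.get((fwd_label, rev_label))
            comment = f" i5={outer[0]} i7={outer[1]}" if outer else ""
            for _ in range(reads_per_sample):
                serial += 1
                read_id = f"{prefix}:{serial}"
                jumped = False
                obs_rev = rev_tag
                if tag_jump_rate > 0 and rng.random() < tag_jump_rate:
                    others = [t for t in rev_tags if t.label != rev_label]
                    if others:
                        obs_rev = rng.choice(others)
                        jumped = True
                insert = (
                    rng.choice(inserts)
                    if inserts
                    else "".join(rng.choice("ACGT") for _ in range(insert_length))
                )
                fp = _resolve_iupac(fwd_primer, rng)
                rp = _resolve_iupac(rev_primer, rng)

                # top strand downstream of the Read1 site, read 5'->3' as R1
                top = (
                    fwd_tag.full_sequence + fp + insert + revcomp(rp)
                    + revcomp(obs_rev.full_sequence) + revcomp(read2_tail)
                )
                # bottom strand downstream of the Read2 site, read 5'->3' as R2
                bottom = (
                    obs_rev.full_sequence + rp + revcomp(insert) + revcomp(fp)
                    + revcomp(fwd_tag.full_sequence) + revcomp(read1_tail)
                )
                r1 = (top + "A" * read_length)[:read_length]
                r2 = (bottom + "A" * read_length)[:read_length]

                tag1 = (0, len(fwd_tag))
                tag2 = (0, len(obs_rev))
                r1, e1 = _inject_errors(r1, rng, error_rate, tag1, errors_per_tag)
                r2, e2 = _inject_errors(r2, rng, error_rate, tag2, errors_per_tag)

                ins_start = len(fwd_tag) + len(fp)
                ins_span = (min(ins_start, read_length), min(ins_start + len(insert), read_length))
                truth.add(
                    TruthEntry(read_id, sample_id, fwd_label, obs_rev.label,
                               ins_span, e1, e2, jumped)
                )
                q = QUALITY_CHAR * read_length
                h1.write(f"@{read_id}{comment}\n{r1}\n+\n{q}\n")
                h2.write(f"@{read_id}{comment}\n{r2}\n+\n{q}\n")

    params = {
        "seed": seed, "reads_per_sample": reads_per_sample, "read_length": read_length,
        "error_rate": error_rate, "errors_per_tag": errors_per_tag,
        "tag_jump_rate": tag_jump_rate, "chemistry": chemistry,
        "insert_length": insert_length, "n_samples": len(sheet.entries),
        "total_pairs": len(truth),
    }
    truth.write_tsv(out_dir / f"{prefix}_truth.tsv")
    (out_dir / f"{prefix}_params.json").write_text(json.dumps(params, indent=2) + "\n")
    return SimulatedRun(r1_path, r2_path, truth, params)


def assignments_from_dir(out_dir: str | Path) -> dict[str, str]:
    """Recover per-read assignments from a demultiplexer output directory.

    Maps read ID -> sample ID (or unassigned category) by scanning the R1
    FASTQ files the demultiplexer wrote.
    """
    out: dict[str, str] = {}
    for path in sorted(Path(out_dir).glob("*_R1.fastq*")):
        stem = path.name.split("_R1.fastq")[0]
        with open_maybe_gzip(path) as handle:
            for i, line in enumerate(handle):
                if i % 4 == 0:
                    out[line[1:].split()[0]] = stem
    return out


@dataclass(frozen=True)
class ScoreReport:
    total: int
    fraction_correct: float
    fraction_misassigned: float
    fraction_unassigned: float


def score_demux(assignments: dict[str, str], truth: TruthTable) -> ScoreReport:
    """Score demultiplexer assignments against the simulation truth.

    A read assigned to its true sample is correct; assigned to any other
    sample is misassigned; anything else (no-tag, ambiguous, unexpected
    combination, or missing from the outputs) is unassigned. The three
    fractions sum to 1.
    """
    unknown = set(assignments) - set(truth.entries)
    if unknown:
        raise ValueError(f"assignments contain unknown read IDs, e.g. {sorted(unknown)[:3]}")
    sample_ids = {e.sample_id for e in truth.entries.values()}
    correct = mis = 0
    for read_id, entry in truth.entries.items():
        got = assignments.get(read_id)
        if got == entry.sample_id:
            correct += 1
        elif got in sample_ids:
            mis += 1
    total = len(truth)
    if total == 0:
        raise ValueError("empty truth table")
    return ScoreReport(
        total=total,
        fraction_correct=correct / total,
        fraction_misassigned=mis / total,
        fraction_unassigned=(total - correct - mis) / total,
    )
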