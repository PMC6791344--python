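"""Fusion-primer assembly for indexed amplicon libraries.

A fusion primer is the concatenation, 5' to 3', of a partial Illumina adapter
tail (the TruSeq or Nextera Read1/Read2 sequencing-primer sequence), an
optional internal tag (heterogeneity spacer + 5 nt index), and the
locus-specific primer. Amplifying with such primers yields products that a
second, limited-cycle PCR with indexed universal (iTru/iNext-style) primers
converts into full-length dual-indexed Illumina libraries.

A standard panel for one locus is 22 oligos: 2 non-indexed fusions plus 8
indexed forward (tags A-H) and 12 indexed reverse (tags 1-12). Used
combinatorially, row-wise forward tags and column-wise reverse tags address
all 96 wells of a plate. "Flipped" panels swap which locus primer carries the
Read1 vs Read2 tail, mitigating the Read 2 quality bias of some instruments.

No thermodynamic screening is performed: secondary structures, hairpins and
primer dimers are NOT checked here and should be vetted before ordering.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .index_kit import IndexSet, IndexTag, validate

__all__ = [
    "ADAPTER_TAILS",
    "IUPAC_CODES",
    "AdapterTail",
    "LocusPrimer",
    "FusionPrimer",
    "PrimerPanel",
    "PlateMap",
    "build_fusion_primer",
    "build_primer_panel",
    "plate_layout",
    "write_order_sheet",
    "read_order_sheet",
    "write_plate_csv",
]

Chemistry = Literal["TruSeq", "Nextera"]

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class AdapterTail:
    name: str
    sequence: str


ADAPTER_TAILS: dict[str, AdapterTail] = {
    "TruSeq_Read1": AdapterTail("TruSeq_Read1", "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"),
    "TruSeq_Read2": AdapterTail("TruSeq_Read2", "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"),
    "Nextera_Read1": AdapterTail("Nextera_Read1", "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"),
    "Nextera_Read2": AdapterTail("Nextera_Read2", "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"),
}


def tail_for(chemistry: Chemistry, read: Literal[1, 2]) -> AdapterTail:
    return ADAPTER_TAILS[f"{chemistry}_Read{read}"]


@dataclass(frozen=True)
class LocusPrimer:
    """A locus-specific primer; IUPAC degeneracy codes are allowed and kept."""

    name: str
    sequence: str
    orientation: Literal["forward", "reverse"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError(f"locus primer {self.name!r} has an empty sequence")
        bad = set(self.sequence) - set(IUPAC_CODES)
        if bad:
            raise ValueError(
                f"locus primer {self.name!r}: non-IUPAC characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class FusionPrimer:
    name: str
    tail: AdapterTail
    tag: IndexTag | None
    locus: LocusPrimer
    flipped: bool = False

    @property
    def full_sequence(self) -> str:
        tag_part = self.tag.full_sequence if self.tag is not None else ""
        return self.tail.sequence + tag_part + self.locus.sequence

    @property
    def display_sequence(self) -> str:
        """Uppercase tail/index with the heterogeneity spacer in lowercase."""
        tag_part = self.tag.display_sequence if self.tag is not None else ""
        return self.tail.sequence + tag_part + self.locus.sequence

    def __len__(self) -> int:
        return len(self.full_sequence)


@dataclass
class PrimerPanel:
    chemistry: Chemistry
    flipped: bool
    primers: list[FusionPrimer]
    forward_locus: LocusPrimer
    reverse_locus: LocusPrimer
    index_set: IndexSet

    def by_name(self, name: str) -> FusionPrimer:
        for p in self.primers:
            if p.name == name:
                return p
        raise KeyError(name)

    def indexed(self, orientation: str, flipped: bool = False) -> list[FusionPrimer]:
        return [
            p
            for p in self.primers
            if p.tag is not None
            and p.locus.orientation == orientation
            and p.flipped == flipped
        ]


@dataclass
class PlateMap:
    """96-well combinatorial layout: row r, column c -> (forward tag r, reverse tag c)."""

    wells: dict[str, tuple[str, str]] = field(default_factory=dict)

    ROWS = "ABCDEFGH"
    COLUMNS = tuple(range(1, 13))


def _primer_name(
    locus: LocusPrimer, chemistry: Chemistry, read: int, tag: IndexTag | None, flipped: bool
) -> str:
    tag_part = tag.label if tag is not None else "NoTag"
    suffix = "_flip" if flipped else ""
    return f"{locus.name}_{chemistry}_R{read}_{tag_part}{suffix}"


def build_fusion_primer(
    tail: AdapterTail,
    tag: IndexTag | None,
    locus: LocusPrimer,
    chemistry: Chemistry | None = None,
    flipped: bool = False,
) -> FusionPrimer:
    """Concatenate tail + (spacer + index) + locus primer, no separators.

    In an unflipped design the forward locus primer carries a Read1 tail and
    the reverse a Read2 tail; ``flipped=True`` marks the swapped pairing.
    IUPAC codes in the locus primer pass through untouched.
    """
    read = 1 if tail.name.endswith("Read1") else 2
    expected = ("forward", "reverse") if not flipped else ("reverse", "forward")
    if locus.orientation != expected[read - 1]:
        raise ValueError(
            f"{tail.name} with a {locus.orientation} locus primer requires flipped="
            f"{not flipped}"
        )
    chem: Chemistry = chemistry or ("TruSeq" if tail.name.startswith("TruSeq") else "Nextera")
    return FusionPrimer(
        name=_primer_name(locus, chem, read, tag, flipped),
        tail=tail,
        tag=tag,
        locus=locus,
        flipped=flipped,
    )


def build_primer_panel(
    forward: LocusPrimer,
    reverse: LocusPrimer,
    chemistry: Chemistry,
    index_set: IndexSet,
    flipped: bool = False,
    min_edit: int = 3,
) -> PrimerPanel:
    """Generate the full fusion-primer panel for one locus.

    Returns 2 non-indexed + 8 indexed forward + 12 indexed reverse = 22
    primers; with ``flipped=True`` the 22 tail-swapped variants are appended
    (44 total). Tags stay with their locus primer in flipped mode: flipping
    changes only which adapter tail each locus primer carries.
    """
    if forward.sequence == reverse.sequence:
        raise ValueError("forward and reverse locus primers must differ")
    report = validate(index_set, min_edit=min_edit)
    if not report.passed:
        raise ValueError(
            f"index set {index_set.name!r} fails validation "
            f"(min edit distance {report.min_edit_distance}, "
            f"{len(report.balance_violations)} balance / "
            f"{len(report.length_violations)} length violations)"
        )

    def half(flip: bool) -> list[FusionPrimer]:
        fwd_read, rev_read = (1, 2) if not flip else (2, 1)
        fwd_tail = tail_for(chemistry, fwd_read)
        rev_tail = tail_for(chemistry, rev_read)
        primers = [
            build_fusion_primer(fwd_tail, None, forward, chemistry, flipped=flip),
            build_fusion_primer(rev_tail, None, reverse, chemistry, flipped=flip),
        ]
        primers += [
            build_fusion_primer(fwd_tail, t, forward, chemistry, flipped=flip)
            for t in index_set.forward_tags
        ]
        primers += [
            build_fusion_primer(rev_tail, t, reverse, chemistry, flipped=flip)
            for t in index_set.reverse_tags
        ]
        return primers

    primers = half(False)
    if flipped:
        primers += half(True)
    return PrimerPanel(
        chemistry=chemistry,
        flipped=flipped,
        primers=primers,
        forward_locus=forward,
        reverse_locus=reverse,
        index_set=index_set,
    )


def plate_layout(panel: PrimerPanel) -> PlateMap:
    """Map the 8 x 12 indexed primers onto a 96-well plate.

    Row r gets the r-th forward tag, column c the c-th reverse tag, so every
    well amplifies with a distinct tag combination.
    """
    fwd = panel.indexed("forward")
    rev = panel.indexed("reverse")
    if len(fwd) != 8 or len(rev) != 12:
        raise ValueError(
            f"plate layout needs 8 indexed forward and 12 indexed reverse primers, "
            f"got {len(fwd)} and {len(rev)}"
        )
    wells = {}
    for row, fp in zip(PlateMap.ROWS, fwd):
        for col, rp in zip(PlateMap.COLUMNS, rev):
            wells[f"{row}{col}"] = (fp.tag.label, rp.tag.label)
    return PlateMap(wells=wells)


def write_order_sheet(panel: PrimerPanel, path: str | Path) -> None:
    """Write a synthesis order sheet (CSV).

    The ``sequence`` column is all-uppercase (vendors ignore case); the
    ``annotated_sequence`` column keeps the lowercase spacer for human
    proofreading.
    """
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["name", "sequence", "length", "role", "tag_label", "annotated_sequence"]
        )
        for p in panel.primers:
            writer.writerow(
                [
                    p.name,
                    p.full_sequence,
                    len(p),
                    p.locus.orientation,
                    p.tag.label if p.tag is not None else "",
                    p.display_sequence,
                ]
            )


def read_order_sheet(path: str | Path) -> list[dict[str, str]]:
    """Read back an order sheet; returns the raw rows (name, sequence, ...)."""
    with Path(path).open(newline="") as handle:
        return list(csv.DictReader(handle))


def write_plate_csv(plate: PlateMap, path: str | Path, samples: dict[str, str] | None = None) -> None:
    """Write the 96-well layout as CSV (well, sample, forward tag, reverse tag)."""
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["well", "sample_id", "fwd_tag", "rev_tag"])
        for row in PlateMap.ROWS:
            for col in PlateMap.COLUMNS:
                well = f"{row}{col}"
                fwd, rev = plate.wells[well]
                writer.writerow([well, (samples or {}).get(well, ""), fwd, rev])
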