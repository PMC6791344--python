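"""Variable-length internal index sets for combinatorial amplicon multiplexing.

An internal (inline) index is a short identifying sequence placed between the
Illumina Read1/Read2 sequencing-primer site and the locus-specific primer, so
it is read as the first bases of each mate. Each tag is a 0-3 nt
"heterogeneity spacer" followed by a 5 nt index. The spacers stagger
otherwise-identical amplicon bases across sequencing cycles, restoring the
per-cycle base diversity that Illumina basecalling needs; within each group of
four tags (a *tetrad*) the full-sequence lengths are exactly {5, 6, 7, 8} and
the red/green detection channels (A,C red; G,T green on MiSeq and HiSeq <=
2500) are balanced 2/2 at every cycle the whole tetrad spans.

The default set of 8 forward (A-H) and 12 reverse (1-12) tags supports
8 x 12 = 96 combinatorial sample assignments per plate, and every pair of
indexes is at Levenshtein distance >= 3, so a single sequencing error can be
corrected unambiguously. :func:`design_set` generates fresh sets under the
same constraints.
"""

from __future__ import annotations

import csv
import itertools
import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import edlib

__all__ = [
    "IndexTag",
    "IndexSet",
    "ValidationReport",
    "SetDesignError",
    "load_default_set",
    "load_set_csv",
    "write_set_csv",
    "min_pairwise_edit_distance",
    "channel_balance",
    "validate",
    "design_set",
    "multiplex_capacity",
]

DNA = frozenset("ACGT")
RED_CHANNEL = frozenset("AC")  # MiSeq / HiSeq <=2500 two-laser scheme
GREEN_CHANNEL = frozenset("GT")

Role = Literal["forward", "reverse"]


class SetDesignError(RuntimeError):
    """Raised when a constraint-satisfying index set cannot be found."""


@dataclass(frozen=True)
class IndexTag:
    """One internal identifier: heterogeneity spacer + 5 nt index.

    ``spacer`` and ``index`` are stored uppercase in separate fields; the
    conventional rendering (lowercase spacer, uppercase index) is available
    as :attr:`display_sequence`.
    """

    label: str
    spacer: str
    index: str
    role: Role
    group: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacer", self.spacer.upper())
        object.__setattr__(self, "index", self.index.upper())
        if len(self.index) != 5:
            raise ValueError(
                f"tag {self.label!r}: index must be 5 nt, got {self.index!r}"
            )
        bad = (set(self.spacer) | set(self.index)) - DNA
        if bad:
            raise ValueError(f"tag {self.label!r}: non-ACGT characters {sorted(bad)}")
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"tag {self.label!r}: bad role {self.role!r}")

    @property
    def full_sequence(self) -> str:
        """Spacer + index, the bases actually synthesised into the primer."""
        return self.spacer + self.index

    @property
    def display_sequence(self) -> str:
        """Lowercase spacer + uppercase index, as printed in order sheets."""
        return self.spacer.lower() + self.index

    def __len__(self) -> int:
        return len(self.spacer) + 5


@dataclass
class IndexSet:
    """An ordered collection of forward and reverse internal tags."""

    forward_tags: list[IndexTag]
    reverse_tags: list[IndexTag]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        for role, tags in (("forward", self.forward_tags), ("reverse", self.reverse_tags)):
            labels = [t.label for t in tags]
            if len(labels) != len(set(labels)):
                raise ValueError(f"duplicate {role} tag labels")
            for t in tags:
                if t.role != role:
                    raise ValueError(f"tag {t.label!r} has role {t.role!r}, expected {role!r}")

    @property
    def all_tags(self) -> list[IndexTag]:
        return self.forward_tags + self.reverse_tags

    def tag(self, role: Role, label: str) -> IndexTag:
        pool = self.forward_tags if role == "forward" else self.reverse_tags
        for t in pool:
            if t.label == label:
                return t
        raise KeyError(f"no {role} tag labelled {label!r}")

    def groups(self) -> dict[int, list[IndexTag]]:
        out: dict[int, list[IndexTag]] = {}
        for t in self.all_tags:
            out.setdefault(t.group, []).append(t)
        return out


@dataclass
class ValidationReport:
    """Outcome of the three design checks on an index set.

    ``balance_violations`` holds (group, position, red_count, green_count)
    rows where the tetrad's channel counts are uneven; ``length_violations``
    holds (group, sorted lengths) for tetrads whose full-sequence lengths are
    not one each of the staggered range.
    """

    min_edit_distance: int
    balance_violations: list[tuple[int, int, int, int]] = field(default_factory=list)
    length_violations: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)
    group_size_violations: list[tuple[int, int]] = field(default_factory=list)
    min_edit_required: int = 3
    passed: bool = False

    def __post_init__(self) -> None:
        self.passed = (
            not self.balance_violations
            and not self.length_violations
            and not self.group_size_violations
            and self.min_edit_distance >= self.min_edit_required
        )


def _data_path(name: str):
    return resources.files("taggimatrix.data").joinpath(name)


def load_default_set() -> IndexSet:
    """Load the built-in 8 forward + 12 reverse tag set."""
    with _data_path("default_index_set.csv").open() as handle:
        return _read_set(csv.DictReader(handle), name="default")


def load_set_csv(path: str | Path, name: str | None = None) -> IndexSet:
    """Load an index set from a CSV with columns label, role, spacer, index, group."""
    path = Path(path)
    with path.open(newline="") as handle:
        return _read_set(csv.DictReader(handle), name=name or path.stem)


def _read_set(rows: Iterable[dict], name: str) -> IndexSet:
    fwd: list[IndexTag] = []
    rev: list[IndexTag] = []
    for row in rows:
        tag = IndexTag(
            label=row["label"].strip(),
            spacer=(row.get("spacer") or "").strip(),
            index=row["index"].strip(),
            role=row["role"].strip(),  # type: ignore[arg-type]
            group=int(row["group"]),
        )
        (fwd if tag.role == "forward" else rev).append(tag)
    return IndexSet(fwd, rev, name=name)


def write_set_csv(index_set: IndexSet, path: str | Path) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["label", "role", "spacer", "index", "group"])
        for t in index_set.all_tags:
            writer.writerow([t.label, t.role, t.spacer.lower(), t.index, t.group])


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitutions, insertions, deletions)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def min_pairwise_edit_distance(
    index_set: IndexSet, on: Literal["index", "full_sequence"] = "index"
) -> int:
    """Minimum Levenshtein distance over all unordered tag pairs.

    Forward and reverse tags are pooled into one universe: a set whose
    forward tags collide with reverse tags would be fragile against
    orientation mix-ups even if each role were internally consistent.
    """
    tags = index_set.all_tags
    if len(tags) < 2:
        raise ValueError("need at least 2 tags to compute a pairwise distance")
    seqs = [getattr(t, on) for t in tags]
    return min(levenshtein(a, b) for a, b in itertools.combinations(seqs, 2))


def channel_balance(index_set: IndexSet) -> list[tuple[int, int, int, int]]:
    """Red/green channel counts per tetrad and cycle.

    Full sequences are aligned at their 5' ends and positions 1..5 (the
    shortest member's span) are counted; beyond that, tetrad members run out
    at different cycles so per-cycle balance is not defined for the group.
    Returns (group, position, red_count, green_count) for every evaluated
    cell; groups with fewer than 4 members contribute no rows.
    """
    rows: list[tuple[int, int, int, int]] = []
    for group, members in sorted(index_set.groups().items()):
        if len(members) != 4:
            continue
        seqs = [t.full_sequence for t in members]
        span = min(len(s) for s in seqs)
        for pos in range(min(span, 5)):
            red = sum(1 for s in seqs if s[pos] in RED_CHANNEL)
            rows.append((group, pos + 1, red, 4 - red))
    return rows


def validate(
    index_set: IndexSet,
    min_edit: int = 3,
    on: Literal["index", "full_sequence"] = "index",
    length_range: tuple[int, int] | None = None,
) -> ValidationReport:
    """Check the three design guarantees of a tag set.

    1. every pair of tags (pooled across roles) is at Levenshtein distance
       >= ``min_edit`` on the chosen sequence field;
    2. each tetrad's four full-sequence lengths stagger one cycle apart
       (``length_range`` defaults to (min observed, min+3));
    3. each tetrad is channel-balanced 2 red / 2 green at positions 1-5.

    Violations are returned as data, never raised.
    """
    min_dist = min_pairwise_edit_distance(index_set, on=on)

    group_size_violations: list[tuple[int, int]] = []
    length_violations: list[tuple[int, tuple[int, ...]]] = []
    for group, members in sorted(index_set.groups().items()):
        if len(members) != 4:
            group_size_violations.append((group, len(members)))
            continue
        lengths = tuple(sorted(len(t) for t in members))
        low = length_range[0] if length_range else lengths[0]
        expected = tuple(range(low, low + 4))
        if lengths != expected:
            length_violations.append((group, lengths))

    balance_violations = [
        row for row in channel_balance(index_set) if row[2] != row[3]
    ]

    return ValidationReport(
        min_edit_distance=min_dist,
        balance_violations=balance_violations,
        length_violations=length_violations,
        group_size_violations=group_size_violations,
        min_edit_required=min_edit,
    )


def multiplex_capacity(n_fwd_inner: int, n_rev_inner: int, n_i5: int, n_i7: int) -> int:
    """Number of samples distinguishable by combinatorial quadruple indexing.

    Two inline tags and two outer (i5/i7) indexes multiply: 8 x 12 inline
    combinations alone address a 96-well plate; with 384 i5 and 384 i7
    primers the capacity reaches 14,155,776.
    """
    args = (n_fwd_inner, n_rev_inner, n_i5, n_i7)
    if any(int(a) != a or a < 1 for a in args):
        raise ValueError(f"all index counts must be positive integers, got {args}")
    out = 1
    for a in args:
        out *= int(a)
    return out


# ---------------------------------------------------------------------------
# Set generation


def _balanced_tetrad(
    indexes: Sequence[str], spacer_lengths: Sequence[int], rng: random.Random
) -> list[tuple[str, str]] | None:
    """Try to attach spacers (lengths a permutation of ``spacer_lengths``) to
    four fixed indexes so positions 1..5 of the full sequences balance 2/2.

    A column position is filled partly by spacer bases (free: we choose their
    channel) and partly by index bases (fixed). The permutation of spacer
    lengths is searched; for each, the fully index-determined columns must
    already balance and the partly-free columns must be fixable.
    Returns [(spacer, index)] * 4 or None.
    """
    assert len(indexes) == 4
    for perm in itertools.permutations(spacer_lengths):
        # channel of the fixed (index) base landing in column pos for member j
        ok = True
        free_red_needed: dict[int, int] = {}
        for pos in range(5):  # 0-based column
            fixed_red = 0
            n_free = 0
            for sl, idx in zip(perm, indexes):
                if pos < sl:
                    n_free += 1
                else:
                    fixed_red += idx[pos - sl] in RED_CHANNEL
            need = 2 - fixed_red
            if need < 0 or need > n_free:
                ok = False
                break
            free_red_needed[pos] = need
        if not ok:
            continue
        # materialise spacers column by column
        spacers = [list("." * sl) for sl in perm]
        for pos in range(max(perm, default=0)):
            free_members = [j for j, sl in enumerate(perm) if pos < sl]
            if pos < 5:
                reds = rng.sample(free_members, free_red_needed[pos])
            else:  # beyond the balanced span: unconstrained
                reds = [j for j in free_members if rng.random() < 0.5]
            for j in free_members:
                channel = "AC" if j in reds else "GT"
                spacers[j][pos] = rng.choice(channel)
        return [("".join(s), idx) for s, idx in zip(spacers, indexes)]
    return None


def design_set(
    n_forward: int,
    n_reverse: int,
    index_len: int = 5,
    spacer_range: tuple[int, int] = (0, 3),
    min_edit: int = 3,
    seed: int = 0,
    max_tries: int = 20_000,
) -> IndexSet:
    """Generate a fresh constraint-satisfying tag set.

    Indexes are drawn greedily from a seeded random enumeration of all
    ``4**index_len`` words, accepting each word only if it keeps every
    pairwise Levenshtein distance >= ``min_edit`` (forward and reverse pooled).
    Each accepted quadruple is then dressed with heterogeneity spacers whose
    lengths are a permutation of ``spacer_range`` and whose bases are chosen
    column-wise to force exact 2 red / 2 green balance at positions 1-5; if
    no spacer-length permutation can balance a quadruple, the last index is
    swapped out and the search continues.

    Deterministic for a fixed seed. Raises :class:`SetDesignError` naming the
    unsatisfied constraint when the candidate budget is exhausted.
    """
    if index_len != 5:
        raise NotImplementedError("only 5 nt indexes are supported")
    for n, role in ((n_forward, "forward"), (n_reverse, "reverse")):
        if n % 4 != 0 and n != 0:
            raise ValueError(f"{role} count {n} is not divisible into tetrads")
    lo, hi = spacer_range
    if hi - lo != 3:
        raise ValueError("spacer_range must span exactly 4 lengths (one tetrad)")
    spacer_lengths = list(range(lo, hi + 1))

    rng = random.Random(seed)
    words = ["".join(p) for p in itertools.product("ACGT", repeat=index_len)]
    rng.shuffle(words)

    accepted: list[str] = []  # indexes, in tetrad order
    tetrads: list[list[tuple[str, str]]] = []
    n_tetrads = (n_forward + n_reverse) // 4
    tries = 0
    cursor = 0

    def next_candidate() -> str:
        nonlocal cursor, tries
        while cursor < len(words):
            w = words[cursor]
            cursor += 1
            tries += 1
            if tries > max_tries:
                raise SetDesignError(
                    f"candidate budget ({max_tries}) exhausted with "
                    f"{len(accepted)} indexes accepted: min_edit={min_edit} "
                    f"appears unsatisfiable for {n_tetrads * 4} indexes of length {index_len}"
                )
            if all(levenshtein(w, a) >= min_edit for a in accepted):
                return w
        raise SetDesignError(
            f"exhausted all {len(words)} candidate indexes with "
            f"{len(accepted)} accepted: min_edit={min_edit} is unsatisfiable "
            f"for {n_tetrads * 4} indexes of length {index_len}"
        )

    while len(tetrads) < n_tetrads:
        # accumulate four mutually-compatible indexes
        quad_idx: list[str] = []
        while len(quad_idx) < 4:
            w = next_candidate()
            if all(levenshtein(w, q) >= min_edit for q in quad_idx):
                quad_idx.append(w)
        # attach balanced spacers; on failure, replace members one at a time
        dressed = _balanced_tetrad(quad_idx, spacer_lengths, rng)
        while dressed is None:
            quad_idx.pop(rng.randrange(4))
            w = next_candidate()
            while not all(levenshtein(w, q) >= min_edit for q in quad_idx):
                w = next_candidate()
            quad_idx.append(w)
            dressed = _balanced_tetrad(quad_idx, spacer_lengths, rng)
        accepted.extend(quad_idx)
        tetrads.append(dressed)

    fwd_labels = [chr(ord("A") + i) for i in range(n_forward)]
    rev_labels = [str(i + 1) for i in range(n_reverse)]
    forward: list[IndexTag] = []
    reverse: list[IndexTag] = []
    flat = [(g + 1, spacer, index) for g, quad in enumerate(tetrads) for spacer, index in quad]
    for i, label in enumerate(fwd_labels):
        group, spacer, index = flat[i]
        forward.append(IndexTag(label, spacer, index, "forward", group))
    for i, label in enumerate(rev_labels):
        group, spacer, index = flat[n_forward + i]
        reverse.append(IndexTag(label, spacer, index, "reverse", group))
    return IndexSet(forward, reverse, name=f"designed_seed{seed}")
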