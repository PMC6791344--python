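"""Molarity-aware pooling calculator for sequencing sub-pools.

Given each amplicon sub-pool's mean length (bp), concentration (ng/µL) and
desired share of reads from the run, compute molar concentrations and the
pipetting volumes that combine the sub-pools in proportion to their read
targets. Amplicons of different lengths at the same mass concentration
differ in molarity — and clusters form per molecule, not per nanogram — so
volumes are balanced on moles, not mass. Differences in clustering
efficiency between library types are NOT modeled by default, but a
per-component efficiency hook is exposed for users who want to correct for
platform-specific bias.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

__all__ = [
    "DS_DNA_BP_GRAMS_PER_MOLE",
    "PoolComponent",
    "PoolingPlan",
    "molarity",
    "read_fractions",
    "plan_pool",
    "load_components_csv",
    "write_plan_csv",
]

# average mass of one double-stranded base pair, g/mol; configurable in molarity()
DS_DNA_BP_GRAMS_PER_MOLE = 660.0

MIN_PIPETTABLE_UL = 0.5


@dataclass(frozen=True)
class PoolComponent:
    name: str
    mean_length: int  # bp
    concentration: float  # ng/µL
    target_reads: float

    def __post_init__(self) -> None:
        if self.mean_length <= 0:
            raise ValueError(f"{self.name!r}: mean_length must be positive")
        if self.concentration < 0 or self.target_reads < 0:
            raise ValueError(f"{self.name!r}: concentration and target_reads must be >= 0")


@dataclass
class PlanRow:
    component: PoolComponent
    molarity_nM: float
    read_fraction: float
    volume_uL: float


@dataclass
class PoolingPlan:
    rows: list[PlanRow]
    cap_volume_uL: float
    warnings: list[str] = field(default_factory=list)

    def volume(self, name: str) -> float:
        for row in self.rows:
            if row.component.name == name:
                return row.volume_uL
        raise KeyError(name)

    def fraction(self, name: str) -> float:
        for row in self.rows:
            if row.component.name == name:
                return row.read_fraction
        raise KeyError(name)


def molarity(
    concentration: float, mean_length: int, bp_mass: float = DS_DNA_BP_GRAMS_PER_MOLE
) -> float:
    """Convert a mass concentration (ng/µL) to nM for dsDNA of a given length.

    nM = (ng/µL) × 10^6 / (length_bp × 660), e.g. 6.6 ng/µL of a 1,000 bp
    product is 10 nM.
    """
    if mean_length <= 0:
        raise ValueError("mean_length must be positive")
    return concentration * 1e6 / (mean_length * bp_mass)


def read_fractions(components: Sequence[PoolComponent]) -> dict[str, float]:
    """Normalize target read counts to fractions of the run."""
    total = sum(c.target_reads for c in components)
    if total <= 0:
        raise ValueError("at least one component must have target_reads > 0")
    return {c.name: c.target_reads / total for c in components}


def plan_pool(
    components: Sequence[PoolComponent],
    cap_volume_uL: float = 10.0,
    reference: str | None = None,
    reference_volume_uL: float | None = None,
    efficiency: Callable[[PoolComponent], float] | None = None,
    min_pipettable_uL: float = MIN_PIPETTABLE_UL,
) -> PoolingPlan:
    """Compute pipetting volumes proportional to target_reads / molarity.

    Volumes are scaled so the largest equals ``cap_volume_uL``, or — when a
    ``reference`` component and ``reference_volume_uL`` are given — so that
    component gets exactly its set volume. ``efficiency`` maps a component to
    a relative clustering efficiency (identity by default): a component that
    clusters 2x as well needs half the molecules for the same reads.
    Components with target_reads == 0 get zero volume. Volumes below
    ``min_pipettable_uL`` are reported in the plan's warnings.
    """
    active = [c for c in components if c.target_reads > 0]
    if not active:
        raise ValueError("no component has target_reads > 0")
    for c in active:
        if c.concentration == 0:
            raise ValueError(
                f"component {c.name!r} has target_reads > 0 but zero concentration"
            )
    eff = efficiency or (lambda _c: 1.0)
    fractions = read_fractions(components)

    raw: dict[str, float] = {}
    for c in components:
        if c.target_reads <= 0:
            raw[c.name] = 0.0
            continue
        raw[c.name] = c.target_reads / (molarity(c.concentration, c.mean_length) * eff(c))

    if reference is not None:
        if reference_volume_uL is None:
            raise ValueError("reference_volume_uL is required with a reference component")
        if raw.get(reference, 0.0) <= 0:
            raise ValueError(f"reference component {reference!r} has no demand")
        scale = reference_volume_uL / raw[reference]
    else:
        scale = cap_volume_uL / max(raw.values())

    warnings: list[str] = []
    rows: list[PlanRow] = []
    for c in components:
        # exact volumes are stored; rounding to 0.1 µL happens when reporting
        vol = raw[c.name] * scale
        if 0 < vol < min_pipettable_uL:
            warnings.append(
                f"{c.name}: volume {vol:.1f} µL is below the pipettable minimum "
                f"({min_pipettable_uL} µL); consider diluting this sub-pool"
            )
        rows.append(
            PlanRow(
                component=c,
                molarity_nM=molarity(c.concentration, c.mean_length),
                read_fraction=fractions[c.name],
                volume_uL=vol,
            )
        )
    return PoolingPlan(rows=rows, cap_volume_uL=cap_volume_uL, warnings=warnings)


def load_components_csv(path: str | Path) -> list[PoolComponent]:
    """Read components from CSV with columns name, mean_length, concentration, target_reads."""
    out = []
    with Path(path).open(newline="") as handle:
        for row in csv.DictReader(handle):
            out.append(
                PoolComponent(
                    name=row["name"].strip(),
                    mean_length=int(float(row["mean_length"])),
                    concentration=float(row["concentration"]),
                    target_reads=float(row["target_reads"]),
                )
            )
    return out


def write_plan_csv(plan: PoolingPlan, path: str | Path) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["name", "mean_length_bp", "concentration_ng_uL", "target_reads",
             "molarity_nM", "read_fraction", "volume_uL"]
        )
        for row in plan.rows:
            c = row.component
            writer.writerow(
                [c.name, c.mean_length, c.concentration, c.target_reads,
                 f"{row.molarity_nM:.4g}", f"{row.read_fraction:.4f}", f"{row.volume_uL:.1f}"]
            )
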