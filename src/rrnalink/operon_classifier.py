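"""Operon pairing and linkage classification.

The core procedure: within each replicon, order all complete 16S/23S rRNA
genes by start coordinate, then scan once left to right.  A sense 16S
followed immediately by a sense 23S forms an operon unit, as does an
antisense 23S followed immediately by an antisense 16S (the same operon
read on the opposite strand).  Anything that does not pair becomes a
single rRNA copy.  On circular replicons, an unconsumed trailing/leading
pair that is valid across the origin is joined with a wrapped ITS.

The internal transcribed spacer (ITS) is the gap between the two gene
bodies, exclusive on both sides; a unit with ITS over 1500 bp is an
unlinked operon.  A genome is "linked" when every unit is a linked pair,
"unlinked" when no linked pair exists, and "mixed" otherwise.  Lone 16S or
23S copies count as unlinked evidence: a genome whose 16S and 23S sit on
opposite strands or different replicons is the canonical unlinked case
(e.g. *Wolbachia*) yet yields no pair under the scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotation_io import RnaFeature, RnaType, Topology


class Linkage(str, Enum):
    LINKED = "linked"
    UNLINKED = "unlinked"
    SINGLE = "single"


class GenomeStatus(str, Enum):
    LINKED = "linked"
    MIXED = "mixed"
    UNLINKED = "unlinked"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable knobs of the classifier; the 1500 bp ITS threshold is the
    published linkage criterion."""

    its_threshold: int = 1500

    def __post_init__(self) -> None:
        if self.its_threshold <= 0:
            raise ValueError("its_threshold must be positive")


@dataclass
class OperonUnit:
    kind: str  # "pair" or "single"
    ssu: Optional[RnaFeature] = None
    lsu: Optional[RnaFeature] = None
    its_length: Optional[int] = None
    linkage: Linkage = Linkage.SINGLE
    wrapped: bool = False

    @property
    def chrom_id(self) -> str:
        f = self.ssu or self.lsu
        assert f is not None
        return f.chrom_id

    @property
    def strand(self) -> str:
        f = self.ssu or self.lsu
        assert f is not None
        return f.strand

    @property
    def features(self) -> list[RnaFeature]:
        return [f for f in (self.ssu, self.lsu) if f is not None]


@dataclass(frozen=True)
class GenomeCall:
    genome_id: str
    status: GenomeStatus
    n_linked_units: int
    n_unlinked_units: int
    n_singles: int


def order_features(features: Iterable[RnaFeature]) -> dict[str, list[RnaFeature]]:
    """Group by replicon and sort ascending by (start, end, rna_type).

    The two tie-breakers make the ordering deterministic even for
    coincident coordinates.
    """
    grouped: dict[str, list[RnaFeature]] = {}
    for f in features:
        grouped.setdefault(f.chrom_id, []).append(f)
    for chrom in grouped:
        grouped[chrom].sort(key=lambda f: (f.start, f.end, f.rna_type.value))
    return grouped


def its_length(
    upstream_end: int,
    downstream_start: int,
    topology: Topology,
    chrom_length: int,
    wrapped: Optional[bool] = None,
) -> int:
    """Gap in bp between two gene bodies, exclusive of both.

    A non-wrapping pair gives ``downstream_start - upstream_end - 1``.  A
    pair that spans the origin of a circular replicon (inferred when
    ``downstream_start <= upstream_end``, or forced via ``wrapped=True``)
    gives ``(chrom_length - upstream_end) + (downstream_start - 1)``.
    A negative linear gap (overlapping annotations) is clamped to 0 with a
    warning.
    """
    for name, coord in (("upstream_end", upstream_end), ("downstream_start", downstream_start)):
        if not 1 <= coord <= chrom_length:
            raise ValueError(f"{name}={coord} outside [1, {chrom_length}]")
    if wrapped is None:
        wrapped = downstream_start <= upstream_end
        if wrapped and topology is not Topology.CIRCULAR:
            raise ValueError("wrapping ITS requested on a linear chromosome")
    if wrapped:
        if topology is not Topology.CIRCULAR:
            raise ValueError("wrapping ITS requested on a linear chromosome")
        return (chrom_length - upstream_end) + (downstream_start - 1)
    gap = downstream_start - upstream_end - 1
    if gap < 0:
        warnings.warn(
            f"overlapping features (gap {gap}); clamping ITS to 0", stacklevel=2
        )
        return 0
    return gap


def _pairable(a: RnaFeature, b: RnaFeature) -> bool:
    """Is (a, then b in coordinate order) a valid operon pair?"""
    if a.chrom_id != b.chrom_id or a.strand != b.strand:
        return False
    if a.strand == "+":
        return a.rna_type is RnaType.SSU_16S and b.rna_type is RnaType.LSU_23S
    return a.rna_type is RnaType.LSU_23S and b.rna_type is RnaType.SSU_16S


def _make_pair(
    a: RnaFeature,
    b: RnaFeature,
    topology: Topology,
    chrom_length: int,
    cfg: ClassifierConfig,
    wrapped: bool,
) -> OperonUnit:
    its = its_length(a.end, b.start, topology, chrom_length, wrapped=wrapped)
    ssu, lsu = (a, b) if a.rna_type is RnaType.SSU_16S else (b, a)
    unit = OperonUnit(kind="pair", ssu=ssu, lsu=lsu, its_length=its, wrapped=wrapped)
    unit.linkage = classify_unit(unit, cfg)
    return unit


def pair_operons(
    sorted_features: Sequence[RnaFeature],
    topology: Topology,
    chrom_length: int,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> list[OperonUnit]:
    """Single left-to-right scan over one replicon's sorted features.

    "Following" means the immediately next feature in coordinate order; an
    intervening rRNA of the wrong type or strand breaks the pair and the
    candidate becomes a single.  Paired features are consumed.  On circular
    replicons, unconsumed last and first features that would form a valid
    pair across the origin are joined with ``wrapped=True``.
    """
    feats = list(sorted_features)
    n = len(feats)
    consumed = [False] * n
    units: list[OperonUnit] = []

    i = 0
    while i < n - 1:
        if _pairable(feats[i], feats[i + 1]):
            units.append(
                _make_pair(feats[i], feats[i + 1], topology, chrom_length, cfg, wrapped=False)
            )
            consumed[i] = consumed[i + 1] = True
            i += 2
        else:
            i += 1

    if (
        topology is Topology.CIRCULAR
        and n >= 2
        and not consumed[-1]
        and not consumed[0]
        and _pairable(feats[-1], feats[0])
    ):
        units.append(
            _make_pair(feats[-1], feats[0], topology, chrom_length, cfg, wrapped=True)
        )
        consumed[-1] = consumed[0] = True

    for idx, f in enumerate(feats):
        if not consumed[idx]:
            if f.rna_type is RnaType.SSU_16S:
                units.append(OperonUnit(kind="single", ssu=f, linkage=Linkage.SINGLE))
            else:
                units.append(OperonUnit(kind="single", lsu=f, linkage=Linkage.SINGLE))
    return units


def classify_unit(unit: OperonUnit, cfg: ClassifierConfig = ClassifierConfig()) -> Linkage:
    """Linked iff ITS <= threshold; strictly over the threshold is unlinked."""
    if unit.kind != "pair":
        raise ValueError("classify_unit applies to paired units only")
    assert unit.its_length is not None
    return Linkage.LINKED if unit.its_length <= cfg.its_threshold else Linkage.UNLINKED


def classify_genome(genome_id: str, units: Sequence[OperonUnit]) -> GenomeCall:
    """Genome verdict from its operon units.

    Singles count toward unlinked status (their partner gene is elsewhere
    or absent); a genome with no 16S/23S features at all is undetermined.
    """
    n_linked = sum(1 for u in units if u.kind == "pair" and u.linkage is Linkage.LINKED)
    n_unlinked = sum(1 for u in units if u.kind == "pair" and u.linkage is Linkage.UNLINKED)
    n_singles = sum(1 for u in units if u.kind == "single")
    if not units:
        status = GenomeStatus.UNDETERMINED
    elif n_unlinked == 0 and n_singles == 0:
        status = GenomeStatus.LINKED
    elif n_linked == 0:
        status = GenomeStatus.UNLINKED
    else:
        status = GenomeStatus.MIXED
    return GenomeCall(genome_id, status, n_linked, n_unlinked, n_singles)


def call_genome(
    genome_id: str,
    features: Iterable[RnaFeature],
    chromosomes: Mapping[str, tuple[int, Topology]],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple[list[OperonUnit], GenomeCall]:
    """Order, pair and classify all features of one genome.

    ``chromosomes`` maps replicon id to (length, topology); pairing never
    crosses replicons.
    """
    units: list[OperonUnit] = []
    for chrom_id, feats in order_features(features).items():
        if chrom_id not in chromosomes:
            raise KeyError(f"features reference unknown replicon {chrom_id!r}")
        length, topology = chromosomes[chrom_id]
        units.extend(pair_operons(feats, topology, length, cfg))
    return units, classify_genome(genome_id, units)


def units_to_frame(genome_id: str, units: Iterable[OperonUnit]) -> pd.DataFrame:
    rows = []
    for u in units:
        rows.append(
            {
                "genome": genome_id,
                "chrom": u.chrom_id,
                "kind": u.kind,
                "ssu_start": u.ssu.start if u.ssu else pd.NA,
                "ssu_end": u.ssu.end if u.ssu else pd.NA,
                "lsu_start": u.lsu.start if u.lsu else pd.NA,
                "lsu_end": u.lsu.end if u.lsu else pd.NA,
                "strand": u.strand,
                "its_length": u.its_length if u.its_length is not None else pd.NA,
                "wrapped": u.wrapped,
                "linkage": u.linkage.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome", "chrom", "kind", "ssu_start", "ssu_end",
            "lsu_start", "lsu_end", "strand", "its_length", "wrapped", "linkage",
        ],
    )
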