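"""Genome FASTA and GFF3 ingestion for rRNA operon analysis.

Reads replicon sequences and annotated 16S/23S rRNA features, applying the
screening rules used throughout the pipeline:

* rRNA features flagged ``partial=true`` (or whose ``Note`` says the
  prediction is too short) are removed before any operon pairing;
* only 16S and 23S genes are kept — 5S and all non-rRNA feature types are
  dropped silently;
* coordinates stay GFF3-native: 1-based, inclusive on both ends;
* replicon topology is read from ``Is_circular`` region attributes, with an
  overridable default of circular (complete bacterial chromosomes are
  predominantly circular).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
from Bio import SeqIO
from gffutils.iterators import DataIterator

log = logging.getLogger(__name__)

PARTIAL_NOTE_MARKER = "prediction is too short"


class Topology(str, Enum):
    CIRCULAR = "circular"
    LINEAR = "linear"


class RnaType(str, Enum):
    SSU_16S = "16S"
    LSU_23S = "23S"


@dataclass(frozen=True)
class ChromosomeRecord:
    """One replicon: sequence, length and circular/linear topology."""

    id: str
    sequence: str
    topology: Topology = Topology.CIRCULAR

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RnaFeature:
    """One annotated or PCR-predicted 16S/23S gene.

    Coordinates are 1-based and inclusive; features are stored un-wrapped,
    so ``start <= end`` always holds (annotated features that themselves
    span the replicon origin are rejected at parse time).
    """

    chrom_id: str
    rna_type: RnaType
    strand: str  # "+" or "-"
    start: int
    end: int
    partial: bool = False
    source: str = "annotation"  # or "insilico"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"unknown strand {self.strand!r} for {self.rna_type.value} "
                f"feature on {self.chrom_id}"
            )
        if self.start < 1:
            raise ValueError(f"feature start {self.start} < 1 on {self.chrom_id}")
        if self.end < self.start:
            raise ValueError(
                f"feature end {self.end} < start {self.start} on {self.chrom_id}; "
                "origin-spanning annotations are not supported"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


TopologyLike = Union[Topology, str, None]


def _coerce_topology(value: TopologyLike) -> Topology:
    if isinstance(value, Topology):
        return value
    return Topology(str(value).lower())


def read_genome(
    fasta_path: Union[str, Path],
    topology: Optional[Mapping[str, TopologyLike]] = None,
) -> list[ChromosomeRecord]:
    """Read a genome FASTA into :class:`ChromosomeRecord` objects.

    ``topology`` maps replicon id to ``circular``/``linear`` (typically the
    output of :func:`detect_topology`); ids absent from the map default to
    circular, with a log notice.
    """
    fasta_path = Path(fasta_path)
    records: list[ChromosomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} in {fasta_path} has an empty sequence")
        topo = Topology.CIRCULAR
        if topology and rec.id in topology:
            topo = _coerce_topology(topology[rec.id])
        else:
            log.info("no topology for %s; defaulting to circular", rec.id)
        records.append(ChromosomeRecord(id=rec.id, sequence=seq, topology=topo))
    if not records:
        raise ValueError(f"no FASTA records parsed from {fasta_path}")
    return records


def _attr_values(attrs, *keys: str) -> list[str]:
    out: list[str] = []
    lowered = {k.lower(): k for k in attrs}
    for key in keys:
        real = lowered.get(key.lower())
        if real is not None:
            out.extend(attrs[real])
    return out


def _is_partial(attrs) -> bool:
    for v in _attr_values(attrs, "partial"):
        if v.strip().lower() == "true":
            return True
    for v in _attr_values(attrs, "Note"):
        if PARTIAL_NOTE_MARKER in v.lower():
            return True
    return False


def _rna_type(attrs) -> Optional[RnaType]:
    text = " ".join(_attr_values(attrs, "product", "Name", "gene")).lower()
    if "16s" in text:
        return RnaType.SSU_16S
    if "23s" in text:
        return RnaType.LSU_23S
    return None


def read_rrna_features(gff_path: Union[str, Path]) -> list[RnaFeature]:
    """Return complete (non-partial) 16S/23S rRNA features from a GFF3 file.

    5S genes and every non-rRNA feature type are absent from the output.
    A feature with ``end < start`` or an unknown strand symbol raises.
    """
    features: list[RnaFeature] = []
    for f in DataIterator(str(Path(gff_path))):
        if f.featuretype != "rRNA":
            continue
        rna_type = _rna_type(f.attributes)
        if rna_type is None:
            continue
        if int(f.end) < int(f.start):
            raise ValueError(
                f"rRNA feature on {f.seqid} has end {f.end} < start {f.start}"
            )
        if _is_partial(f.attributes):
            continue
        features.append(
            RnaFeature(
                chrom_id=f.seqid,
                rna_type=rna_type,
                strand=f.strand,
                start=int(f.start),
                end=int(f.end),
                partial=False,
                source="annotation",
            )
        )
    return features


def detect_topology(
    gff_path: Union[str, Path],
    override: Optional[Mapping[str, TopologyLike]] = None,
) -> dict[str, Topology]:
    """Map replicon id to topology from GFF ``region`` features.

    Follows the ``Is_circular=true`` convention; an ``override`` entry wins
    over the file (with a warning when they contradict); replicons with no
    information default to circular, logged.
    """
    from_file: dict[str, Topology] = {}
    seqids: list[str] = []
    for f in DataIterator(str(Path(gff_path))):
        if f.seqid not in seqids:
            seqids.append(f.seqid)
        if f.featuretype != "region":
            continue
        vals = _attr_values(f.attributes, "Is_circular")
        if vals:
            from_file[f.seqid] = (
                Topology.CIRCULAR if vals[0].strip().lower() == "true" else Topology.LINEAR
            )
    result: dict[str, Topology] = {}
    for seqid in seqids:
        if override and seqid in override:
            chosen = _coerce_topology(override[seqid])
            if seqid in from_file and from_file[seqid] != chosen:
                log.warning(
                    "topology override for %s (%s) contradicts file (%s); override wins",
                    seqid, chosen.value, from_file[seqid].value,
                )
            result[seqid] = chosen
        elif seqid in from_file:
            result[seqid] = from_file[seqid]
        else:
            log.info("no topology information for %s; defaulting to circular", seqid)
            result[seqid] = Topology.CIRCULAR
    if override:
        for seqid, topo in override.items():
            result.setdefault(seqid, _coerce_topology(topo))
    return result


def features_to_frame(features: Iterable[RnaFeature]) -> pd.DataFrame:
    """Tabulate features (chrom, type, strand, start, end, partial)."""
    return pd.DataFrame(
        [
            {
                "chrom": f.chrom_id,
                "rna_type": f.rna_type.value,
                "strand": f.strand,
                "start": f.start,
                "end": f.end,
                "partial": f.partial,
            }
            for f in features
        ],
        columns=["chrom", "rna_type", "strand", "start", "end", "partial"],
    )
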