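"""Per-genome genomic feature table.

The five features that separate operon-unlinked symbionts from linked ones
in ordination: whole-genome size, whole-genome AT fraction, 16S copy
number, and the mean lengths of the 16S and 23S genes — plus the mean AT
fraction of the 16S genes themselves and an externally supplied symbiont
label.  Genome size sums every replicon present in the assembly
(chromosomes and plasmids alike).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import math

import pandas as pd

from .annotation_io import ChromosomeRecord, RnaFeature, RnaType
from .insilico_pcr import reverse_complement
from .operon_classifier import GenomeCall, OperonUnit


@dataclass(frozen=True)
class FeatureRow:
    genome_id: str
    genome_size: int
    genome_at: float
    mean_16S_at: float  # NaN when the genome has no 16S
    n16S: int
    mean_16S_len: float  # NaN when absent
    mean_23S_len: float  # NaN when absent
    status: str
    symbiont: str  # "yes", "no", or "unknown"


def at_content(sequence: str) -> float:
    """(A + T) / length, case-insensitive.

    Ambiguity codes contribute to the denominator only: an N is neither A
    nor T, so heavily ambiguous sequence dilutes the AT fraction rather
    than being silently skipped.
    """
    if not sequence:
        raise ValueError("at_content of an empty sequence is undefined")
    s = sequence.upper()
    return (s.count("A") + s.count("T")) / len(s)


def feature_sequence(record: ChromosomeRecord, feature: RnaFeature) -> str:
    """Extract a feature's sequence, reverse-complemented for antisense genes."""
    if feature.chrom_id != record.id:
        raise ValueError(f"feature on {feature.chrom_id} does not belong to {record.id}")
    seq = record.sequence[feature.start - 1 : feature.end]
    return reverse_complement(seq) if feature.strand == "-" else seq


def read_symbiont_labels(path: Union[str, Path]) -> dict[str, str]:
    """Read a genome→symbiont(yes/no) label TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"genome_id", "symbiont"}.issubset(df.columns):
        raise ValueError(f"{path} must have columns genome_id and symbiont")
    return dict(zip(df["genome_id"], df["symbiont"].str.lower()))


def _mean(values: list[float]) -> float:
    return sum(values) / len(values) if values else math.nan


def build_feature_table(
    genomes: Mapping[str, Sequence[ChromosomeRecord]],
    units: Mapping[str, Sequence[OperonUnit]],
    calls: Mapping[str, GenomeCall],
    symbiont_labels: Optional[Mapping[str, str]] = None,
) -> list[FeatureRow]:
    """One row per screened genome.

    Mean gene lengths come from feature coordinates (end − start + 1); the
    symbiont label is joined from the provided table and defaults to
    ``unknown`` for genomes absent from it.
    """
    rows: list[FeatureRow] = []
    for genome_id, records in genomes.items():
        if genome_id not in calls:
            raise KeyError(f"no genome call for {genome_id!r}")
        rec_by_id = {}
        for rec in records:
            if rec.id in rec_by_id:
                raise ValueError(f"duplicate replicon id {rec.id!r} in genome {genome_id!r}")
            rec_by_id[rec.id] = rec
        feats: list[RnaFeature] = []
        for u in units.get(genome_id, []):
            feats.extend(u.features)
        ssu = [f for f in feats if f.rna_type is RnaType.SSU_16S]
        lsu = [f for f in feats if f.rna_type is RnaType.LSU_23S]
        genome_seq_len = sum(r.length for r in records)
        at_num = sum(
            r.sequence.count("A") + r.sequence.count("T") for r in records
        )
        symbiont = "unknown"
        if symbiont_labels is not None and genome_id in symbiont_labels:
            symbiont = str(symbiont_labels[genome_id]).lower()
        rows.append(
            FeatureRow(
                genome_id=genome_id,
                genome_size=genome_seq_len,
                genome_at=at_num / genome_seq_len,
                mean_16S_at=_mean(
                    [at_content(feature_sequence(rec_by_id[f.chrom_id], f)) for f in ssu]
                ),
                n16S=len(ssu),
                mean_16S_len=_mean([float(f.length) for f in ssu]),
                mean_23S_len=_mean([float(f.length) for f in lsu]),
                status=calls[genome_id].status.value,
                symbiont=symbiont,
            )
        )
    return rows


FEATURE_COLUMNS = [
    "genome_id", "genome_size", "genome_at", "mean_16S_at",
    "n16S", "mean_16S_len", "mean_23S_len", "status", "symbiont",
]


def feature_frame(rows: Iterable[FeatureRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "genome_size": r.genome_size,
                "genome_at": r.genome_at,
                "mean_16S_at": r.mean_16S_at,
                "n16S": r.n16S,
                "mean_16S_len": r.mean_16S_len,
                "mean_23S_len": r.mean_23S_len,
                "status": r.status,
                "symbiont": r.symbiont,
            }
            for r in rows
        ],
        columns=FEATURE_COLUMNS,
    )
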