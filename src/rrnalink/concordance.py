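"""Cross-validation of annotated rRNA counts against in silico PCR.

Annotation errors (misassembly, dropped predictions, primer-site variation)
are caught by comparing the per-type counts of annotated 16S/23S genes with
the counts recovered by in silico PCR.  The comparison is escalated: first
with a budget of two mismatches per primer, then — for genomes that
disagree — with four; genomes still discordant after escalation are
excluded from all downstream analyses but retained in the screening report.

The comparison is component-wise on (n16S, n23S), never on totals: genomes
can have equal total counts yet discordant per-type profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotation_io import ChromosomeRecord, RnaFeature, RnaType
from .insilico_pcr import (
    DEFAULT_PRIMER_PAIRS,
    PrimerPair,
    count_rrna_loci,
    predict_amplicons,
)

DEFAULT_MISMATCH_BUDGETS: tuple[int, ...] = (2, 4)


@dataclass(frozen=True)
class ScreeningResult:
    genome_id: str
    annotation_counts: tuple[int, int]  # (n16S, n23S)
    pcr_counts_mm2: tuple[int, int]
    pcr_counts_mm4: Optional[tuple[int, int]]
    verdict: str  # "pass_mm2", "pass_mm4", or "excluded"

    @property
    def passed(self) -> bool:
        return self.verdict != "excluded"


def profile_counts(features: Iterable[RnaFeature]) -> tuple[int, int]:
    """(n16S, n23S) over all replicons of one genome (partials removed upstream)."""
    n16 = n23 = 0
    for f in features:
        if f.rna_type is RnaType.SSU_16S:
            n16 += 1
        else:
            n23 += 1
    return n16, n23


def pcr_profile(
    records: Sequence[ChromosomeRecord],
    primer_pairs: Mapping[RnaType, PrimerPair],
    max_mm: int,
) -> tuple[int, int]:
    """(n16S, n23S) locus counts from in silico PCR at one mismatch budget."""
    counts: dict[RnaType, int] = {}
    for target, pair in primer_pairs.items():
        n = 0
        for rec in records:
            n += count_rrna_loci(predict_amplicons(rec, pair, max_mm))
        counts[target] = n
    return counts.get(RnaType.SSU_16S, 0), counts.get(RnaType.LSU_23S, 0)


def screen_genome(
    genome_id: str,
    records: Sequence[ChromosomeRecord],
    annotation_counts: tuple[int, int],
    primer_pairs: Mapping[RnaType, PrimerPair] = DEFAULT_PRIMER_PAIRS,
    budgets: Sequence[int] = DEFAULT_MISMATCH_BUDGETS,
) -> ScreeningResult:
    """Escalating concordance screen of one genome.

    Budgets must be strictly increasing (default (2, 4)).  Passing at the
    first budget is ``pass_mm2``; passing only after escalation is
    ``pass_mm4``; still-discordant genomes are ``excluded``.
    """
    if list(budgets) != sorted(set(budgets)):
        raise ValueError("mismatch budgets must be strictly increasing")
    profiles = []
    verdict = "excluded"
    for level, budget in enumerate(budgets):
        prof = pcr_profile(records, primer_pairs, budget)
        profiles.append(prof)
        if prof == tuple(annotation_counts):
            verdict = "pass_mm2" if level == 0 else "pass_mm4"
            break
    mm2 = profiles[0]
    mm4 = profiles[1] if len(profiles) > 1 else None
    return ScreeningResult(
        genome_id=genome_id,
        annotation_counts=tuple(annotation_counts),
        pcr_counts_mm2=mm2,
        pcr_counts_mm4=mm4,
        verdict=verdict,
    )


def screening_to_frame(results: Iterable[ScreeningResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        mm4 = r.pcr_counts_mm4
        rows.append(
            {
                "genome_id": r.genome_id,
                "n16S_annot": r.annotation_counts[0],
                "n23S_annot": r.annotation_counts[1],
                "n16S_mm2": r.pcr_counts_mm2[0],
                "n23S_mm2": r.pcr_counts_mm2[1],
                "n16S_mm4": mm4[0] if mm4 is not None else pd.NA,
                "n23S_mm4": mm4[1] if mm4 is not None else pd.NA,
                "verdict": r.verdict,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "n16S_annot", "n23S_annot", "n16S_mm2", "n23S_mm2",
            "n16S_mm4", "n23S_mm4", "verdict",
        ],
    )
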