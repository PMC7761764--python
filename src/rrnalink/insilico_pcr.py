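"""In silico PCR with degenerate primers.

Predicts 16S and 23S rRNA amplicons from genome sequence using the
universal primer pairs 27F/1492R (16S) and 11a/2241r (23S), an absolute
per-primer mismatch budget, and strict product-length windows
(1000 bp < 16S product < 4000 bp; 1000 bp < 23S product < 6800 bp).

Matching semantics: a primer position written as an IUPAC ambiguity code
matches any base in the code's set; a genome base outside {A,C,G,T}
(e.g. N) always counts as a mismatch.  The search runs on the linearized
sequence — no origin-spanning products are generated, so a genome whose
only rRNA crosses the replicon origin would fail downstream concordance
screening (documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .annotation_io import ChromosomeRecord, RnaType

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# Degenerate-aware complement: R<->Y, K<->M, B<->V, D<->H; S/W/N are self.
_COMPLEMENT = str.maketrans("ACGTRYKMBVDHSWN", "TGCAYRMKVBHDSWN")

# _MISMATCH_LUT[code][byte] == 1 when the genome byte is NOT in the code's set.
_MISMATCH_LUT: dict[str, np.ndarray] = {}
for _code, _allowed in IUPAC_SETS.items():
    _tab = np.ones(256, dtype=np.int16)
    for _b in _allowed:
        _tab[ord(_b)] = 0
    _MISMATCH_LUT[_code] = _tab


def reverse_complement(seq: str) -> str:
    """Reverse complement, handling degenerate IUPAC codes."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Primer:
    name: str
    iupac_seq: str

    def __post_init__(self) -> None:
        if not self.iupac_seq:
            raise ValueError(f"primer {self.name!r} has an empty sequence")
        bad = set(self.iupac_seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"primer {self.name!r} has non-IUPAC characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.iupac_seq)


@dataclass(frozen=True)
class PrimerPair:
    target: RnaType
    forward: Primer
    reverse: Primer
    min_product_len: int  # exclusive lower bound
    max_product_len: int  # exclusive upper bound

    def __post_init__(self) -> None:
        if self.min_product_len >= self.max_product_len:
            raise ValueError("min_product_len must be < max_product_len")


PAIR_16S = PrimerPair(
    target=RnaType.SSU_16S,
    forward=Primer("27F", "AGRGTTYGATYHTGGCTCAG"),
    reverse=Primer("1492R", "TACCTTGTTAYGACTT"),
    min_product_len=1000,
    max_product_len=4000,
)

PAIR_23S = PrimerPair(
    target=RnaType.LSU_23S,
    forward=Primer("11a", "GGAACTGAAACATCTAAGTA"),
    reverse=Primer("2241r", "ACCRCCCCAGTHAAACT"),
    min_product_len=1000,
    max_product_len=6800,
)

DEFAULT_PRIMER_PAIRS: dict[RnaType, PrimerPair] = {
    RnaType.SSU_16S: PAIR_16S,
    RnaType.LSU_23S: PAIR_23S,
}


class PrimerSite(NamedTuple):
    position: int  # 1-based left end of the matched window
    orientation: str  # "forward" (primer on stored strand) or "reverse"
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    chrom_id: str
    target: RnaType
    start: int  # 1-based, 5' end of the forward primer site
    end: int  # 1-based, 3' end of the reverse primer site
    strand: str  # product orientation relative to the stored sequence
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def iupac_mismatches(primer_window: str, genome_window: str) -> int:
    """Count primer/genome mismatches under IUPAC set membership."""
    if len(primer_window) != len(genome_window):
        raise ValueError(
            f"window length mismatch: primer {len(primer_window)} vs genome {len(genome_window)}"
        )
    n = 0
    for p, g in zip(primer_window, genome_window):
        try:
            allowed = IUPAC_SETS[p]
        except KeyError:
            raise ValueError(f"non-IUPAC primer character {p!r}") from None
        if g not in allowed:
            n += 1
    return n


def _scan_pattern(seq_arr: np.ndarray, pattern: str, max_mm: int) -> list[tuple[int, int]]:
    """All (0-based position, mismatches) where pattern matches with <= max_mm."""
    L = len(pattern)
    m = seq_arr.size - L + 1
    if m <= 0:
        return []
    mm = np.zeros(m, dtype=np.int16)
    for j, code in enumerate(pattern):
        mm += _MISMATCH_LUT[code][seq_arr[j : j + m]]
    idx = np.flatnonzero(mm <= max_mm)
    return [(int(i), int(mm[i])) for i in idx]


def _as_bytes(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)


def find_primer_sites(
    chrom: ChromosomeRecord, primer: Primer, max_mm: int
) -> list[PrimerSite]:
    """All windows matching ``primer`` (forward) or its reverse complement
    (reverse) with at most ``max_mm`` mismatches; positions are 1-based at
    the window's left end.  A primer longer than the chromosome yields an
    empty list.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    arr = _as_bytes(chrom.sequence)
    sites = [
        PrimerSite(pos + 1, "forward", mm)
        for pos, mm in _scan_pattern(arr, primer.iupac_seq, max_mm)
    ]
    rc = reverse_complement(primer.iupac_seq)
    sites += [
        PrimerSite(pos + 1, "reverse", mm) for pos, mm in _scan_pattern(arr, rc, max_mm)
    ]
    sites.sort()
    return sites


def predict_amplicons(
    chrom: ChromosomeRecord, pair: PrimerPair, max_mm: int
) -> list[Amplicon]:
    """Predict PCR products for one primer pair on one replicon.

    A plus-strand product pairs a forward-orientation forward-primer site
    with a downstream reverse-orientation reverse-primer site; a
    minus-strand product is the symmetric arrangement.  Only products
    strictly inside the pair's length window survive.
    """
    arr = _as_bytes(chrom.sequence)
    f_len, r_len = len(pair.forward), len(pair.reverse)

    fwd_fwd = _scan_pattern(arr, pair.forward.iupac_seq, max_mm)
    rev_rev = _scan_pattern(arr, reverse_complement(pair.reverse.iupac_seq), max_mm)
    rev_fwd = _scan_pattern(arr, pair.reverse.iupac_seq, max_mm)
    fwd_rev = _scan_pattern(arr, reverse_complement(pair.forward.iupac_seq), max_mm)

    out: list[Amplicon] = []
    for fpos, fmm in fwd_fwd:
        for rpos, rmm in rev_rev:
            if rpos < fpos:
                continue
            start, end = fpos + 1, rpos + r_len
            length = end - start + 1
            if pair.min_product_len < length < pair.max_product_len:
                out.append(
                    Amplicon(chrom.id, pair.target, start, end, "+", fmm, rmm)
                )
    for rpos, rmm in rev_fwd:
        for fpos, fmm in fwd_rev:
            if fpos < rpos:
                continue
            start, end = rpos + 1, fpos + f_len
            length = end - start + 1
            if pair.min_product_len < length < pair.max_product_len:
                out.append(
                    Amplicon(chrom.id, pair.target, start, end, "-", fmm, rmm)
                )
    out.sort(key=lambda a: (a.chrom_id, a.start, a.end, a.strand))
    return out


def count_rrna_loci(amplicons: Sequence[Amplicon]) -> int:
    """Number of distinct loci after merging redundant amplicons.

    Amplicons on the same chromosome whose intervals reciprocally overlap
    by at least 50% are merged into one locus (transitively).
    """
    if not amplicons:
        return 0
    targets = {a.target for a in amplicons}
    if len(targets) > 1:
        raise ValueError("count_rrna_loci expects amplicons of a single target type")

    parent = list(range(len(amplicons)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(len(amplicons)):
        for j in range(i + 1, len(amplicons)):
            a, b = amplicons[i], amplicons[j]
            if a.chrom_id != b.chrom_id:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start) + 1
            if ov <= 0:
                continue
            if ov >= 0.5 * a.length and ov >= 0.5 * b.length:
                union(i, j)
    return len({find(i) for i in range(len(amplicons))})


def amplicons_to_frame(amplicons: Iterable[Amplicon]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": a.chrom_id,
                "target": a.target.value,
                "start": a.start,
                "end": a.end,
                "strand": a.strand,
                "length": a.length,
                "fwd_mm": a.fwd_mismatches,
                "rev_mm": a.rev_mismatches,
            }
            for a in amplicons
        ],
        columns=["chrom", "target", "start", "end", "strand", "length", "fwd_mm", "rev_mm"],
    )
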