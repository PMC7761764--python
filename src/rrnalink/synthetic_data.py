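"""Synthetic bacterial genomes with known rRNA operon structure.

Generates FASTA + GFF3 cohorts covering every configuration the pipeline
must handle — linked, unlinked, antisense and origin-spanning operons,
lone 16S/23S copies, partially annotated genes, primer-site mutations and
annotation/sequence count discordances — together with a ground-truth
manifest of the expected features, ITS lengths, unit linkages, genome
calls and screening verdicts.

Design notes:

* rRNA gene templates embed exact realizations of the universal primer
  sites (27F/1492R for 16S, 11a/2241r for 23S), so concordance screening
  fails only when a failure is explicitly planted.
* The background sequence is sanitized: any window matching a primer at
  up to four mismatches outside a planted site is resampled.  Short
  reverse primers (16–17 nt) otherwise match random sequence at budget
  four often enough to perturb locus counts.
* Interior gene sequence is uniform pseudo-random at a configurable AT
  fraction; no rRNA secondary structure is attempted.
* Everything is deterministic given the spec's seed; identical spec +
  seed reproduce byte-identical files.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation_io import ChromosomeRecord, RnaType, Topology
from .insilico_pcr import (
    DEFAULT_PRIMER_PAIRS,
    IUPAC_SETS,
    _scan_pattern,
    reverse_complement,
)

ITS_TRUTH_THRESHOLD = 1500  # bp; the published linkage criterion

# default gene lengths; per-genome values live on ScenarioSpec
TEMPLATE_LENGTH = {RnaType.SSU_16S: 1550, RnaType.LSU_23S: 2900}
UNIT_SPACING = 2000  # minimum bp between planted units
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

PAIR_KINDS = {"linked_pair", "unlinked_pair", "antisense_pair", "wraparound_pair"}
SINGLE_KINDS = {"single_16S", "single_23S"}
LAYOUT_KINDS = PAIR_KINDS | SINGLE_KINDS


@dataclass
class OperonLayout:
    """One planted operon unit (or lone rRNA copy)."""

    kind: str
    its: Optional[int] = None  # pairs only; gap between gene bodies
    strand: Optional[str] = None  # default: '+', '-' for antisense_pair / single_23S
    chromosome: int = 0
    tail_gap: Optional[int] = None  # wraparound: bp between upstream gene end and origin

    def __post_init__(self) -> None:
        if self.kind not in LAYOUT_KINDS:
            raise ValueError(f"unknown layout kind {self.kind!r}")
        if self.strand is None:
            if self.kind == "antisense_pair":
                self.strand = "-"
            elif self.kind == "single_23S":
                self.strand = "-"
            else:
                self.strand = "+"
        if self.kind in PAIR_KINDS:
            if self.its is None:
                self.its = 5000 if self.kind == "unlinked_pair" else 400
            if self.kind == "linked_pair" and self.its > ITS_TRUTH_THRESHOLD:
                raise ValueError("linked_pair layout requires its <= 1500")
            if self.kind == "unlinked_pair" and self.its <= ITS_TRUTH_THRESHOLD:
                raise ValueError("unlinked_pair layout requires its > 1500")


@dataclass
class ScenarioSpec:
    """Full description of one synthetic genome."""

    genome_id: str
    chromosomes: list[tuple[int, Topology]]
    layouts: list[OperonLayout]
    primer_site_mutations: dict[str, int] = field(default_factory=dict)
    partial_annotations: Sequence[int] = ()
    annotation_errors: str = "none"  # none | missing_feature | extra_feature
    at_fraction: float = 0.50
    rrna_at_fraction: float = 0.45
    len_16S: int = TEMPLATE_LENGTH[RnaType.SSU_16S]
    len_23S: int = TEMPLATE_LENGTH[RnaType.LSU_23S]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.annotation_errors not in ("none", "missing_feature", "extra_feature"):
            raise ValueError(f"unknown annotation_errors {self.annotation_errors!r}")
        if self.len_16S < 100 or self.len_23S < 100:
            raise ValueError("gene lengths must exceed the primer footprints")

    @property
    def gene_lengths(self) -> dict[RnaType, int]:
        return {RnaType.SSU_16S: self.len_16S, RnaType.LSU_23S: self.len_23S}


@dataclass
class PlantedSite:
    primer_name: str
    start: int  # 1-based, stored strand
    end: int
    pattern: str  # degenerate pattern as it appears on the stored strand
    n_subs: int = 0


@dataclass
class PlantedFeature:
    chrom_id: str
    chrom_idx: int
    rna_type: RnaType
    strand: str
    start: int
    end: int
    sites: list[PlantedSite]
    partial: bool = False
    annotated: bool = True
    genuine: bool = True  # present in the sequence (extra annotations are not)
    layout_idx: Optional[int] = None

    @property
    def planted_mm(self) -> int:
        return max((s.n_subs for s in self.sites), default=0)


@dataclass
class UnitTruth:
    kind: str  # "pair" or "single"
    linkage: str  # linked | unlinked | single
    its: Optional[int]
    wrapped: bool
    strand: str


@dataclass
class GenomeTruth:
    genome_id: str
    class_label: str
    status: str
    n_linked: int
    n_unlinked: int
    n_singles: int
    verdict: str
    n16S_annot: int
    n23S_annot: int
    symbiont: Optional[str] = None


@dataclass
class SimulatedGenome:
    spec: ScenarioSpec
    records: list[ChromosomeRecord]
    features: list[PlantedFeature]  # sorted by (chrom_idx, start)
    decoys: list[tuple[str, int, int, str]]  # 5S annotations: (chrom, start, end, strand)
    units: list[UnitTruth]
    truth: GenomeTruth


# ---------------------------------------------------------------------------
# sequence building blocks

def _random_bases(n: int, at: float, rng: np.random.Generator) -> np.ndarray:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return rng.choice(_BASES, size=n, p=p)


def _realize(pattern: str, rng: np.random.Generator) -> str:
    out = []
    for code in pattern:
        opts = sorted(IUPAC_SETS[code])
        out.append(opts[rng.integers(len(opts))])
    return "".join(out)


@dataclass
class _Template:
    seq: str
    sites: list[tuple[str, int, int, str]]  # (primer_name, rel0_start, rel0_end, pattern)


def build_rrna_template(
    rna_type: RnaType,
    rng: np.random.Generator,
    at_fraction: float = 0.45,
    length: Optional[int] = None,
) -> _Template:
    """A gene template carrying exact primer binding sites at both ends.

    16S: ~1550 bp opening with a realization of the 27F site and closing
    with the reverse complement of a 1492R realization; 23S: ~2900 bp
    analogously for 11a/2241r.  By construction each template yields
    exactly one in silico product inside its pair's length window.
    """
    pair = DEFAULT_PRIMER_PAIRS[rna_type]
    total = length if length is not None else TEMPLATE_LENGTH[rna_type]
    fwd = _realize(pair.forward.iupac_seq, rng)
    rev_site_pattern = reverse_complement(pair.reverse.iupac_seq)
    rev = reverse_complement(_realize(pair.reverse.iupac_seq, rng))
    interior_len = total - len(fwd) - len(rev)
    interior = _random_bases(interior_len, at_fraction, rng).tobytes().decode("ascii")
    seq = fwd + interior + rev
    sites = [
        (pair.forward.name, 0, len(fwd) - 1, pair.forward.iupac_seq),
        (pair.reverse.name, total - len(rev), total - 1, rev_site_pattern),
    ]
    return _Template(seq=seq, sites=sites)


def _oriented_gene(
    rna_type: RnaType,
    strand: str,
    rng: np.random.Generator,
    at: float,
    length: Optional[int] = None,
) -> tuple[str, list[tuple[str, int, int, str]]]:
    """Template sequence and site intervals as stored on the chromosome strand."""
    tpl = build_rrna_template(rna_type, rng, at, length=length)
    if strand == "+":
        return tpl.seq, tpl.sites
    L = len(tpl.seq)
    seq = reverse_complement(tpl.seq)
    sites = [
        (name, L - 1 - e, L - 1 - s, reverse_complement(pat))
        for name, s, e, pat in tpl.sites
    ]
    return seq, sites


# ---------------------------------------------------------------------------
# genome assembly

@dataclass
class _Placement:
    rna_type: RnaType
    strand: str
    start: int  # 1-based
    layout_idx: int


def _layout_placements(
    layout: OperonLayout, layout_idx: int, cursor: int, gene_len: dict[RnaType, int]
) -> tuple[list[_Placement], int]:
    """Gene placements for a non-wraparound layout starting at ``cursor``."""
    if layout.kind in ("linked_pair", "unlinked_pair", "antisense_pair"):
        if layout.strand == "+":
            first, second = RnaType.SSU_16S, RnaType.LSU_23S
        else:
            first, second = RnaType.LSU_23S, RnaType.SSU_16S
        p1 = _Placement(first, layout.strand, cursor, layout_idx)
        p2 = _Placement(
            second, layout.strand, cursor + gene_len[first] + layout.its, layout_idx
        )
        end = p2.start + gene_len[second] - 1
        return [p1, p2], end
    rna = RnaType.SSU_16S if layout.kind == "single_16S" else RnaType.LSU_23S
    p = _Placement(rna, layout.strand, cursor, layout_idx)
    return [p], cursor + gene_len[rna] - 1


def _wrap_placements(
    layout: OperonLayout, layout_idx: int, chrom_len: int, gene_len: dict[RnaType, int]
) -> tuple[list[_Placement], int, int]:
    """Placements for an origin-spanning pair.

    Returns (placements, head_end, tail_start): the downstream gene sits at
    the replicon head, the upstream gene at the tail, and the wrapped ITS
    equals the layout's ``its``.
    """
    its = layout.its
    a = layout.tail_gap if layout.tail_gap is not None else its // 2
    if not 0 <= a <= its:
        raise ValueError(f"tail_gap {a} outside [0, its={its}]")
    s2 = its - a + 1  # downstream gene start (head)
    if layout.strand == "+":
        up_type, down_type = RnaType.SSU_16S, RnaType.LSU_23S
    else:
        up_type, down_type = RnaType.LSU_23S, RnaType.SSU_16S
    up_len = gene_len[up_type]
    down_len = gene_len[down_type]
    up_start = chrom_len - a - up_len + 1
    if up_start <= s2 + down_len - 1:
        raise ValueError("chromosome too short for wraparound layout")
    placements = [
        _Placement(down_type, layout.strand, s2, layout_idx),
        _Placement(up_type, layout.strand, up_start, layout_idx),
    ]
    return placements, s2 + down_len - 1, up_start


def _sanitize_background(
    arr: np.ndarray,
    whitelist: list[tuple[int, int]],  # 0-based inclusive intervals to preserve
    at: float,
    rng: np.random.Generator,
    max_iter: int = 30,
) -> None:
    """Resample windows that match any primer at <= 4 mismatches outside
    planted sites, so screening outcomes are fully controlled."""
    patterns = []
    for pair in DEFAULT_PRIMER_PAIRS.values():
        for primer in (pair.forward, pair.reverse):
            patterns.append(primer.iupac_seq)
            patterns.append(reverse_complement(primer.iupac_seq))

    def overlaps_whitelist(s: int, e: int) -> bool:
        return any(s <= we and ws <= e for ws, we in whitelist)

    for _ in range(max_iter):
        offenders: list[tuple[int, int]] = []
        for pattern in patterns:
            for pos, _mm in _scan_pattern(arr, pattern, 4):
                s, e = pos, pos + len(pattern) - 1
                if not overlaps_whitelist(s, e):
                    offenders.append((s, e))
        if not offenders:
            return
        for s, e in offenders:
            arr[s : e + 1] = _random_bases(e - s + 1, at, rng)
    raise RuntimeError("background sanitization did not converge")


# ---------------------------------------------------------------------------
# truth derivation (compact re-statement of the documented pairing rules)

def _truth_pairable(a: PlantedFeature, b: PlantedFeature) -> bool:
    if a.strand != b.strand:
        return False
    if a.strand == "+":
        return a.rna_type is RnaType.SSU_16S and b.rna_type is RnaType.LSU_23S
    return a.rna_type is RnaType.LSU_23S and b.rna_type is RnaType.SSU_16S


def _truth_units(
    feats: list[PlantedFeature], topology: Topology, chrom_len: int
) -> list[UnitTruth]:
    feats = sorted(feats, key=lambda f: (f.start, f.end, f.rna_type.value))
    n = len(feats)
    taken = [False] * n
    units: list[UnitTruth] = []
    k = 0
    while k < n - 1:
        if _truth_pairable(feats[k], feats[k + 1]):
            gap = max(feats[k + 1].start - feats[k].end - 1, 0)
            units.append(
                UnitTruth(
                    kind="pair",
                    linkage="linked" if gap <= ITS_TRUTH_THRESHOLD else "unlinked",
                    its=gap,
                    wrapped=False,
                    strand=feats[k].strand,
                )
            )
            taken[k] = taken[k + 1] = True
            k += 2
        else:
            k += 1
    if (
        topology is Topology.CIRCULAR
        and n >= 2
        and not taken[-1]
        and not taken[0]
        and _truth_pairable(feats[-1], feats[0])
    ):
        gap = (chrom_len - feats[-1].end) + (feats[0].start - 1)
        units.append(
            UnitTruth(
                kind="pair",
                linkage="linked" if gap <= ITS_TRUTH_THRESHOLD else "unlinked",
                its=gap,
                wrapped=True,
                strand=feats[-1].strand,
            )
        )
        taken[-1] = taken[0] = True
    for k, f in enumerate(feats):
        if not taken[k]:
            units.append(UnitTruth("single", "single", None, False, f.strand))
    return units


def _status_from_units(units: list[UnitTruth]) -> tuple[str, int, int, int]:
    n_linked = sum(1 for u in units if u.linkage == "linked")
    n_unlinked = sum(1 for u in units if u.linkage == "unlinked")
    n_singles = sum(1 for u in units if u.kind == "single")
    if not units:
        status = "undetermined"
    elif n_unlinked == 0 and n_singles == 0:
        status = "linked"
    elif n_linked == 0:
        status = "unlinked"
    else:
        status = "mixed"
    return status, n_linked, n_unlinked, n_singles


# ---------------------------------------------------------------------------
# main generator

def simulate_genome(spec: ScenarioSpec, class_label: str = "", symbiont: Optional[str] = None) -> SimulatedGenome:
    """Build one genome (sequences + planted annotation + truth) from a spec."""
    rng = np.random.default_rng(spec.seed)
    n_chrom = len(spec.chromosomes)
    chrom_ids = [f"{spec.genome_id}_chr{i + 1}" for i in range(n_chrom)]

    placements: list[list[_Placement]] = [[] for _ in range(n_chrom)]
    for ci, (chrom_len, topology) in enumerate(spec.chromosomes):
        layouts = [
            (li, l) for li, l in enumerate(spec.layouts) if l.chromosome == ci
        ]
        wraps = [(li, l) for li, l in layouts if l.kind == "wraparound_pair"]
        if len(wraps) > 1:
            raise ValueError("at most one wraparound layout per chromosome")
        cursor = 1000
        tail_limit = chrom_len - 1000
        if wraps:
            li, wl = wraps[0]
            if topology is not Topology.CIRCULAR:
                raise ValueError("wraparound layout requires a circular chromosome")
            wplace, head_end, tail_start = _wrap_placements(wl, li, chrom_len, spec.gene_lengths)
            placements[ci].extend(wplace)
            cursor = head_end + UNIT_SPACING
            tail_limit = tail_start - UNIT_SPACING
        for li, layout in layouts:
            if layout.kind == "wraparound_pair":
                continue
            cursor += UNIT_SPACING + int(rng.integers(0, 2001))
            placed, end = _layout_placements(layout, li, cursor, spec.gene_lengths)
            if end > tail_limit:
                raise ValueError(
                    f"layout overflow on {chrom_ids[ci]}: unit ends at {end}, "
                    f"limit {tail_limit}"
                )
            placements[ci].extend(placed)
            cursor = end

    # assemble sequences
    arrays: list[np.ndarray] = []
    features: list[PlantedFeature] = []
    decoys: list[tuple[str, int, int, str]] = []
    free_cursor: list[int] = []
    for ci, (chrom_len, topology) in enumerate(spec.chromosomes):
        arr = _random_bases(chrom_len, spec.at_fraction, rng)
        whitelist: list[tuple[int, int]] = []
        last_end = 0
        for pl in sorted(placements[ci], key=lambda p: p.start):
            seq, rel_sites = _oriented_gene(
                pl.rna_type, pl.strand, rng, spec.rrna_at_fraction,
                length=spec.gene_lengths[pl.rna_type],
            )
            s0 = pl.start - 1
            arr[s0 : s0 + len(seq)] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            sites = [
                PlantedSite(name, pl.start + rs, pl.start + re_, pat)
                for name, rs, re_, pat in rel_sites
            ]
            whitelist.extend((s.start - 1, s.end - 1) for s in sites)
            features.append(
                PlantedFeature(
                    chrom_id=chrom_ids[ci],
                    chrom_idx=ci,
                    rna_type=pl.rna_type,
                    strand=pl.strand,
                    start=pl.start,
                    end=pl.start + len(seq) - 1,
                    sites=sites,
                    layout_idx=pl.layout_idx,
                )
            )
            last_end = max(last_end, pl.start + len(seq) - 1)
        _sanitize_background(arr, whitelist, spec.at_fraction, rng)
        arrays.append(arr)
        free_cursor.append(last_end + UNIT_SPACING + 1)

    # 5S decoy annotations trail each sense 23S (annotation only; the reader
    # must drop them)
    for f in features:
        if f.rna_type is RnaType.LSU_23S and f.strand == "+":
            s5 = f.end + 80
            e5 = s5 + 119
            if e5 <= spec.chromosomes[f.chrom_idx][0]:
                decoys.append((f.chrom_id, s5, e5, "+"))

    # planted primer-site mutations: substitutions guaranteed to mismatch
    for primer_name, n_subs in spec.primer_site_mutations.items():
        hit = False
        for f in features:
            for site in f.sites:
                if site.primer_name != primer_name:
                    continue
                hit = True
                site_len = site.end - site.start + 1
                offs = rng.choice(site_len, size=n_subs, replace=False)
                for off in offs:
                    code = site.pattern[int(off)]
                    options = sorted(set("ACGT") - IUPAC_SETS[code])
                    base = options[rng.integers(len(options))]
                    arrays[f.chrom_idx][site.start - 1 + int(off)] = ord(base)
                site.n_subs = int(n_subs)
        if not hit:
            raise ValueError(f"no planted site for primer {primer_name!r}")

    features.sort(key=lambda f: (f.chrom_idx, f.start, f.end, f.rna_type.value))

    # annotation perturbations (GFF only; the sequence is untouched)
    for idx in spec.partial_annotations:
        features[idx].partial = True
    if spec.annotation_errors == "missing_feature":
        features[-1].annotated = False
    elif spec.annotation_errors == "extra_feature":
        ci = 0
        chrom_len = spec.chromosomes[0][0]
        start = free_cursor[0]
        end = start + spec.gene_lengths[RnaType.SSU_16S] - 1
        if end > chrom_len - 1000:
            raise ValueError("no room for the extra annotation")
        features.append(
            PlantedFeature(
                chrom_id=chrom_ids[ci],
                chrom_idx=ci,
                rna_type=RnaType.SSU_16S,
                strand="+",
                start=start,
                end=end,
                sites=[],
                annotated=True,
                genuine=False,
            )
        )
        features.sort(key=lambda f: (f.chrom_idx, f.start, f.end, f.rna_type.value))

    records = [
        ChromosomeRecord(
            id=chrom_ids[ci],
            sequence=arrays[ci].tobytes().decode("ascii"),
            topology=spec.chromosomes[ci][1],
        )
        for ci in range(n_chrom)
    ]

    # ---- truth ----
    visible = [f for f in features if f.annotated and not f.partial]
    units: list[UnitTruth] = []
    for ci, (chrom_len, topology) in enumerate(spec.chromosomes):
        units.extend(
            _truth_units([f for f in visible if f.chrom_idx == ci], topology, chrom_len)
        )
    status, n_linked, n_unlinked, n_singles = _status_from_units(units)

    clean = (
        spec.annotation_errors == "none"
        and not spec.partial_annotations
    )
    if clean:
        _check_intent(spec, units)

    ann = Counter(f.rna_type for f in visible)
    genuine = [f for f in features if f.genuine]
    mm2 = Counter(f.rna_type for f in genuine if f.planted_mm <= 2)
    mm4 = Counter(f.rna_type for f in genuine if f.planted_mm <= 4)
    ann_t = (ann[RnaType.SSU_16S], ann[RnaType.LSU_23S])
    mm2_t = (mm2[RnaType.SSU_16S], mm2[RnaType.LSU_23S])
    mm4_t = (mm4[RnaType.SSU_16S], mm4[RnaType.LSU_23S])
    if ann_t == mm2_t:
        verdict = "pass_mm2"
    elif ann_t == mm4_t:
        verdict = "pass_mm4"
    else:
        verdict = "excluded"

    truth = GenomeTruth(
        genome_id=spec.genome_id,
        class_label=class_label,
        status=status,
        n_linked=n_linked,
        n_unlinked=n_unlinked,
        n_singles=n_singles,
        verdict=verdict,
        n16S_annot=ann_t[0],
        n23S_annot=ann_t[1],
        symbiont=symbiont,
    )
    return SimulatedGenome(spec, records, features, decoys, units, truth)


def _check_intent(spec: ScenarioSpec, units: list[UnitTruth]) -> None:
    """Layouts must map one-to-one onto derived units; otherwise the spec
    created an ambiguous adjacency (e.g. two lone copies that pair)."""
    expected: list[tuple[str, Optional[int], bool]] = []
    for l in spec.layouts:
        if l.kind in PAIR_KINDS:
            expected.append(("pair", l.its, l.kind == "wraparound_pair"))
        else:
            expected.append(("single", None, False))
    got = sorted((u.kind, u.its, u.wrapped) for u in units)
    if got != sorted(expected):
        raise ValueError(
            f"{spec.genome_id}: layouts produce ambiguous adjacencies; "
            f"expected units {sorted(expected)}, derived {got}"
        )


# ---------------------------------------------------------------------------
# file output

def write_genome_files(sim: SimulatedGenome, outdir: Union[str, Path]) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gid = sim.spec.genome_id
    fna = outdir / f"{gid}.fna"
    gff = outdir / f"{gid}.gff"

    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in sim.records],
        str(fna),
        "fasta",
    )

    lines = ["##gff-version 3"]
    for r in sim.records:
        lines.append(f"##sequence-region {r.id} 1 {r.length}")
    for r in sim.records:
        circ = "true" if r.topology is Topology.CIRCULAR else "false"
        lines.append(
            f"{r.id}\trrnalink_sim\tregion\t1\t{r.length}\t.\t+\t.\t"
            f"ID=region-{r.id};Is_circular={circ}"
        )
    i = 0
    for f in sim.features:
        if not f.annotated:
            continue
        i += 1
        attrs = f"ID=rrna-{gid}-{i};product={f.rna_type.value} ribosomal RNA"
        if f.partial:
            attrs += ";partial=true;Note=rRNA prediction is too short"
        lines.append(
            f"{f.chrom_id}\trrnalink_sim\trRNA\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}"
        )
    for chrom, s, e, strand in sim.decoys:
        i += 1
        lines.append(
            f"{chrom}\trrnalink_sim\trRNA\t{s}\t{e}\t.\t{strand}\t.\t"
            f"ID=rrna-{gid}-{i};product=5S ribosomal RNA"
        )
    gff.write_text("\n".join(lines) + "\n")
    return fna, gff


def manifest_frame(genomes: Sequence[SimulatedGenome]) -> pd.DataFrame:
    rows = []
    for g in genomes:
        t = g.truth
        rows.append(
            {
                "genome_id": t.genome_id,
                "class_label": t.class_label,
                "expected_status": t.status,
                "n_linked": t.n_linked,
                "n_unlinked": t.n_unlinked,
                "n_singles": t.n_singles,
                "expected_verdict": t.verdict,
                "n16S_annot": t.n16S_annot,
                "n23S_annot": t.n23S_annot,
                "symbiont": t.symbiont if t.symbiont is not None else "",
                "genome_size": sum(r.length for r in g.records),
                "at_fraction": g.spec.at_fraction,
            }
        )
    return pd.DataFrame(rows)


def features_manifest_frame(genomes: Sequence[SimulatedGenome]) -> pd.DataFrame:
    rows = []
    for g in genomes:
        for f in g.features:
            rows.append(
                {
                    "genome_id": g.spec.genome_id,
                    "chrom": f.chrom_id,
                    "rna_type": f.rna_type.value,
                    "strand": f.strand,
                    "start": f.start,
                    "end": f.end,
                    "partial": f.partial,
                    "annotated": f.annotated,
                    "genuine": f.genuine,
                }
            )
    return pd.DataFrame(rows)


def write_cohort(
    genomes: Sequence[SimulatedGenome], outdir: Union[str, Path]
) -> Path:
    """Write per-genome FASTA/GFF plus manifest.tsv, features_manifest.tsv
    and labels.tsv (for genomes carrying a symbiont label)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        write_genome_files(g, outdir)
    manifest_frame(genomes).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    features_manifest_frame(genomes).to_csv(
        outdir / "features_manifest.tsv", sep="\t", index=False
    )
    labeled = [g for g in genomes if g.truth.symbiont is not None]
    pd.DataFrame(
        [{"genome_id": g.spec.genome_id, "symbiont": g.truth.symbiont} for g in labeled],
        columns=["genome_id", "symbiont"],
    ).to_csv(outdir / "labels.tsv", sep="\t", index=False)
    return outdir


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortParams:
    """Class-conditional study conditions for the linked/mixed/unlinked cohort.

    AT fractions are the reported class means (51.4 / 50.1 / 64.9 %);
    genome sizes are the class means scaled to desk scale (1/10).
    """

    size_mean: tuple[float, float, float] = (386_000.0, 300_000.0, 168_000.0)
    size_sd_frac: float = 0.10
    at_mean: tuple[float, float, float] = (0.514, 0.501, 0.649)
    at_sd: float = 0.02
    rrna_at_mean: tuple[float, float, float] = (0.45, 0.45, 0.52)
    rrna_at_sd: float = 0.01
    symbiont_prob: tuple[float, float, float] = (0.5, 0.5, 0.75)
    # per-genome gene lengths (bp); unlinked genomes drift slightly shorter
    len16_mean: tuple[float, float, float] = (1550.0, 1548.0, 1530.0)
    len23_mean: tuple[float, float, float] = (2900.0, 2898.0, 2880.0)
    len_sd: float = 15.0


COHORT_CLASSES = ("linked", "mixed", "unlinked")


def _cohort_layouts(cls: str, rng: np.random.Generator) -> list[OperonLayout]:
    def linked(strand: str = "+") -> OperonLayout:
        kind = "linked_pair" if strand == "+" else "antisense_pair"
        return OperonLayout(kind, its=int(rng.integers(300, 601)), strand=strand)

    def unlinked() -> OperonLayout:
        return OperonLayout("unlinked_pair", its=int(rng.integers(3000, 8001)))

    if cls == "linked":
        k = int(rng.integers(2, 5))
        return [linked("-" if rng.random() < 0.3 else "+") for _ in range(k)]
    if cls == "mixed":
        return [linked() for _ in range(int(rng.integers(1, 3)))] + [
            unlinked() for _ in range(int(rng.integers(1, 3)))
        ]
    u = rng.random()
    if u < 0.5:
        return [unlinked()]
    if u < 0.8:
        return [unlinked(), unlinked()]
    return [OperonLayout("single_16S", strand="+"), OperonLayout("single_23S", strand="-")]


def simulate_cohort(
    n_per_class: tuple[int, int, int] = (5, 5, 5),
    seed: int = 0,
    outdir: Optional[Union[str, Path]] = None,
    params: CohortParams = CohortParams(),
) -> list[SimulatedGenome]:
    """A cohort of linked/mixed/unlinked genomes with class-conditional
    genome size, AT content and rRNA copy number, plus symbiont labels.

    Fully reproducible from ``seed``; files are written when ``outdir`` is
    given (FASTA/GFF per genome plus manifest and label tables).
    """
    rng = np.random.default_rng(seed)
    genomes: list[SimulatedGenome] = []
    for ci, cls in enumerate(COHORT_CLASSES):
        for k in range(n_per_class[ci]):
            size = int(
                max(
                    rng.normal(params.size_mean[ci], params.size_mean[ci] * params.size_sd_frac),
                    80_000,
                )
            )
            at = float(np.clip(rng.normal(params.at_mean[ci], params.at_sd), 0.25, 0.75))
            rat = float(
                np.clip(rng.normal(params.rrna_at_mean[ci], params.rrna_at_sd), 0.30, 0.65)
            )
            layouts = _cohort_layouts(cls, rng)
            symbiont = "yes" if rng.random() < params.symbiont_prob[ci] else "no"
            spec = ScenarioSpec(
                genome_id=f"{cls}_{k:03d}",
                chromosomes=[(size, Topology.CIRCULAR)],
                layouts=layouts,
                at_fraction=at,
                rrna_at_fraction=rat,
                len_16S=int(rng.normal(params.len16_mean[ci], params.len_sd)),
                len_23S=int(rng.normal(params.len23_mean[ci], params.len_sd)),
                seed=int(rng.integers(2**31)),
            )
            sim = simulate_genome(spec, class_label=cls, symbiont=symbiont)
            if sim.truth.status != cls:
                raise AssertionError(
                    f"cohort genome {spec.genome_id} derived status {sim.truth.status}"
                )
            genomes.append(sim)
    if outdir is not None:
        write_cohort(genomes, outdir)
    return genomes


LAYOUT_SUITE_KINDS = (
    "linked_pair",
    "unlinked_pair",
    "antisense_pair",
    "wraparound_pair",
    "single_16S",
    "single_23S",
)


def simulate_layout_suite(
    n_per_layout: int = 10,
    seed: int = 0,
    outdir: Optional[Union[str, Path]] = None,
    chrom_len: int = 16_000,
) -> list[SimulatedGenome]:
    """One-layout genomes covering all six operon configurations.

    Each genome carries a single planted unit on a circular chromosome, so
    every configuration's genome call is unambiguous ground truth.
    """
    rng = np.random.default_rng(seed)
    genomes: list[SimulatedGenome] = []
    for kind in LAYOUT_SUITE_KINDS:
        for k in range(n_per_layout):
            if kind == "unlinked_pair":
                its = int(rng.integers(2000, 4001))
            elif kind in PAIR_KINDS:
                its = int(rng.integers(300, 601))
            else:
                its = None
            spec = ScenarioSpec(
                genome_id=f"{kind}_{k:02d}",
                chromosomes=[(chrom_len, Topology.CIRCULAR)],
                layouts=[OperonLayout(kind, its=its)],
                len_16S=int(rng.integers(1500, 1601)),
                len_23S=int(rng.integers(2850, 2951)),
                seed=int(rng.integers(2**31)),
            )
            genomes.append(simulate_genome(spec, class_label=kind))
    if outdir is not None:
        write_cohort(genomes, outdir)
    return genomes
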