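"""Degenerate-primer matching and amplicon prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rrnalink.annotation_io import ChromosomeRecord, RnaType
from rrnalink.insilico_pcr import (
    IUPAC_SETS,
    PAIR_16S,
    Amplicon,
    Primer,
    count_rrna_loci,
    find_primer_sites,
    iupac_mismatches,
    predict_amplicons,
    reverse_complement,
)
from rrnalink.synthetic_data import build_rrna_template

P27F = "AGRGTTYGATYHTGGCTCAG"


def random_chrom(rng, n):
    seq = "".join(rng.choice(list("ACGT"), size=n))
    return ChromosomeRecord(id="c", sequence=seq)


class TestIupacMismatches:
    @pytest.mark.parametrize(
        "primer,genome,expected",
        [
            ("R", "A", 0),  # R = A|G
            ("R", "C", 1),
            (P27F, "AGAGTTTGATCATGGCTCAG", 0),  # exact degenerate realization
            ("ACGT", "ACGN", 1),  # N counts as a mismatch
            ("NNNN", "ACGN", 1),  # even against primer N
        ],
    )
    def test_examples(self, primer, genome, expected):
        assert iupac_mismatches(primer, genome) == expected

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            iupac_mismatches("ACG", "AC")

    @settings(max_examples=60, derandomize=True)
    @given(
        st.text(alphabet=sorted(IUPAC_SETS), min_size=1, max_size=25).flatmap(
            lambda p: st.tuples(
                st.just(p),
                st.text(alphabet="ACGTN", min_size=len(p), max_size=len(p)),
            )
        )
    )
    def test_matches_set_membership_oracle(self, case):
        primer, genome = case
        oracle = sum(
            1
            for p, g in zip(primer, genome)
            if g not in IUPAC_SETS[p] or g not in "ACGT"
        )
        assert iupac_mismatches(primer, genome) == oracle


class TestReverseComplement:
    def test_degenerate_codes(self):
        assert reverse_complement("RYKMBVDHSWN") == "NWSDHBVKMRY"
        assert reverse_complement("AGRGTT") == "AACYCT"

    @settings(max_examples=30, derandomize=True)
    @given(st.text(alphabet=sorted(IUPAC_SETS), max_size=30))
    def test_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s


class TestFindPrimerSites:
    def test_planted_exact_site(self):
        site = "AGAGTTTGATCATGGCTCAG"
        chrom = ChromosomeRecord(id="c", sequence="C" * 100 + site + "C" * 100)
        sites = find_primer_sites(chrom, Primer("27F", P27F), max_mm=0)
        assert sites == [(101, "forward", 0)]

    def test_mismatch_budget_gates_detection(self):
        site = list("AGAGTTTGATCATGGCTCAG")
        # three substitutions at non-degenerate positions (0-based 3, 4, 12)
        for pos, base in [(3, "C"), (4, "A"), (12, "A")]:
            site[pos] = base
        chrom = ChromosomeRecord(id="c", sequence="C" * 50 + "".join(site) + "C" * 50)
        primer = Primer("27F", P27F)
        assert find_primer_sites(chrom, primer, max_mm=2) == []
        assert find_primer_sites(chrom, primer, max_mm=4) == [(51, "forward", 3)]

    def test_reverse_orientation_site(self):
        realization = "TACCTTGTTACGACTT"  # 1492R with Y -> C
        chrom = ChromosomeRecord(
            id="c", sequence="G" * 60 + reverse_complement(realization) + "G" * 60
        )
        sites = find_primer_sites(chrom, Primer("1492R", "TACCTTGTTAYGACTT"), max_mm=0)
        assert sites == [(61, "reverse", 0)]

    def test_primer_longer_than_chromosome(self):
        chrom = ChromosomeRecord(id="c", sequence="ACGT")
        assert find_primer_sites(chrom, Primer("27F", P27F), max_mm=4) == []

    def test_monotone_in_budget(self):
        rng = np.random.default_rng(7)
        chrom = random_chrom(rng, 5000)
        primer = Primer("1492R", "TACCTTGTTAYGACTT")
        prev = set()
        for mm in range(0, 7):
            cur = set(find_primer_sites(chrom, primer, mm))
            assert prev <= {(p, o, m) for p, o, m in cur}
            prev = cur


class TestPredictAmplicons:
    def test_template_yields_single_product(self):
        rng = np.random.default_rng(3)
        tpl = build_rrna_template(RnaType.SSU_16S, rng)
        chrom = ChromosomeRecord(id="c", sequence="C" * 2000 + tpl.seq + "C" * 2000)
        amps = predict_amplicons(chrom, PAIR_16S, max_mm=0)
        assert len(amps) == 1
        a = amps[0]
        assert (a.start, a.end, a.strand) == (2001, 2000 + len(tpl.seq), "+")
        assert 1000 < a.length < 4000
        assert a.fwd_mismatches == a.rev_mismatches == 0

    def test_short_product_filtered(self):
        fwd = "AGAGTTTGATCATGGCTCAG"
        rev_site = reverse_complement("TACCTTGTTACGACTT")
        # reverse site begins 900 bp after the forward site: product < 1000
        chrom = ChromosomeRecord(
            id="c", sequence="C" * 100 + fwd + "C" * (900 - len(fwd)) + rev_site + "C" * 100
        )
        assert predict_amplicons(chrom, PAIR_16S, max_mm=0) == []

    def test_no_sites_no_products(self):
        chrom = ChromosomeRecord(id="c", sequence="C" * 3000)
        assert predict_amplicons(chrom, PAIR_16S, max_mm=2) == []

    def test_strand_symmetry(self):
        rng = np.random.default_rng(11)
        tpl = build_rrna_template(RnaType.SSU_16S, rng)
        left = "".join(rng.choice(list("ACGT"), size=1500))
        right = "".join(rng.choice(list("ACGT"), size=1500))
        fwd_chrom = ChromosomeRecord(id="c", sequence=left + tpl.seq + right)
        rev_chrom = ChromosomeRecord(
            id="c", sequence=reverse_complement(fwd_chrom.sequence)
        )
        a = predict_amplicons(fwd_chrom, PAIR_16S, max_mm=2)
        b = predict_amplicons(rev_chrom, PAIR_16S, max_mm=2)
        key = lambda amps: sorted((x.length, x.fwd_mismatches, x.rev_mismatches) for x in amps)
        assert key(a) == key(b)
        assert {x.strand for x in b} == {"-"}


class TestCountLoci:
    def amp(self, chrom, start, end):
        return Amplicon(chrom, RnaType.SSU_16S, start, end, "+", 0, 0)

    def test_duplicates_merge(self):
        a = self.amp("c", 100, 1600)
        assert count_rrna_loci([a, a]) == 1

    def test_different_chromosomes_distinct(self):
        assert count_rrna_loci([self.amp("c1", 100, 1600), self.amp("c2", 100, 1600)]) == 2

    def test_spaced_loci_distinct(self):
        amps = [self.amp("c", s, s + 1500) for s in (100, 6000, 12000)]
        assert count_rrna_loci(amps) == 3

    def test_partial_overlap_below_half_not_merged(self):
        assert count_rrna_loci([self.amp("c", 1, 1000), self.amp("c", 900, 3000)]) == 2

    def test_mixed_targets_rejected(self):
        a = self.amp("c", 100, 1600)
        b = Amplicon("c", RnaType.LSU_23S, 100, 3000, "+", 0, 0)
        with pytest.raises(ValueError):
            count_rrna_loci([a, b])


def brute_force_sites(chrom, primer, max_mm):
    """Independent per-window oracle: IUPAC set membership, both orientations."""
    out = []
    for pattern, orient in ((primer.iupac_seq, "forward"),
                            (reverse_complement(primer.iupac_seq), "reverse")):
        L = len(pattern)
        for start in range(len(chrom.sequence) - L + 1):
            window = chrom.sequence[start : start + L]
            mm = 0
            for p, g in zip(pattern, window):
                if g not in IUPAC_SETS[p] or g not in "ACGT":
                    mm += 1
            if mm <= max_mm:
                out.append((start + 1, orient, mm))
    return sorted(out)


def test_scanner_equals_brute_force_on_small_chromosomes():
    rng = np.random.default_rng(23)
    primers = [PAIR_16S.forward, PAIR_16S.reverse]
    for _ in range(10):
        chrom = random_chrom(rng, int(rng.integers(500, 3000)))
        primer = primers[rng.integers(len(primers))]
        mm = int(rng.integers(0, 5))
        assert sorted(find_primer_sites(chrom, primer, mm)) == brute_force_sites(chrom, primer, mm)
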