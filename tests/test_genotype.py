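"""Read realignment support, copy-number read-off, genotype decision rules."""

import numpy as np
import pytest

from microsat.assemble import Contig
from microsat.genotype import (
    GenotypeParams,
    ContigSupport,
    assign_reads_to_contigs,
    call_genotype,
    estimate_copy_number,
    flank_normalized_template,
    read_calls,
    write_calls,
    GenotypeCall,
)

from conftest import make_locus


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def contig(seq, cid="c0", reads=10):
    return Contig(contig_id=cid, sequence=seq, n_supporting_reads=reads)


def brute_force_score(read, target):
    """Best semi-global score (+1/-1/-2, gaps only as overhang-free shifts)
    over all ungapped placements — oracle for substitution-only cases."""
    best = None
    for shift in range(len(target) - len(read) + 1):
        window = target[shift : shift + len(read)]
        mism = sum(a != b for a, b in zip(read, window))
        score = (len(read) - mism) - mism
        best = score if best is None else max(best, score)
    return best


class TestAssignment:
    def test_single_contig_takes_every_alignable_read(self):
        c = contig(random_seq(300, 1))
        reads = [c.sequence[i : i + 100] for i in range(0, 200, 20)]
        [sup] = assign_reads_to_contigs(reads, [c])
        assert sup.n_assigned_reads == len(reads)
        assert sup.support_fraction == 1.0

    def test_read_prefers_exact_contig_over_hamming_12(self):
        a = contig(random_seq(300, 2), "A")
        b_seq = list(a.sequence)
        rng = np.random.default_rng(3)
        for pos in rng.choice(np.arange(100, 200), size=12, replace=False):
            b_seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b_seq[pos]]
        b = contig("".join(b_seq), "B")
        read = a.sequence[80: 230]
        sups = {s.contig.contig_id: s for s in assign_reads_to_contigs([read], [a, b])}
        assert sups["A"].n_assigned_reads == 1 and sups["B"].n_assigned_reads == 0
        assert brute_force_score(read, a.sequence) > brute_force_score(read, b.sequence)

    def test_equidistant_read_is_unassigned(self):
        shared = random_seq(200, 4)
        a = contig(shared + "AAAA", "A")
        b = contig(shared + "TTTT", "B")
        read = shared[:150]
        sups = assign_reads_to_contigs([read], [a, b])
        assert all(s.n_assigned_reads == 0 for s in sups)

    def test_identical_templates_resolve_to_one_candidate(self):
        seq = random_seq(250, 5)
        a, b = contig(seq, "A", 9), contig(seq, "B", 3)
        sups = {s.contig.contig_id: s for s in assign_reads_to_contigs([seq[:150]], [a, b])}
        assert sups["A"].n_assigned_reads == 1
        assert sups["B"].n_assigned_reads == 0


class TestCopyNumber:
    def make_ref(self, unit="ACAG", copies=5, seed=6):
        left, right = random_seq(300, seed), random_seq(300, seed + 1)
        tract = unit * copies
        ref = {"chr1": left + tract + right}
        locus = make_locus("chr1", 300, 300 + len(tract), unit, float(copies))
        return ref, locus

    def test_constructed_tract_is_measured_exactly(self):
        ref, locus = self.make_ref()
        c = contig(ref["chr1"][270:300] + "ACAG" * 8 + ref["chr1"][320:350])
        assert estimate_copy_number(c, locus, ref) == 8.0

    def test_reference_window_returns_catalog_copy_number(self):
        ref, locus = self.make_ref()
        c = contig(ref["chr1"][250:370])
        assert estimate_copy_number(c, locus, ref) == locus.copy_number

    def test_mid_phase_tract_counts_like_phase_aligned(self):
        # contig enters the tract mid-unit; any rotation must be accepted
        ref, locus = self.make_ref()
        rotated = "GACAGACAGACAGACAGACAGACAGACAGAC"  # 31 bases of period 4
        c_anchorless = rotated  # no flanks at all -> unusable
        assert estimate_copy_number(contig(c_anchorless), locus, ref) is None
        # 3' anchored, measured leftward over rotations
        c = contig("G" + "ACAG" * 7 + ref["chr1"][320:345])
        assert estimate_copy_number(c, locus, ref) == 7.25

    def test_one_mismatch_anchor_fallback(self):
        ref, locus = self.make_ref()
        left_flank = list(ref["chr1"][280:300])
        left_flank[5] = "A" if left_flank[5] != "A" else "T"
        c = contig("".join(left_flank) + "ACAG" * 6 + ref["chr1"][320:330])
        assert estimate_copy_number(c, locus, ref) == 6.0

    def test_fractional_trailing_unit(self):
        ref, locus = self.make_ref()
        c = contig(ref["chr1"][280:300] + "ACAG" * 6 + "AC" + ref["chr1"][320:340])
        assert estimate_copy_number(c, locus, ref) == 6.5

    def test_flank_normalized_template_equalizes_reach(self):
        # two contigs of the same allele with different flank reach; both
        # contain the 20 bp anchors, so normalization must equalize them
        ref, locus = self.make_ref()
        short = contig(ref["chr1"][278:345], "s")
        long = contig(ref["chr1"][250:380], "l")
        ts = flank_normalized_template(short, locus, ref, pad=100)
        tl = flank_normalized_template(long, locus, ref, pad=100)
        assert ts == tl


def support(cid, n, frac, cn, total_reads=100):
    s = ContigSupport(
        contig=contig("X" , cid, n), n_assigned_reads=n, support_fraction=frac
    )
    s.copy_number = cn
    return s


class TestCallGenotype:
    def setup_method(self):
        self.ref, self.locus = TestCopyNumber().make_ref()

    def call(self, supports, flag=False, **kw):
        return call_genotype(supports, flag, self.locus, self.ref, GenotypeParams(), **kw)

    def test_dominant_contig_is_homozygous_alternate(self):
        c = self.call([support("a", 80, 0.8, 12.0), support("b", 20, 0.2, 9.0)])
        assert (c.genotype, c.allele1_copy_number, c.allele2_copy_number) == ("hom_alt", 12.0, None)

    def test_balanced_supports_are_heterozygous(self):
        c = self.call([support("a", 55, 0.55, 12.0), support("b", 45, 0.45, 9.0)])
        assert c.genotype == "het"
        assert sorted(c.alleles) == [9.0, 12.0]

    def test_exact_30_percent_boundary_calls_het(self):
        c = self.call([support("a", 70, 0.7, 12.0), support("b", 30, 0.3, 9.0)])
        assert c.genotype == "het"

    def test_just_under_30_percent_calls_hom(self):
        c = self.call([support("a", 71, 0.71, 12.0), support("b", 29, 0.29, 9.0)])
        assert c.genotype == "hom_alt"

    def test_single_contig_is_homozygous(self):
        c = self.call([support("a", 40, 1.0, 14.0)])
        assert (c.genotype, c.allele1_copy_number) == ("hom_alt", 14.0)

    def test_no_contigs_with_reference_flag_is_hom_ref(self):
        c = self.call([], flag=True)
        assert (c.genotype, c.allele1_copy_number) == ("hom_ref", self.locus.copy_number)

    def test_reference_flag_plus_strong_alternate_is_het(self):
        c = self.call(
            [support("a", 50, 1.0, 12.0)], flag=True, n_reference_identical=50
        )
        assert c.genotype == "het"
        assert sorted(c.alleles) == sorted([self.locus.copy_number, 12.0])

    def test_reference_flag_with_noise_contig_stays_hom_ref(self):
        # 4 error reads assembled vs 96 reference-identical reads
        c = self.call(
            [support("a", 4, 1.0, 12.0)], flag=True, n_reference_identical=96
        )
        assert c.genotype == "hom_ref"

    def test_reference_flag_with_ref_copy_contig_stays_hom_ref(self):
        c = self.call(
            [support("a", 50, 1.0, self.locus.copy_number)],
            flag=True,
            n_reference_identical=50,
        )
        assert c.genotype == "hom_ref"

    def test_no_contigs_no_flag_statuses(self):
        assert self.call([], n_reads=0).status == "NO_READS"
        assert self.call([], n_reads=50).status == "NO_ASSEMBLY"

    def test_absolute_count_mode(self):
        params = GenotypeParams(het_min_reads=10)
        c = call_genotype(
            [support("a", 80, 0.8, 12.0), support("b", 11, 0.11, 9.0)],
            False,
            self.locus,
            self.ref,
            params,
        )
        assert c.genotype == "het"

    def test_monotone_in_second_support(self):
        outcomes = []
        for n2 in range(0, 60, 5):
            c = self.call([support("a", 70, 0.7, 12.0), support("b", n2, n2 / 100, 9.0)])
            outcomes.append(c.genotype == "het")
        # once heterozygous, more second-allele support never flips it back
        assert outcomes == sorted(outcomes)

    def test_same_copy_number_contigs_pool_into_one_allele(self):
        # two fragments of one allele must not masquerade as a het pair, and
        # their pooled support dominates the true minor cluster
        sups = [
            support("a", 40, 0.4, 12.0),
            support("b", 35, 0.35, 12.0),  # fragment of the same allele
            support("c", 25, 0.25, 9.0),
        ]
        c = self.call(sups)
        assert c.genotype == "hom_alt"  # 25/(75+25) < 0.30
        assert c.alleles == (12.0,)
        # but a genuinely strong minor cluster still calls het
        c2 = self.call(
            [support("a", 40, 0.4, 12.0), support("b", 20, 0.2, 12.0),
             support("c", 30, 0.3, 9.0)]
        )
        assert c2.genotype == "het" and sorted(c2.alleles) == [9.0, 12.0]


def test_calls_tsv_round_trip(tmp_path):
    calls = [
        GenotypeCall("l1", "het", allele1_copy_number=9.0, allele2_copy_number=14.0,
                     contig_ids=["c0", "c1"], support_fractions=[0.6, 0.4]),
        GenotypeCall("l2", "hom_ref", allele1_copy_number=5.0),
        GenotypeCall("l3", "", status="NO_READS"),
    ]
    path = tmp_path / "calls.tsv"
    write_calls(calls, path)
    back = read_calls(path)
    assert [(c.locus_id, c.genotype, c.status, c.alleles) for c in calls] == [
        (c.locus_id, c.genotype, c.status, c.alleles) for c in back
    ]
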