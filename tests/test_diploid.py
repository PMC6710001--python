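"""Diploid expansion simulation: genotype draws, insertion arithmetic, truth."""

import numpy as np
import pytest
from scipy import stats

from microsat.diploid import (
    PhaseError,
    SimulationConfig,
    draw_event,
    expand_region,
    read_truth,
    simulate_diploid,
    write_truth,
)
from microsat.sequtils import max_tandem_run

from conftest import make_locus


def count_unit_occurrences(seq, unit):
    """Brute-force non-overlapping scan used as an oracle for expansions."""
    n = i = 0
    while i + len(unit) <= len(seq):
        if seq[i : i + len(unit)] == unit:
            n += 1
            i += len(unit)
        else:
            i += 1
    return n


class TestDrawEvent:
    def test_all_hom_config_shares_one_expansion(self):
        cfg = SimulationConfig(seed=1, p_het=0.0, p_hom_ref=0.0)
        rng = np.random.default_rng(1)
        for _ in range(50):
            ev = draw_event(make_locus(), cfg, rng)
            assert ev.genotype == "hom_alt"
            assert ev.maternal_n == ev.paternal_n >= 1

    def test_all_het_config_draws_two_distinct_alternates(self):
        cfg = SimulationConfig(seed=1, p_het=1.0, p_het_ref_allele=0.0)
        rng = np.random.default_rng(2)
        for _ in range(50):
            ev = draw_event(make_locus(), cfg, rng)
            assert ev.genotype == "het"
            assert ev.maternal_n != ev.paternal_n
            assert ev.maternal_n >= 1 and ev.paternal_n >= 1

    def test_het_with_reference_allele_keeps_one_n_zero(self):
        cfg = SimulationConfig(seed=1, p_het=1.0, p_het_ref_allele=1.0)
        rng = np.random.default_rng(3)
        for _ in range(50):
            ev = draw_event(make_locus(), cfg, rng)
            assert sorted([ev.maternal_n, ev.paternal_n])[0] == 0
            assert max(ev.maternal_n, ev.paternal_n) >= 1

    def test_expansion_factor_uniform_on_1_to_30(self):
        cfg = SimulationConfig(seed=1, p_het=0.0)
        rng = np.random.default_rng(4)
        draws = [draw_event(make_locus(), cfg, rng).maternal_n for _ in range(10_000)]
        counts = np.bincount(draws, minlength=31)[1:31]
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.01  # uniform law not rejected

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_het=1.5)


class TestExpandRegion:
    def test_zero_expansion_is_identity(self):
        seq = "TTTT" + "ACAG" * 5 + "GGGG"
        assert expand_region(seq, make_locus(start=4, end=24), 0) == seq

    def test_three_extra_units_counted_by_brute_force(self):
        seq = "TTTT" + "ACAG" * 5 + "GGGG"
        locus = make_locus(start=4, end=24)
        out = expand_region(seq, locus, 3)
        assert len(out) == len(seq) + 12
        assert count_unit_occurrences(out[4 : 24 + 12], "ACAG") == 8

    @pytest.mark.parametrize("n", [1, 5, 30])
    def test_length_conservation(self, n):
        seq = "TGCA" + "ACTGG" * 6 + "TTAA"
        locus = make_locus(start=4, end=34, unit="ACTGG", copy_number=6.0)
        assert len(expand_region(seq, locus, n)) == len(seq) + n * 5

    def test_rotated_tract_phase_is_preserved(self):
        # tract entered mid-phase: starts with CAGA, a rotation of ACAG
        seq = "TTTT" + ("CAGA" * 5) + "GGGG"
        locus = make_locus(start=4, end=24)
        out = expand_region(seq, locus, 2)
        assert max_tandem_run(out, 4, "ACAG") == 28

    def test_phase_mismatch_raises(self):
        seq = "TTTT" + "GGCC" * 5 + "AAAA"
        with pytest.raises(PhaseError):
            expand_region(seq, make_locus(start=4, end=24), 1)


class TestSimulateDiploid:
    def test_empty_locus_list_returns_reference_verbatim(self):
        ref = {"chr1": "ACGT" * 100}
        mat, pat, truth, _ = simulate_diploid(ref, [], SimulationConfig(seed=0))
        assert mat == pat == ref and truth == []

    def test_length_conservation_per_haplotype(self, small_world):
        ref, loci = small_world
        mat, pat, truth, _ = simulate_diploid(ref, loci, SimulationConfig(seed=3))
        unit_of = {l.locus_id: l.unit_length for l in loci}
        for haps, attr in ((mat, "maternal_n"), (pat, "paternal_n")):
            expected = sum(getattr(t, attr) * unit_of[t.locus_id] for t in truth)
            assert len(haps["chrS"]) - len(ref["chrS"]) == expected

    def test_downstream_locus_coordinates_shift_by_upstream_insertions(self):
        unit = "ACAG"
        rng = np.random.default_rng(77)
        parts = ["".join("ACGT"[i] for i in rng.integers(0, 4, size=200)) for _ in range(3)]
        ref = {"c": parts[0] + unit * 5 + parts[1] + "TCGGA" * 4 + parts[2]}
        l1 = make_locus("c", 200, 220, unit, 5.0)
        l2 = make_locus("c", 420, 440, "TCGGA", 4.0)
        cfg = SimulationConfig(seed=11, p_het=0.0)
        mat, _, truth, maps = simulate_diploid(ref, [l1, l2], cfg)
        n1 = truth[0].maternal_n
        # locate the second tract by its unique 5' flank
        flank = ref["c"][400:420]
        found = mat["c"].find(flank) + 20
        assert found == 420 + n1 * 4
        assert truth[1].maternal_span[0] == found

    def test_truth_spans_remeasure_to_new_copy_number(self, small_world):
        ref, loci = small_world
        mat, pat, truth, _ = simulate_diploid(ref, loci, SimulationConfig(seed=3))
        unit = {l.locus_id: l.unit for l in loci}
        for t in truth:
            for hap, span, cn in (
                (mat["chrS"], t.maternal_span, t.maternal_copy_number),
                (pat["chrS"], t.paternal_span, t.paternal_copy_number),
            ):
                run = max_tandem_run(hap, span[0], unit[t.locus_id])
                assert run == round(cn * len(unit[t.locus_id]))

    def test_determinism_and_seed_sensitivity(self, small_world):
        ref, loci = small_world
        a = simulate_diploid(ref, loci, SimulationConfig(seed=42))
        b = simulate_diploid(ref, loci, SimulationConfig(seed=42))
        c = simulate_diploid(ref, loci, SimulationConfig(seed=43))
        assert a[0] == b[0] and a[1] == b[1]
        assert a[0] != c[0] or a[1] != c[1]

    def test_locus_outside_reference_raises(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_diploid(
                {"chr1": "A" * 50}, [make_locus("chr1", 100, 120)], SimulationConfig()
            )

    def test_overlapping_locus_skipped_with_warning(self):
        ref = {"c": "T" * 100 + "ACAG" * 5 + "G" * 100}
        l1 = make_locus("c", 100, 120)
        l2 = make_locus("c", 110, 130)
        with pytest.warns(UserWarning, match="overlaps"):
            _, _, truth, _ = simulate_diploid(ref, [l1, l2], SimulationConfig(seed=1))
        assert [t.locus_id for t in truth] == [l1.locus_id]


def test_truth_table_round_trip(tmp_path, small_world):
    ref, loci = small_world
    _, _, truth, _ = simulate_diploid(ref, loci, SimulationConfig(seed=3))
    path = tmp_path / "truth.tsv"
    write_truth(truth, path)
    back = read_truth(path)
    assert [(t.locus_id, t.genotype, t.alleles) for t in truth] == [
        (t.locus_id, t.genotype, t.alleles) for t in back
    ]
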