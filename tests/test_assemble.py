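"""Greedy OLC assembler: overlaps, layout, consensus, repeat resolution."""

from itertools import permutations

import numpy as np
import pytest

from microsat.assemble import (
    AssemblyParams,
    ExternalToolError,
    find_overlaps,
    layout_and_consensus,
    parse_contig_fasta,
    run_external_assembler,
)
from microsat.sequtils import revcomp


def brute_force_max_overlap(a: str, b: str) -> int:
    """All-shifts scan oracle for the maximal suffix(a)/prefix(b) overlap."""
    for o in range(min(len(a), len(b)), 0, -1):
        if a[-o:] == b[:o]:
            return o
    return 0


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def tile(source, read_len, step, start=0):
    reads = [
        source[i : i + read_len]
        for i in range(start, len(source) - read_len + 1, step)
    ]
    if reads and reads[-1] != source[-read_len:]:
        reads.append(source[-read_len:])  # cover the terminal bases
    return reads


def exhaustive_superstring(reads, min_overlap):
    """Oracle: best merge over all read orders; None if not unique."""
    best_len, best = None, set()
    for perm in permutations(reads):
        s = perm[0]
        ok = True
        for nxt in perm[1:]:
            if nxt in s:
                continue
            o = brute_force_max_overlap(s, nxt)
            if o < min_overlap:
                ok = False
                break
            s = s + nxt[o:]
        if not ok:
            continue
        if best_len is None or len(s) < best_len:
            best_len, best = len(s), {s}
        elif len(s) == best_len:
            best.add(s)
    return best.pop() if len(best) == 1 else None


class TestFindOverlaps:
    def test_sixty_base_overlap_found_with_oracle_length(self):
        src = random_seq(240, 1)
        r1, r2 = src[:150], src[90:240]
        edges = find_overlaps([("R1", r1), ("R2", r2)], AssemblyParams(min_overlap=40))
        fwd = [e for e in edges if not e.containment]
        assert len(fwd) == 1
        e = fwd[0]
        assert (e.from_read, e.to_read) == ("R1", "R2")
        assert e.overlap_length == brute_force_max_overlap(r1, r2) == 60

    def test_no_shared_kmer_no_edges(self):
        assert find_overlaps([("a", "A" * 100), ("b", "C" * 100)], AssemblyParams()) == []

    def test_containment_reported(self):
        src = random_seq(200, 2)
        edges = find_overlaps([("big", src), ("small", src[30:120])], AssemblyParams())
        cont = [e for e in edges if e.containment]
        assert [(e.from_read, e.to_read) for e in cont] == [("big", "small")]

    def test_reverse_complement_mode_finds_rc_overlap(self):
        src = random_seq(240, 3)
        r1, r2 = src[:150], revcomp(src[90:240])
        plain = find_overlaps([("f", r1), ("r", r2)], AssemblyParams())
        both = find_overlaps([("f", r1), ("r", r2)], AssemblyParams(), both_orientations=True)
        assert plain == []
        assert any(e.orientation == "reverse-complement" for e in both)

    def test_mismatch_budget_admits_noisy_overlap(self):
        src = random_seq(240, 4)
        r2 = list(src[90:240])
        r2[10] = "A" if r2[10] != "A" else "C"
        params = AssemblyParams(min_overlap=40, max_overlap_mismatches=1)
        edges = find_overlaps([("R1", src[:150]), ("R2", "".join(r2))], params)
        assert any(e.overlap_length >= 40 for e in edges)


class TestLayout:
    def test_single_read_is_its_own_contig(self):
        params = AssemblyParams(min_reads_per_contig=1)
        [contig] = layout_and_consensus(["ACGT" * 40], params)
        assert contig.sequence == "ACGT" * 40 and contig.n_supporting_reads == 1

    def test_empty_read_set_gives_no_contigs(self):
        assert layout_and_consensus([], AssemblyParams()) == []

    def test_error_free_tiling_reconstructs_the_allele(self):
        allele = random_seq(400, 5)
        reads = tile(allele, 150, 5)  # 30x-ish tiling
        [contig] = layout_and_consensus(reads, AssemblyParams())
        assert contig.sequence == allele
        assert contig.n_supporting_reads == len(reads)

    def test_two_alleles_differing_by_insertion_give_two_contigs(self):
        # same flanks, 12 bp insertion of unique (non-repetitive) sequence;
        # reads shared between the alleles can enter only one layout path, so
        # the first contig recovers one allele in full and the second covers
        # the other allele's branch including the discriminating insertion
        flank5, flank10 = random_seq(200, 6), random_seq(200, 7)
        mid = random_seq(12, 8)
        allele_a = flank5 + flank10
        allele_b = flank5 + mid + flank10
        reads = tile(allele_a, 150, 4) + tile(allele_b, 150, 4)
        contigs = layout_and_consensus(reads, AssemblyParams())
        assert len(contigs) >= 2
        first, second = contigs[0].sequence, contigs[1].sequence
        assert first == allele_a
        assert second in allele_b and mid in second

    def test_determinism(self):
        allele = random_seq(500, 9)
        reads = tile(allele, 150, 7) + tile(allele, 150, 11)
        a = layout_and_consensus(reads, AssemblyParams())
        b = layout_and_consensus(list(reads), AssemblyParams())
        assert [(c.sequence, c.n_supporting_reads) for c in a] == [
            (c.sequence, c.n_supporting_reads) for c in b
        ]

    def test_soundness_contigs_are_substrings_of_the_source(self):
        allele = random_seq(600, 10)
        rng = np.random.default_rng(11)
        starts = sorted(rng.integers(0, 450, size=60))
        reads = [allele[s : s + 150] for s in starts]
        for contig in layout_and_consensus(reads, AssemblyParams()):
            assert contig.sequence in allele

    def test_greedy_matches_exhaustive_oracle_on_small_inputs(self):
        src = random_seq(330, 12)
        for n_reads, step in [(3, 90), (5, 45), (7, 30)]:
            reads = tile(src, 150, step)[:n_reads]
            expected = exhaustive_superstring(reads, 40)
            assert expected is not None, "fixture must have a unique superstring"
            [contig] = layout_and_consensus(reads, AssemblyParams(min_reads_per_contig=1))
            assert contig.sequence == expected

    def test_majority_vote_fixes_an_interior_error(self):
        allele = random_seq(300, 13)
        reads = tile(allele, 150, 10) * 2  # every column covered >= 2x
        bad = list(reads[0])
        bad[75] = "A" if bad[75] != "A" else "G"
        reads[0] = "".join(bad)
        contigs = layout_and_consensus(reads, AssemblyParams())
        assert contigs[0].sequence == allele

    def test_periodic_gap_resolved_with_density_hint(self):
        # expanded tract longer than the read length: overlaps through the
        # tract are ambiguous and the coverage-mass rule must size the gap
        unit = "ATGG"
        flank5, flank3 = random_seq(160, 14), random_seq(160, 15)
        tract = unit * 50  # 200 bp > read length
        hap = flank5 + tract + flank3
        reads = [hap[s : s + 150] for s in range(0, len(hap) - 150 + 1, 2)]
        params = AssemblyParams(unit=unit, read_density=0.5)
        contigs = layout_and_consensus(reads, params)
        assert contigs[0].sequence == hap


class TestExternalAdapter:
    def test_missing_binary_is_a_clear_environment_error(self, tmp_path):
        (tmp_path / "reads.fastq").write_text("@r\nACGT\n+\n!!!!\n")
        with pytest.raises(ExternalToolError, match="not found"):
            run_external_assembler(
                "definitely-not-a-real-assembler {input} {outdir}",
                tmp_path / "reads.fastq",
                tmp_path / "out",
            )

    def test_zero_contig_output_yields_empty_list(self, tmp_path):
        (tmp_path / "reads.fastq").write_text("@r\nACGT\n+\n!!!!\n")
        contigs = run_external_assembler(
            "true", tmp_path / "reads.fastq", tmp_path / "out"
        )
        assert contigs == []

    def test_adapter_round_trips_internal_fasta(self, tmp_path):
        allele = random_seq(400, 16)
        internal = layout_and_consensus(tile(allele, 150, 5), AssemblyParams())
        fasta = tmp_path / "contigs.fa"
        fasta.write_text(
            "".join(
                f">{c.contig_id} reads={c.n_supporting_reads}\n{c.sequence}\n"
                for c in internal
            )
        )
        via_adapter = run_external_assembler(
            f"cp {fasta} {{outdir}}/contigs.fa", tmp_path / "ignored.fastq", tmp_path / "out"
        )
        assert [(c.contig_id, c.sequence, c.n_supporting_reads) for c in via_adapter] == [
            (c.contig_id, c.sequence, c.n_supporting_reads) for c in internal
        ]


def test_parse_contig_fasta_multiline(tmp_path):
    p = tmp_path / "c.fa"
    p.write_text(">c0 reads=7\nACGT\nACGT\n>c1\nTTTT\n")
    contigs = parse_contig_fasta(p)
    assert [(c.contig_id, c.sequence, c.n_supporting_reads) for c in contigs] == [
        ("c0", "ACGTACGT", 7),
        ("c1", "TTTT", 0),
    ]
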