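"""Illumina-like paired-end read simulator with truth placements.

Fragments are drawn uniformly along each haplotype with Normal-distributed
lengths; mate 1 is the fragment's 5' end, mate 2 the reverse complement of
its 3' end (FR layout).  Sequencing noise is an i.i.d. per-base substitution
model with flat Q30 qualities.  An optional PCR-stutter knob adds/removes one
repeat unit from fragments overlapping a tract.

Because every fragment's origin is known, the simulator can also emit a
"truth placement" SAM in which each read sits at its true reference-projected
position with the correct insertion CIGAR — this makes the downstream
extraction/assembly/genotyping stages testable without an external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pysam

from .catalog import MicrosatelliteLocus
from .diploid import TruthRecord
from .liftover import HaplotypeMap
from .sequtils import revcomp

__all__ = ["ReadSimConfig", "ReadPair", "simulate_reads", "truth_place_alignments", "write_fastq"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation parameters (150 bp reads, 350 bp mean fragments)."""

    read_length: int = 150
    mean_fragment: float = 350.0
    fragment_sd: float = 35.0
    coverage: float = 60.0
    substitution_error_rate: float = 0.001
    stutter_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        for name in ("substitution_error_rate", "stutter_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass
class ReadPair:
    """One simulated fragment: two mates plus full truth provenance."""

    pair_id: str
    mate1_seq: str
    mate2_seq: str
    quality: str
    truth_chrom: str
    truth_haplotype: int  # 1 = maternal, 2 = paternal
    truth_fragment_start: int  # haplotype coordinates
    truth_fragment_end: int
    mate1_subs: int = 0
    mate2_subs: int = 0
    stutter_shift: int = 0  # net bases added(+)/removed(-) by PCR stutter


def _apply_substitutions(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    if n_subs == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    for p in pos:
        old = arr[p]
        choices = _BASES[_BASES != old]
        arr[p] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def n_pairs_for(hap_length: int, config: ReadSimConfig) -> int:
    """Pairs per haplotype so the diploid totals ``coverage``:
    round(coverage * L / (2 * 2 * read_length))."""
    return int(round(config.coverage * hap_length / (2 * 2 * config.read_length)))


def simulate_reads(
    haplotypes: dict[tuple[str, int], str],
    config: ReadSimConfig,
    *,
    truth_records: Sequence[TruthRecord] | None = None,
) -> list[ReadPair]:
    """Simulate paired reads from every (chrom, haplotype) sequence.

    ``truth_records`` is only needed when ``stutter_rate > 0`` (to know where
    tracts lie on each haplotype).  Output order, and hence FASTQ content, is
    deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    pairs: list[ReadPair] = []

    tracts: dict[tuple[str, int], list[tuple[int, int, str]]] = {}
    if config.stutter_rate > 0 and truth_records:
        for rec in truth_records:
            chrom = rec.locus_id.split(":")[0]
            for hap, span in ((1, rec.maternal_span), (2, rec.paternal_span)):
                if span is not None:
                    tracts.setdefault((chrom, hap), []).append((span[0], span[1], rec.locus_id))

    for (chrom, hap), seq in sorted(haplotypes.items()):
        length = len(seq)
        if rl > length:
            raise ValueError(f"read_length {rl} exceeds haplotype {chrom}/{hap} length {length}")
        n = n_pairs_for(length, config)
        if n == 0:
            continue
        frag_lens = np.clip(
            np.rint(rng.normal(config.mean_fragment, config.fragment_sd, size=n)),
            rl,
            length,
        ).astype(int)
        starts = (rng.random(n) * (length - frag_lens + 1)).astype(int)
        sub_counts = rng.binomial(rl, config.substitution_error_rate, size=(n, 2))
        stutter_draws = rng.random(n) if config.stutter_rate > 0 else None

        for i in range(n):
            fstart = int(starts[i])
            fend = fstart + int(frag_lens[i])
            fragment = seq[fstart:fend]
            shift = 0
            if stutter_draws is not None and stutter_draws[i] < config.stutter_rate:
                fragment, shift = _stutter(fragment, fstart, tracts.get((chrom, hap), []), rng)
            m1 = fragment[:rl]
            m2 = revcomp(fragment[-rl:])
            s1, s2 = int(sub_counts[i, 0]), int(sub_counts[i, 1])
            m1 = _apply_substitutions(m1, s1, rng)
            m2 = _apply_substitutions(m2, s2, rng)
            pairs.append(
                ReadPair(
                    pair_id=f"{chrom}_h{hap}_{i}",
                    mate1_seq=m1,
                    mate2_seq=m2,
                    quality="?" * rl,  # flat Q30
                    truth_chrom=chrom,
                    truth_haplotype=hap,
                    truth_fragment_start=fstart,
                    truth_fragment_end=fend,
                    mate1_subs=s1,
                    mate2_subs=s2,
                    stutter_shift=shift,
                )
            )
    return pairs


def _stutter(
    fragment: str,
    fstart: int,
    tracts: list[tuple[int, int, str]],
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Insert or delete one repeat unit inside the fragment if it overlaps a
    tract.  The unit is inferred from the tract's own periodicity; fragments
    not overlapping any tract are returned unchanged."""
    fend = fstart + len(fragment)
    for t_start, t_end, _locus_id in tracts:
        lo, hi = max(fstart, t_start), min(fend, t_end)
        if hi - lo < 8:  # need some tract inside the fragment
            continue
        local = lo - fstart
        # detect period from the overlapping tract snippet (2..6 bp)
        snippet = fragment[local : hi - fstart]
        for period in range(2, 7):
            if len(snippet) >= 2 * period and all(
                snippet[j] == snippet[j - period] for j in range(period, len(snippet))
            ):
                unit = snippet[:period]
                if rng.random() < 0.5:
                    return fragment[:local] + unit + fragment[local:], period
                return fragment[:local] + fragment[local + period :], -period
        break
    return fragment, 0


def write_fastq(pairs: Iterable[ReadPair], prefix: Union[str, Path]) -> tuple[Path, Path]:
    """Write mates to ``<prefix>_1.fastq`` / ``<prefix>_2.fastq``."""
    p1 = Path(f"{prefix}_1.fastq")
    p2 = Path(f"{prefix}_2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for pair in pairs:
            f1.write(f"@{pair.pair_id}/1\n{pair.mate1_seq}\n+\n{pair.quality}\n")
            f2.write(f"@{pair.pair_id}/2\n{pair.mate2_seq}\n+\n{pair.quality}\n")
    return p1, p2


def truth_place_alignments(
    pairs: Sequence[ReadPair],
    maps: dict[tuple[str, int], HaplotypeMap],
    reference_lengths: dict[str, int],
    out_sam: Union[str, Path],
    read_length: int = 150,
) -> Path:
    """Emit a coordinate-sorted SAM with every mate at its true placement.

    CIGARs contain an I op wherever the mate crosses an inserted (expanded)
    segment; a mate lying entirely inside an insertion gets a single I op at
    the tract start.  NM = inserted bases + simulated substitutions.  Stutter
    fragments are placed at their nominal origin (their CIGAR reflects the
    un-stuttered fragment; the extractor sees them as noisy evidence, which
    is the point of the knob).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": chrom, "LN": length}
            for chrom, length in sorted(reference_lengths.items())
        ],
    }
    rl = read_length
    records = []
    for pair in pairs:
        hmap = maps.get((pair.truth_chrom, pair.truth_haplotype))
        if hmap is None:
            raise KeyError(
                f"no liftover map for ({pair.truth_chrom}, {pair.truth_haplotype})"
            )
        m1_start = pair.truth_fragment_start
        m2_start = pair.truth_fragment_end - rl
        for mate_idx, hap_start, seq, subs in (
            (1, m1_start, pair.mate1_seq, pair.mate1_subs),
            # SAM stores reverse-strand reads in reference-forward orientation
            (2, m2_start, revcomp(pair.mate2_seq), pair.mate2_subs),
        ):
            ref_pos, ops = hmap.cigar_for(hap_start, rl)
            nm = subs + sum(n for op, n in ops if op == "I")
            records.append((pair, mate_idx, ref_pos, ops, seq, nm))

    records.sort(key=lambda r: (r[0].truth_chrom, r[2], r[0].pair_id, r[1]))

    op_codes = {"M": 0, "I": 1}
    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as sam:
        # first pass gathered everything; mate coordinates need both placements
        mate_pos: dict[tuple[str, int], int] = {}
        for pair, mate_idx, ref_pos, _ops, _seq, _nm in records:
            mate_pos[(pair.pair_id, mate_idx)] = ref_pos
        for pair, mate_idx, ref_pos, ops, seq, nm in records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = pair.pair_id
            a.query_sequence = seq
            a.reference_id = sam.header.get_tid(pair.truth_chrom)
            a.reference_start = ref_pos
            a.cigartuples = [(op_codes[op], n) for op, n in ops]
            a.mapping_quality = 60
            a.query_qualities = pysam.qualitystring_to_array(pair.quality)
            a.is_paired = True
            a.is_proper_pair = True
            a.is_read1 = mate_idx == 1
            a.is_read2 = mate_idx == 2
            a.is_reverse = mate_idx == 2
            a.mate_is_reverse = mate_idx == 1
            other = mate_pos[(pair.pair_id, 3 - mate_idx)]
            a.next_reference_id = a.reference_id
            a.next_reference_start = other
            tlen = pair.truth_fragment_end - pair.truth_fragment_start
            a.template_length = tlen if mate_idx == 1 else -tlen
            a.set_tag("NM", int(nm))
            sam.write(a)
    return Path(out_sam)
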