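"""Per-locus read extraction and the reference-allele rule.

Reads are captured for a locus when their alignment span overlaps the locus
window ``[start - window, end + window)``.  Within a capture set, reads are
split into tract-overlapping reads (alignment touches the repeat tract
itself, or carries an insertion at its boundary) and flank-only reads.

A read is *reference-identical* iff its CIGAR is a single match run and
NM == 0 (soft clips, indels or any mismatch disqualify it).  If at least 50%
of the tract-overlapping reads are reference-identical the locus is flagged
as carrying at least one reference allele and those reads are removed from
the assembly input.  The 50% denominator deliberately excludes flank-only
reads: they are reference-identical by construction for any genotype and
would otherwise drown the signal.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union
import warnings

import pysam

from .catalog import MicrosatelliteLocus

__all__ = [
    "REF_IDENTICAL",
    "VARIANT_SUPPORTING",
    "AlignedRead",
    "LocusReadSet",
    "classify_alignment",
    "collect_locus_reads",
    "apply_reference_rule",
    "write_locus_summary",
]

REF_IDENTICAL = "REF_IDENTICAL"
VARIANT_SUPPORTING = "VARIANT_SUPPORTING"

_QUERY_OPS = {0, 1, 4, 7, 8}  # M, I, S, =, X consume query
_REF_OPS = {0, 2, 3, 7, 8}  # M, D, N, =, X consume reference


@dataclass(frozen=True)
class AlignedRead:
    """Minimal alignment view: what CIGAR/NM classification needs."""

    read_id: str
    sequence: str
    chrom: str
    start: int  # 0-based reference position
    cigar: tuple[tuple[int, int], ...]  # pysam op codes
    nm: int | None
    mapq: int = 0

    def __post_init__(self) -> None:
        consumed = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        if consumed != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: CIGAR consumes {consumed} query bases, "
                f"sequence has {len(self.sequence)}"
            )

    @property
    def reference_end(self) -> int:
        return self.start + sum(n for op, n in self.cigar if op in _REF_OPS)

    def insertion_positions(self) -> list[int]:
        """Reference positions of I ops (anchor point of each insertion)."""
        pos = self.start
        out = []
        for op, n in self.cigar:
            if op == 1:
                out.append(pos)
            if op in _REF_OPS:
                pos += n
        return out


def classify_alignment(read: AlignedRead, *, missing_nm_is_variant: bool = True) -> str:
    """REF_IDENTICAL iff the CIGAR is one pure match run and NM == 0."""
    if read.nm is None:
        if missing_nm_is_variant:
            warnings.warn(f"{read.read_id}: NM tag missing, treated as variant", stacklevel=2)
            return VARIANT_SUPPORTING
        raise ValueError(f"{read.read_id}: NM tag missing")
    pure_match = len(read.cigar) == 1 and read.cigar[0][0] in (0, 7)
    return REF_IDENTICAL if pure_match and read.nm == 0 else VARIANT_SUPPORTING


@dataclass
class LocusReadSet:
    """Reads attributed to one locus plus reference-support statistics.

    ``reads`` are the tract-overlapping reads (the denominator of the 50%
    rule); ``flank_reads`` only overlap the capture window.  ``assembly_reads``
    is filled by :func:`apply_reference_rule`.
    """

    locus: MicrosatelliteLocus
    reads: list[AlignedRead] = field(default_factory=list)
    flank_reads: list[AlignedRead] = field(default_factory=list)
    n_reference_identical: int = 0
    ref_fraction: float = 0.0
    has_reference_allele: bool = False
    assembly_reads: list[str] = field(default_factory=list)
    assembly_read_ids: list[str] = field(default_factory=list)

    @property
    def locus_id(self) -> str:
        return self.locus.locus_id


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    # zero-length spans (all-I placements) are treated as 1 bp points
    if a_end <= a_start:
        a_end = a_start + 1
    return a_start < b_end and b_start < a_end


def _tract_overlapping(read: AlignedRead, locus: MicrosatelliteLocus) -> bool:
    if _overlaps(read.start, read.reference_end, locus.start, locus.end):
        return True
    # insertion anchored at a tract boundary still supports the tract
    return any(locus.start <= p <= locus.end for p in read.insertion_positions())


def _from_pysam(seg: pysam.AlignedSegment) -> AlignedRead:
    mate = 1 if seg.is_read1 else (2 if seg.is_read2 else 0)
    return AlignedRead(
        read_id=f"{seg.query_name}/{mate}" if mate else str(seg.query_name),
        sequence=seg.query_sequence or "",
        chrom=seg.reference_name or "",
        start=seg.reference_start,
        cigar=tuple(seg.cigartuples or ()),
        nm=int(seg.get_tag("NM")) if seg.has_tag("NM") else None,
        mapq=seg.mapping_quality,
    )


def collect_locus_reads(
    alignments: Union[str, Path, Iterable[AlignedRead]],
    loci: Sequence[MicrosatelliteLocus],
    window: int = 350,
) -> list[LocusReadSet]:
    """Attribute reads to loci by capture-window overlap.

    ``alignments`` may be a SAM/BAM path (streamed once; unmapped,
    secondary/supplementary and duplicate-flagged reads are skipped) or an
    iterable of :class:`AlignedRead`.  A read may be attributed to several
    overlapping windows.  Returns one :class:`LocusReadSet` per input locus,
    in (chrom, start) order, with reference-identity statistics filled in.
    """
    ordered = sorted(loci, key=lambda l: (l.chrom, l.start, l.end))
    sets = {loc.locus_id: LocusReadSet(locus=loc) for loc in ordered}

    by_chrom: dict[str, list[MicrosatelliteLocus]] = {}
    for loc in ordered:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    # window interval lists per chromosome for bisect lookup
    win_starts = {
        chrom: [loc.start - window for loc in locs] for chrom, locs in by_chrom.items()
    }
    max_span = {
        chrom: max(loc.end - loc.start for loc in locs) for chrom, locs in by_chrom.items()
    }

    def reads_iter() -> Iterable[AlignedRead]:
        if isinstance(alignments, (str, Path)):
            with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
                for seg in fh:
                    if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                        continue
                    if seg.is_duplicate:
                        continue
                    yield _from_pysam(seg)
        else:
            for read in alignments:
                yield read

    for read in reads_iter():
        locs = by_chrom.get(read.chrom)
        if not locs:
            continue
        starts = win_starts[read.chrom]
        span_end = max(read.reference_end, read.start + 1)
        # candidate loci: window start < span_end and window end > read.start
        hi = bisect_left(starts, span_end)
        lo = bisect_right(starts, read.start - max_span[read.chrom] - 2 * window)
        for loc in locs[max(0, lo - 2) : hi]:
            if _overlaps(read.start, read.reference_end, loc.start - window, loc.end + window):
                if _tract_overlapping(read, loc):
                    sets[loc.locus_id].reads.append(read)
                else:
                    sets[loc.locus_id].flank_reads.append(read)

    for rs in sets.values():
        rs.n_reference_identical = sum(
            1 for r in rs.reads if classify_alignment(r) == REF_IDENTICAL
        )
        rs.ref_fraction = rs.n_reference_identical / max(1, len(rs.reads))
        rs.has_reference_allele = rs.ref_fraction >= 0.5
    return [sets[loc.locus_id] for loc in ordered]


def apply_reference_rule(read_set: LocusReadSet, *, include_flanks: bool = False) -> LocusReadSet:
    """Complete the read set per the >=50% reference rule.

    If at least half of the tract-overlapping reads are reference-identical,
    the locus is flagged as having a reference allele and those reads are
    dropped from the assembly input; otherwise every tract-overlapping read
    is kept.  ``include_flanks`` additionally admits flank-only reads.
    """
    read_set.ref_fraction = read_set.n_reference_identical / max(1, len(read_set.reads))
    read_set.has_reference_allele = read_set.ref_fraction >= 0.5
    chosen: list[AlignedRead] = []
    for read in read_set.reads:
        if read_set.has_reference_allele and classify_alignment(read) == REF_IDENTICAL:
            continue
        chosen.append(read)
    if include_flanks:
        for read in read_set.flank_reads:
            if read_set.has_reference_allele and classify_alignment(read) == REF_IDENTICAL:
                continue
            chosen.append(read)
    read_set.assembly_reads = [r.sequence for r in chosen]
    read_set.assembly_read_ids = [r.read_id for r in chosen]
    return read_set


def write_locus_summary(read_sets: Sequence[LocusReadSet], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("#locus_id\tn_reads\tn_flank_reads\tn_ref_identical\tref_fraction\thas_reference_allele\tn_assembly_reads\n")
        for rs in read_sets:
            fh.write(
                f"{rs.locus_id}\t{len(rs.reads)}\t{len(rs.flank_reads)}\t"
                f"{rs.n_reference_identical}\t{rs.ref_fraction:.4f}\t"
                f"{int(rs.has_reference_allele)}\t{len(rs.assembly_reads)}\n"
            )


def write_locus_fastq(read_set: LocusReadSet, path: Union[str, Path]) -> None:
    """Assembly input for one locus, mirroring the pipeline's FASTQ hand-off."""
    with open(path, "w") as fh:
        for rid, seq in zip(read_set.assembly_read_ids, read_set.assembly_reads):
            fh.write(f"@{rid}\n{seq}\n+\n{'?' * len(seq)}\n")
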