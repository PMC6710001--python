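"""Haplotype <-> reference coordinate maps.

A simulated haplotype differs from the reference only by insertions of whole
repeat units at tract starts, so the map is a sorted list of insertion
blocks.  The map answers two questions: where does a haplotype interval land
on the reference, and what CIGAR does a read from that interval get when
placed at its true reference position.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Union

__all__ = ["Insertion", "HaplotypeMap", "write_liftover", "read_liftover"]


@dataclass(frozen=True)
class Insertion:
    """One inserted segment: ``length`` haplotype bases at ``hap_start`` that
    have no reference counterpart; flanking bases map 1:1 around ``ref_pos``."""

    ref_pos: int
    hap_start: int
    length: int

    @property
    def hap_end(self) -> int:
        return self.hap_start + self.length


class HaplotypeMap:
    """Coordinate map for one haplotype of one chromosome."""

    def __init__(self, chrom: str, insertions: list[Insertion] | None = None):
        self.chrom = chrom
        self.insertions = sorted(insertions or [], key=lambda i: i.hap_start)
        self._hap_starts = [i.hap_start for i in self.insertions]

    def add(self, ref_pos: int, hap_start: int, length: int) -> None:
        self.insertions.append(Insertion(ref_pos, hap_start, length))
        self.insertions.sort(key=lambda i: i.hap_start)
        self._hap_starts = [i.hap_start for i in self.insertions]

    def shift_before(self, hap_pos: int) -> int:
        """Total inserted length strictly upstream of ``hap_pos``
        (positions inside an insertion count the consumed part)."""
        idx = bisect_right(self._hap_starts, hap_pos)
        total = 0
        for ins in self.insertions[:idx]:
            total += min(ins.length, hap_pos - ins.hap_start)
        return total

    def to_ref(self, hap_pos: int) -> int:
        """Project a haplotype position to the reference.  Positions inside
        an insertion project to the insertion's anchor point."""
        return hap_pos - self.shift_before(hap_pos)

    def cigar_for(self, hap_start: int, length: int) -> tuple[int, list[tuple[str, int]]]:
        """True placement of a haplotype interval: (ref_pos, cigar ops).

        Ops are ('M', n) / ('I', n) pairs; a read entirely inside an inserted
        tract yields a single I op anchored at the tract's reference start.
        """
        hap_end = hap_start + length
        ops: list[tuple[str, int]] = []
        pos = hap_start
        ref_pos = self.to_ref(hap_start)
        for ins in self.insertions:
            if ins.hap_end <= pos:
                continue
            if ins.hap_start >= hap_end:
                break
            if ins.hap_start > pos:
                ops.append(("M", ins.hap_start - pos))
                pos = ins.hap_start
            overlap = min(ins.hap_end, hap_end) - pos
            if overlap > 0:
                ops.append(("I", overlap))
                pos += overlap
        if pos < hap_end:
            ops.append(("M", hap_end - pos))
        # merge adjacent same-type ops (two abutting insertions)
        merged: list[tuple[str, int]] = []
        for op, n in ops:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + n)
            else:
                merged.append((op, n))
        return ref_pos, merged


def write_liftover(maps: dict[tuple[str, int], HaplotypeMap], path: Union[str, Path]) -> None:
    """TSV dump: one row per insertion, keyed by (chrom, haplotype)."""
    with open(path, "w") as fh:
        fh.write("#chrom\thaplotype\tref_pos\thap_start\tlength\n")
        for (chrom, hap), hmap in sorted(maps.items()):
            for ins in hmap.insertions:
                fh.write(f"{chrom}\t{hap}\t{ins.ref_pos}\t{ins.hap_start}\t{ins.length}\n")


def read_liftover(path: Union[str, Path]) -> dict[tuple[str, int], HaplotypeMap]:
    maps: dict[tuple[str, int], HaplotypeMap] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, hap, ref_pos, hap_start, length = line.split("\t")
            key = (chrom, int(hap))
            maps.setdefault(key, HaplotypeMap(chrom)).add(
                int(ref_pos), int(hap_start), int(length)
            )
    return maps
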