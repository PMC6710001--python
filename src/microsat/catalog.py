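"""Tandem-repeat annotation catalog.

Parses Tandem Repeats Finder / UCSC ``simpleRepeat``-style tables, applies
the locus filters used throughout the pipeline (perfect repeat match, unit
length > 3, copy number > 3), and exposes the filtered catalog that every
downstream stage consumes.

Coordinates are 0-based half-open internally.  UCSC ``simpleRepeat`` input is
already 0-based; native TRF output can be converted with ``one_based=True``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

__all__ = [
    "RawRepeatRecord",
    "MicrosatelliteLocus",
    "CatalogError",
    "parse_repeat_table",
    "filter_loci",
    "region_length",
    "write_catalog",
    "read_catalog",
]

_ALPHABET = set("ACGTN")


class CatalogError(ValueError):
    """Malformed annotation table or unusable dialect."""


@dataclass(frozen=True)
class RawRepeatRecord:
    """One line of a tandem-repeat annotation table, as annotated.

    ``start``/``end`` are 0-based half-open reference coordinates;
    ``percent_match`` is the annotation's repeat-consistency score (0-100).
    """

    chrom: str
    start: int
    end: int
    unit: str
    copy_number: float
    percent_match: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CatalogError(
                f"{self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if not self.unit or not set(self.unit) <= _ALPHABET:
            raise CatalogError(f"invalid repeat unit {self.unit!r}")
        if self.copy_number <= 0:
            raise CatalogError(f"copy_number must be > 0, got {self.copy_number}")

    @property
    def unit_length(self) -> int:
        return len(self.unit)


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """A filtered microsatellite locus (perfect match, unit and copies > 3)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    unit: str
    copy_number: float
    overlapping: bool = field(default=False, compare=False)

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def region_length(self) -> int:
        return self.end - self.start


def _open(stream: Union[str, Path, TextIO]) -> TextIO:
    if isinstance(stream, (str, Path)):
        return open(stream)
    return stream


def parse_repeat_table(
    stream: Union[str, Path, TextIO, str],
    *,
    one_based: bool = False,
) -> list[RawRepeatRecord]:
    """Parse a TRF-derived / UCSC simpleRepeat-like table.

    Accepted dialects (whitespace- or tab-delimited):

    * 7+ columns: ``chrom start end period copy_number percent_match unit``
      (UCSC simpleRepeat column order, ``bin`` column dropped);
    * 16/17 columns: the full UCSC ``simpleRepeat.txt`` row
      (``bin chrom start end name/period ... sequence``), detected by width.

    Lines starting with ``#`` and blank lines are skipped.  ``one_based``
    converts 1-based inclusive starts (native TRF) to 0-based half-open.
    """
    records: list[RawRepeatRecord] = []
    fh = _open(stream)
    for lineno, line in enumerate(fh, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        try:
            if len(fields) >= 16:
                # full UCSC simpleRepeat row: bin chrom start end period
                # copyNum consensusSize perMatch perIndel score A C G T
                # entropy sequence
                chrom = fields[1]
                start, end = int(fields[2]), int(fields[3])
                period = int(fields[4])
                copy_number = float(fields[5])
                percent_match = int(fields[7])
                unit = fields[-1].upper()
            elif len(fields) >= 7:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                period = int(fields[3])
                copy_number = float(fields[4])
                percent_match = int(fields[5])
                unit = fields[6].upper()
            else:
                raise CatalogError(
                    f"line {lineno}: expected >=7 columns, got {len(fields)}"
                )
        except (ValueError, IndexError) as exc:
            if isinstance(exc, CatalogError):
                raise
            raise CatalogError(f"line {lineno}: malformed record: {exc}") from exc
        if one_based:
            start -= 1
        if len(unit) != period:
            # annotation period and consensus unit disagree; trust the unit
            warnings.warn(
                f"line {lineno}: period {period} != len(unit) {len(unit)}; "
                "using the unit sequence",
                stacklevel=2,
            )
        records.append(
            RawRepeatRecord(
                chrom=chrom,
                start=start,
                end=end,
                unit=unit,
                copy_number=copy_number,
                percent_match=percent_match,
            )
        )
    return records


def passes_filters(record: RawRepeatRecord) -> bool:
    """Perfect repeat match, unit length > 3 and copy number > 3 (strict)."""
    return (
        record.percent_match == 100
        and record.unit_length > 3
        and record.copy_number > 3
    )


def filter_loci(records: Iterable[RawRepeatRecord]) -> list[MicrosatelliteLocus]:
    """Apply the catalog filters and assign stable locus ids.

    Keeps exactly the records with ``percent_match == 100``,
    ``unit_length > 3`` and ``copy_number > 3``; output is sorted by
    (chrom, start) with ``locus_id = chrom:start-end``.  Overlapping loci are
    kept but flagged so downstream stages can treat them independently.
    """
    kept = sorted(
        (r for r in records if passes_filters(r)),
        key=lambda r: (r.chrom, r.start, r.end),
    )
    overlapping = [False] * len(kept)
    for i in range(1, len(kept)):
        if kept[i].chrom == kept[i - 1].chrom and kept[i].start < kept[i - 1].end:
            overlapping[i] = overlapping[i - 1] = True
    return [
        MicrosatelliteLocus(
            locus_id=f"{rec.chrom}:{rec.start}-{rec.end}",
            chrom=rec.chrom,
            start=rec.start,
            end=rec.end,
            unit=rec.unit,
            copy_number=rec.copy_number,
            overlapping=flag,
        )
        for rec, flag in zip(kept, overlapping)
    ]


def region_length(locus: MicrosatelliteLocus) -> int:
    """Span of the tract in bp (= end - start).

    Cross-checked against ``round(copy_number * unit_length)``; a discrepancy
    beyond one unit length raises a validation warning, since region size is
    used to bin accuracy results.
    """
    span = locus.end - locus.start
    expected = round(locus.copy_number * locus.unit_length)
    if abs(span - expected) > locus.unit_length:
        warnings.warn(
            f"{locus.locus_id}: span {span} inconsistent with "
            f"copy_number*unit_length={expected}",
            stacklevel=2,
        )
    return span


def write_catalog(loci: Sequence[MicrosatelliteLocus], path: Union[str, Path]) -> None:
    """Write the filtered catalog as BED6+ TSV."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tlocus_id\tunit\tcopy_number\n")
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.locus_id}\t"
                f"{loc.unit}\t{loc.copy_number:g}\n"
            )


def read_catalog(path: Union[str, Path]) -> list[MicrosatelliteLocus]:
    """Read a catalog written by :func:`write_catalog`."""
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, locus_id, unit, copy_number = line.split("\t")
            loci.append(
                MicrosatelliteLocus(
                    locus_id=locus_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    unit=unit,
                    copy_number=float(copy_number),
                )
            )
    return loci


def serialize_repeat_table(records: Sequence[RawRepeatRecord]) -> str:
    """Render records back to the 7-column dialect (round-trip safe)."""
    buf = io.StringIO()
    buf.write("#chrom start end period copy_number percent_match unit\n")
    for r in records:
        buf.write(
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.unit_length}\t"
            f"{r.copy_number:g}\t{r.percent_match}\t{r.unit}\n"
        )
    return buf.getvalue()
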