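"""Synthetic reference sequences with planted microsatellite catalogs.

Emulates the study conditions of the benchmark: a random-genome backdrop
carrying perfect tandem tracts whose annotations pass the catalog filters
(unit length > 3, copy number > 3, perfect match).  Unit lengths are drawn
as 4 bp (60%), 5 bp (25%) and 6 bp (15%) — tetranucleotide repeats dominate
perfect-match catalogs — and reference copy numbers as 4 + Geometric(0.35)
with a fractional trailing unit, capped so region length stays within the
20-220 bp range observed on a real chromosome-scale catalog.  Tracts are
spaced at least ``min_gap`` apart and their boundaries are forced to break
the repeat periodicity, so each annotation is a maximal run, as a tandem
repeat finder would report it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import MicrosatelliteLocus, RawRepeatRecord, filter_loci

__all__ = ["SyntheticCatalogConfig", "make_reference_with_loci"]

_UNIT_LENGTHS = (4, 5, 6)
_UNIT_WEIGHTS = (0.60, 0.25, 0.15)
_MAX_REGION = 220  # bp, matches the observed catalog range
_BASES = "ACGT"


@dataclass(frozen=True)
class SyntheticCatalogConfig:
    length: int = 100_000
    n_loci: int = 30
    min_gap: int = 1_000  # bp between tracts; keeps capture windows disjoint
    copy_geom_p: float = 0.35
    seed: int = 0


def _random_unit(rng: np.random.Generator, unit_len: int) -> str:
    """A repeat unit that is not itself periodic (primitive unit)."""
    while True:
        unit = "".join(_BASES[i] for i in rng.integers(0, 4, size=unit_len))
        if len(set(unit)) == 1:
            continue
        # reject units with a smaller period (e.g. ATAT), so the annotated
        # unit length is the true period
        if all(
            any(unit[i] != unit[i % d] for i in range(unit_len))
            for d in range(1, unit_len)
            if unit_len % d == 0
        ):
            return unit


def make_reference_with_loci(
    config: SyntheticCatalogConfig = SyntheticCatalogConfig(),
) -> tuple[dict[str, str], list[MicrosatelliteLocus]]:
    """Build one synthetic chromosome and its filtered locus catalog."""
    rng = np.random.default_rng(config.seed)
    n = config.n_loci
    usable = config.length - 2 * config.min_gap
    if n > 0 and usable < n * config.min_gap:
        raise ValueError("reference too short for n_loci at min_gap spacing")

    seq = list("".join(_BASES[i] for i in rng.integers(0, 4, size=config.length)))

    # evenly strided tract anchor points with jitter keep gaps >= min_gap
    if n > 0:
        stride = usable / n
        anchors = [
            int(config.min_gap + i * stride + rng.integers(0, max(1, int(stride - config.min_gap) + 1)))
            for i in range(n)
        ]
    else:
        anchors = []

    records: list[RawRepeatRecord] = []
    for pos in anchors:
        unit_len = int(rng.choice(_UNIT_LENGTHS, p=_UNIT_WEIGHTS))
        unit = _random_unit(rng, unit_len)
        max_copies = _MAX_REGION // unit_len
        copies = 4 + int(rng.geometric(config.copy_geom_p))
        copies = min(copies, max_copies)
        extra = int(rng.integers(0, unit_len))  # fractional trailing unit
        if copies * unit_len + extra > _MAX_REGION:
            extra = 0
        tract = (unit * (copies + 1))[: copies * unit_len + extra]
        start, end = pos, pos + len(tract)
        seq[start:end] = tract
        # break periodicity at both boundaries so the annotation is maximal:
        # seq[start-1] must differ from seq[start-1+u], seq[end] from seq[end-u]
        if seq[start - 1] == tract[unit_len - 1]:
            seq[start - 1] = _other_base(rng, tract[unit_len - 1])
        if seq[end] == tract[len(tract) - unit_len]:
            seq[end] = _other_base(rng, tract[len(tract) - unit_len])
        records.append(
            RawRepeatRecord(
                chrom="chrS",
                start=start,
                end=end,
                unit=unit,
                copy_number=copies + extra / unit_len,
                percent_match=100,
            )
        )
    reference = {"chrS": "".join(seq)}
    return reference, filter_loci(records)


def _other_base(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in _BASES if b not in exclude]
    return choices[int(rng.integers(0, len(choices)))]
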