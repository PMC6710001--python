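"""Diploid microsatellite-expansion simulator.

Given a reference and a locus catalog, emits two haplotype sequences
(maternal/paternal) in which each locus is, per draw, left at the reference
allele or expanded by N extra repeat units (N uniform on [1, 30] by default),
together with a per-locus truth table and coordinate liftover maps.

Only expansions are simulated.  New units are inserted at the tract's 5'
boundary, preserving the repeat phase and leaving both flanks untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .catalog import MicrosatelliteLocus
from .liftover import HaplotypeMap
from .sequtils import matching_rotation

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "draw_event",
    "expand_region",
    "simulate_diploid",
    "write_truth",
    "read_truth",
]

HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"


@dataclass(frozen=True)
class SimulationConfig:
    """Genotype-drawing probabilities and the expansion-factor range.

    Defaults mirror the benchmark design: every locus is polymorphic
    (``p_hom_ref=0``), genotypes split evenly between homozygous-alternate
    and heterozygous, and both alleles of a heterozygous locus differ from
    the reference (``p_het_ref_allele=0``).
    """

    seed: int = 0
    p_het: float = 0.5
    p_hom_ref: float = 0.0
    p_het_ref_allele: float = 0.0
    n_min: int = 1
    n_max: int = 30

    def __post_init__(self) -> None:
        for name in ("p_het", "p_hom_ref", "p_het_ref_allele"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.n_min > self.n_max or self.n_min < 1:
            raise ValueError("need 1 <= n_min <= n_max")


@dataclass
class TruthRecord:
    """Ground truth for one locus: genotype class, per-allele copy numbers
    and expansion factors, plus the tract's coordinates on each haplotype."""

    locus_id: str
    genotype: str
    maternal_n: int
    paternal_n: int
    maternal_copy_number: float
    paternal_copy_number: float
    # tract coordinates on each emitted haplotype (filled by simulate_diploid)
    maternal_span: tuple[int, int] | None = None
    paternal_span: tuple[int, int] | None = None

    @property
    def alleles(self) -> tuple[float, float]:
        return (self.maternal_copy_number, self.paternal_copy_number)


def draw_event(
    locus: MicrosatelliteLocus,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> TruthRecord:
    """Draw one locus's diploid genotype.

    hom_alt shares a single N across both haplotypes (same sequence);
    het keeps one reference allele with probability ``p_het_ref_allele``,
    otherwise draws two distinct N values.  N is uniform on [n_min, n_max].
    """

    def rand_n() -> int:
        return int(rng.integers(config.n_min, config.n_max + 1))

    u = rng.random()
    if u < config.p_hom_ref:
        n_m = n_p = 0
        genotype = HOM_REF
    elif u < config.p_hom_ref + (1 - config.p_hom_ref) * config.p_het:
        genotype = HET
        if rng.random() < config.p_het_ref_allele:
            n_alt = rand_n()
            if rng.random() < 0.5:
                n_m, n_p = 0, n_alt
            else:
                n_m, n_p = n_alt, 0
        else:
            n_m = rand_n()
            n_p = rand_n()
            while n_p == n_m:
                n_p = rand_n()
    else:
        genotype = HOM_ALT
        n_m = n_p = rand_n()
    return TruthRecord(
        locus_id=locus.locus_id,
        genotype=genotype,
        maternal_n=n_m,
        paternal_n=n_p,
        maternal_copy_number=locus.copy_number + n_m,
        paternal_copy_number=locus.copy_number + n_p,
    )


class PhaseError(ValueError):
    """Annotated unit (no rotation) does not match the tract start."""


def expand_region(sequence: str, locus: MicrosatelliteLocus, n: int) -> str:
    """Insert ``n`` extra repeat units at the 5' boundary of the tract.

    The tract must begin with some rotation of the annotated unit; the
    matching rotation is the one inserted, so the expanded tract stays in
    phase and ``len(out) == len(in) + n * unit_length``.
    """
    if n == 0:
        return sequence
    tract = sequence[locus.start : locus.end]
    rot = matching_rotation(tract, locus.unit)
    if rot is None:
        raise PhaseError(
            f"{locus.locus_id}: unit {locus.unit} (no rotation) not found at tract start"
        )
    return sequence[: locus.start] + rot * n + sequence[locus.start :]


def simulate_diploid(
    reference: dict[str, str],
    loci: Sequence[MicrosatelliteLocus],
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], list[TruthRecord], dict[tuple[str, int], HaplotypeMap]]:
    """Simulate both haplotypes over all loci.

    Returns (maternal seqs, paternal seqs, truth records, liftover maps);
    liftover maps are keyed by (chrom, haplotype) with haplotype 1=maternal,
    2=paternal.  Loci are processed in (chrom, start) order from a single
    seeded stream, so outputs are byte-reproducible for a fixed config.
    Overlapping loci: the first wins, the rest are skipped with a warning.
    Loci whose tract does not start with any rotation of the unit are skipped
    with a warning (phase mismatch).
    """
    rng = np.random.default_rng(config.seed)
    ordered = sorted(loci, key=lambda l: (l.chrom, l.start, l.end))
    for loc in ordered:
        if loc.chrom not in reference:
            raise KeyError(f"{loc.locus_id}: chromosome {loc.chrom} not in reference")
        if loc.end > len(reference[loc.chrom]):
            raise ValueError(f"{loc.locus_id}: locus outside reference bounds")

    truth: list[TruthRecord] = []
    maternal: dict[str, str] = {}
    paternal: dict[str, str] = {}
    maps: dict[tuple[str, int], HaplotypeMap] = {}

    # group loci per chromosome, preserving order
    by_chrom: dict[str, list[MicrosatelliteLocus]] = {}
    for loc in ordered:
        by_chrom.setdefault(loc.chrom, []).append(loc)

    for chrom, seq in reference.items():
        chrom_loci = by_chrom.get(chrom, [])
        usable: list[MicrosatelliteLocus] = []
        prev_end = -1
        for loc in chrom_loci:
            if loc.start < prev_end:
                warnings.warn(
                    f"{loc.locus_id}: overlaps previous locus, skipped", stacklevel=2
                )
                continue
            if matching_rotation(seq[loc.start : loc.end], loc.unit) is None:
                warnings.warn(
                    f"{loc.locus_id}: phase mismatch with unit {loc.unit}, skipped",
                    stacklevel=2,
                )
                continue
            usable.append(loc)
            prev_end = loc.end

        events = [draw_event(loc, config, rng) for loc in usable]

        for hap_idx, n_attr, span_attr, out in (
            (1, "maternal_n", "maternal_span", maternal),
            (2, "paternal_n", "paternal_span", paternal),
        ):
            pieces: list[str] = []
            hmap = HaplotypeMap(chrom)
            cursor = 0
            shift = 0
            for loc, ev in zip(usable, events):
                n = getattr(ev, n_attr)
                pieces.append(seq[cursor : loc.start])
                tract = seq[loc.start : loc.end]
                if n > 0:
                    rot = matching_rotation(tract, loc.unit)
                    ins = rot * n
                    pieces.append(ins)
                    hmap.add(ref_pos=loc.start, hap_start=loc.start + shift, length=len(ins))
                    setattr(
                        ev,
                        span_attr,
                        (loc.start + shift, loc.end + shift + len(ins)),
                    )
                    shift += len(ins)
                else:
                    setattr(ev, span_attr, (loc.start + shift, loc.end + shift))
                pieces.append(tract)
                cursor = loc.end
            pieces.append(seq[cursor:])
            out[chrom] = "".join(pieces)
            maps[(chrom, hap_idx)] = hmap
        truth.extend(events)
    return maternal, paternal, truth, maps


_TRUTH_COLS = [
    "locus_id",
    "genotype",
    "maternal_n",
    "paternal_n",
    "maternal_copy_number",
    "paternal_copy_number",
    "maternal_start",
    "maternal_end",
    "paternal_start",
    "paternal_end",
]


def write_truth(records: Iterable[TruthRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TRUTH_COLS) + "\n")
        for r in records:
            m = r.maternal_span or (-1, -1)
            p = r.paternal_span or (-1, -1)
            fh.write(
                f"{r.locus_id}\t{r.genotype}\t{r.maternal_n}\t{r.paternal_n}\t"
                f"{r.maternal_copy_number:g}\t{r.paternal_copy_number:g}\t"
                f"{m[0]}\t{m[1]}\t{p[0]}\t{p[1]}\n"
            )


def read_truth(path: Union[str, Path]) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            records.append(
                TruthRecord(
                    locus_id=f[0],
                    genotype=f[1],
                    maternal_n=int(f[2]),
                    paternal_n=int(f[3]),
                    maternal_copy_number=float(f[4]),
                    paternal_copy_number=float(f[5]),
                    maternal_span=(int(f[6]), int(f[7])),
                    paternal_span=(int(f[8]), int(f[9])),
                )
            )
    return records
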