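"""Genotype and per-allele copy-number calling from contigs.

Reads are realigned to every contig of the locus; each read supports the
contig with the best semi-global alignment score (+1 match, -1 mismatch, -2
gap; ties leave the read unassigned).  The top two contigs by support decide
the genotype: a single usable contig, or a second contig below the
heterozygosity threshold (default 30% of the reads assigned to the top two),
means homozygous; otherwise heterozygous.  A locus flagged as carrying a
reference allele contributes the reference copy number as one allele slot.

Copy number is read off a contig by anchoring the reference flank (20 bp,
exact then 1-mismatch) and measuring the maximal tandem run of the unit next
to the anchor: copies = run length / unit length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import edlib

from .assemble import Contig
from .catalog import MicrosatelliteLocus
from .sequtils import max_tandem_run, periodic_run_length, matching_rotation

__all__ = [
    "GenotypeParams",
    "ContigSupport",
    "GenotypeCall",
    "assign_reads_to_contigs",
    "estimate_copy_number",
    "call_genotype",
    "write_calls",
    "read_calls",
]

CALLED = "CALLED"
NO_ASSEMBLY = "NO_ASSEMBLY"
NO_READS = "NO_READS"


@dataclass(frozen=True)
class GenotypeParams:
    het_min_fraction: float = 0.30  # second-allele support below this => homozygous
    het_min_reads: int | None = None  # absolute-count alternative to the fraction
    anchor_length: int = 20
    max_edit_fraction: float = 0.2  # read unalignable beyond this edit distance
    # contigs whose copy numbers agree within this represent the same allele
    # and pool their read support (layout can emit redundant fragments)
    allele_cluster_tolerance: float = 0.5


@dataclass
class ContigSupport:
    contig: Contig
    n_assigned_reads: int = 0
    support_fraction: float = 0.0
    copy_number: float | None = None


@dataclass
class GenotypeCall:
    locus_id: str
    genotype: str  # hom_ref | hom_alt | het
    status: str = CALLED
    allele1_copy_number: float | None = None
    allele2_copy_number: float | None = None  # None for homozygous calls
    contig_ids: list[str] = field(default_factory=list)
    support_fractions: list[float] = field(default_factory=list)
    multiallelic_suspect: bool = False

    @property
    def alleles(self) -> tuple[float, ...]:
        if self.allele2_copy_number is None:
            return (self.allele1_copy_number,) if self.allele1_copy_number is not None else ()
        return (self.allele1_copy_number, self.allele2_copy_number)


def _align_score(read: str, contig: str, max_edit_fraction: float) -> int | None:
    """Semi-global score of read vs contig (+1/-1/-2), None if unalignable."""
    if read in contig:
        return len(read)
    max_dist = int(len(read) * max_edit_fraction)
    res = edlib.align(read, contig, mode="HW", task="path", k=max_dist)
    if res["editDistance"] < 0:
        return None
    ins = dels = subs = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", res["cigar"] or ""):
        n = int(n)
        if op == "I":  # read base not in contig
            ins += n
        elif op == "D":
            dels += n
    subs = res["editDistance"] - ins - dels
    matches = len(read) - ins - subs
    return matches - subs - 2 * (ins + dels)


def flank_normalized_template(
    contig: Contig,
    locus: MicrosatelliteLocus,
    reference: dict[str, str] | str,
    params: GenotypeParams = GenotypeParams(),
    pad: int = 500,
) -> str:
    """Contig with both flanks extended to ``pad`` bp of reference sequence.

    Contigs of the two alleles of one locus can reach unequally far into the
    flanks purely by layout chance; since the flanks are non-polymorphic
    reference sequence under the model, reads lying in them carry no allele
    information and must tie during realignment.  Splicing full-length
    reference flanks onto each contig (located via the same anchors as the
    copy-number read-off) equalizes the flank reach so that only reads
    overlapping the tract's variation discriminate between alleles.
    """
    seq = contig.sequence
    ref = reference[locus.chrom] if isinstance(reference, dict) else reference
    a = params.anchor_length
    left = ref[max(0, locus.start - a) : locus.start]
    right = ref[locus.end : locus.end + a]
    lpos = _find_anchor(seq, left) if len(left) >= a else None
    rpos = _find_anchor(seq, right) if len(right) >= a else None
    if lpos is not None:
        seq = ref[max(0, locus.start - a - pad) : max(0, locus.start - a)] + seq[lpos:]
        if rpos is not None:
            rpos = rpos - lpos + min(pad, max(0, locus.start - a))
    if rpos is not None:
        seq = seq[: rpos + len(right)] + ref[locus.end + a : locus.end + a + pad]
    return seq


def assign_reads_to_contigs(
    reads: Sequence[str],
    contigs: Sequence[Contig],
    params: GenotypeParams = GenotypeParams(),
    templates: dict[str, str] | None = None,
) -> list[ContigSupport]:
    """Assign each read to its best-scoring contig; ties are unassigned.

    ``templates`` optionally substitutes an alignment template per contig id
    (see :func:`flank_normalized_template`).  Support fractions are over the
    total number of assigned reads.  Output order follows decreasing support
    (ties: contig id).
    """
    supports = {c.contig_id: ContigSupport(contig=c) for c in contigs}
    if not contigs:
        return []
    targets = {
        c.contig_id: (templates or {}).get(c.contig_id, c.sequence) for c in contigs
    }
    # contigs with byte-identical targets are the same allele rendered twice;
    # keep the first (layout rank order) so reads do not tie among copies
    seen: set[str] = set()
    candidates: list[Contig] = []
    for c in contigs:
        t = targets[c.contig_id]
        if t in seen:
            continue
        seen.add(t)
        candidates.append(c)
    for read in reads:
        best_score, best_ids = None, []
        for c in candidates:
            score = _align_score(read, targets[c.contig_id], params.max_edit_fraction)
            if score is None:
                continue
            if best_score is None or score > best_score:
                best_score, best_ids = score, [c.contig_id]
            elif score == best_score:
                best_ids.append(c.contig_id)
        if len(best_ids) == 1:
            supports[best_ids[0]].n_assigned_reads += 1
    total = sum(s.n_assigned_reads for s in supports.values())
    for s in supports.values():
        s.support_fraction = s.n_assigned_reads / total if total else 0.0
    return sorted(
        supports.values(), key=lambda s: (-s.n_assigned_reads, s.contig.contig_id)
    )


def estimate_copy_number(
    contig: Contig | str,
    locus: MicrosatelliteLocus,
    reference: dict[str, str] | str,
    params: GenotypeParams = GenotypeParams(),
) -> float | None:
    """Copy number of the locus tract inside a contig, or None if unanchored.

    The 5' reference flank is located in the contig (exact match, then one
    mismatch allowed) and the maximal tandem run of the unit adjacent to it
    is measured; failing that, the 3' flank anchors a leftward measurement.
    When both anchors are present the distance between them is used, which
    also captures fractional trailing units.
    """
    seq = contig.sequence if isinstance(contig, Contig) else contig
    ref = reference[locus.chrom] if isinstance(reference, dict) else reference
    a = params.anchor_length
    left = ref[max(0, locus.start - a) : locus.start]
    right = ref[locus.end : locus.end + a]
    u = locus.unit_length

    lpos = _find_anchor(seq, left) if len(left) >= a else None
    rpos = _find_anchor(seq, right) if len(right) >= a else None
    if lpos is not None and rpos is not None:
        span = rpos - (lpos + len(left))
        if span >= 0:
            return span / u
    if lpos is not None:
        start = lpos + len(left)
        run = max_tandem_run(seq, start, locus.unit)
        return run / u if run else None
    if rpos is not None:
        run = _max_tandem_run_leftward(seq, rpos, locus.unit)
        return run / u if run else None
    return None


def _find_anchor(seq: str, anchor: str) -> int | None:
    """Position of anchor in seq: exact first, then Hamming distance 1."""
    if not anchor:
        return None
    pos = seq.find(anchor)
    if pos >= 0:
        return pos
    n, a = len(seq), len(anchor)
    for i in range(n - a + 1):
        mism = 0
        for x, y in zip(seq[i : i + a], anchor):
            if x != y:
                mism += 1
                if mism > 1:
                    break
        if mism <= 1:
            return i
    return None


def _max_tandem_run_leftward(seq: str, end: int, unit: str) -> int:
    rev_seq = seq[:end][::-1]
    rev_unit = unit[::-1]
    if matching_rotation(rev_seq[: len(unit)], rev_unit) is None:
        return 0
    return periodic_run_length(rev_seq, 0, len(unit))


def _cluster_alleles(
    usable: list[tuple[ContigSupport, float]], tolerance: float
) -> list[tuple[ContigSupport, float]]:
    """Pool support of contigs that estimate the same allele.

    The layout stage may emit several staggered fragments of one allele
    (heterozygous loci share their 5' arm, and reads with sequencing errors
    seed parallel paths); what identifies an allele here is its copy number,
    so contigs agreeing within ``tolerance`` copies are aggregated.  The
    representative contig is the best-supported member; fractions are summed.
    """
    if not usable:
        return usable
    # greedy center-based grouping: the strongest contig anchors a cluster
    # and absorbs contigs within tolerance of *it* (no chain merging, so two
    # real alleles one copy apart never coalesce through a bridge fragment)
    remaining = sorted(usable, key=lambda t: (-t[0].n_assigned_reads, t[0].contig.contig_id))
    clustered: list[tuple[ContigSupport, float]] = []
    while remaining:
        rep, rep_cn = remaining[0]
        grp = [(s, cn) for s, cn in remaining if abs(cn - rep_cn) <= tolerance]
        remaining = [(s, cn) for s, cn in remaining if abs(cn - rep_cn) > tolerance]
        agg = ContigSupport(
            contig=rep.contig,
            n_assigned_reads=sum(s.n_assigned_reads for s, _cn in grp),
            support_fraction=sum(s.support_fraction for s, _cn in grp),
            copy_number=rep_cn,
        )
        clustered.append((agg, rep_cn))
    clustered.sort(key=lambda t: (-t[0].n_assigned_reads, t[0].contig.contig_id))
    return clustered


def call_genotype(
    supports: Sequence[ContigSupport],
    has_reference_allele: bool,
    locus: MicrosatelliteLocus,
    reference: dict[str, str] | str,
    params: GenotypeParams = GenotypeParams(),
    *,
    n_reads: int | None = None,
    n_reference_identical: int = 0,
) -> GenotypeCall:
    """Genotype one locus from contig supports and the reference-allele flag.

    The heterozygosity rule takes the two best-supported contigs with a
    usable copy number and recomputes their support fractions over the reads
    assigned to those two; a second fraction below ``het_min_fraction``
    (or count below ``het_min_reads`` in absolute mode) collapses the call
    to homozygous for the better contig.
    """
    usable: list[tuple[ContigSupport, float]] = []
    for s in supports:
        cn = s.copy_number
        if cn is None:
            cn = estimate_copy_number(s.contig, locus, reference, params)
            s.copy_number = cn
        if cn is not None:
            usable.append((s, cn))
    usable = _cluster_alleles(usable, params.allele_cluster_tolerance)

    if has_reference_allele:
        # the reference allele holds >=50% of the locus reads; an alternate
        # allele must differ from the reference copy number and carry at
        # least the heterozygosity threshold of the remaining read mass,
        # otherwise it is assembly noise from sequencing errors
        total_alt = sum(s.n_assigned_reads for s, _cn in usable)
        denom = max(1, total_alt + n_reference_identical)
        usable = [
            (s, cn)
            for s, cn in usable
            if abs(cn - locus.copy_number) > params.allele_cluster_tolerance
            and s.n_assigned_reads / denom >= params.het_min_fraction
        ]
        if not usable:
            return GenotypeCall(
                locus_id=locus.locus_id,
                genotype="hom_ref",
                allele1_copy_number=locus.copy_number,
            )
        strong = [
            (s, cn) for s, cn in usable[:2] if s.support_fraction >= params.het_min_fraction
        ]
        if len(strong) >= 2:
            # two strong alternate contigs plus a reference signal: report the
            # two alternates and flag the locus as multi-allelic suspect
            (s1, cn1), (s2, cn2) = strong[0], strong[1]
            return GenotypeCall(
                locus_id=locus.locus_id,
                genotype="het",
                allele1_copy_number=cn1,
                allele2_copy_number=cn2,
                contig_ids=[s1.contig.contig_id, s2.contig.contig_id],
                support_fractions=[s1.support_fraction, s2.support_fraction],
                multiallelic_suspect=True,
            )
        s, cn = usable[0]
        return GenotypeCall(
            locus_id=locus.locus_id,
            genotype="het",
            allele1_copy_number=locus.copy_number,
            allele2_copy_number=cn,
            contig_ids=[s.contig.contig_id],
            support_fractions=[s.support_fraction],
        )

    if not usable:
        if n_reads == 0:
            return GenotypeCall(locus_id=locus.locus_id, genotype="", status=NO_READS)
        return GenotypeCall(locus_id=locus.locus_id, genotype="", status=NO_ASSEMBLY)

    if len(usable) == 1:
        s, cn = usable[0]
        return GenotypeCall(
            locus_id=locus.locus_id,
            genotype="hom_alt",
            allele1_copy_number=cn,
            contig_ids=[s.contig.contig_id],
            support_fractions=[s.support_fraction],
        )

    (s1, cn1), (s2, cn2) = usable[0], usable[1]
    top2 = s1.n_assigned_reads + s2.n_assigned_reads
    frac2 = s2.n_assigned_reads / top2 if top2 else 0.0
    if params.het_min_reads is not None:
        is_het = s2.n_assigned_reads >= params.het_min_reads
    else:
        is_het = frac2 >= params.het_min_fraction
    if not is_het:
        return GenotypeCall(
            locus_id=locus.locus_id,
            genotype="hom_alt",
            allele1_copy_number=cn1,
            contig_ids=[s1.contig.contig_id],
            support_fractions=[s1.support_fraction],
        )
    return GenotypeCall(
        locus_id=locus.locus_id,
        genotype="het",
        allele1_copy_number=cn1,
        allele2_copy_number=cn2,
        contig_ids=[s1.contig.contig_id, s2.contig.contig_id],
        support_fractions=[s1.support_fraction, s2.support_fraction],
    )


_CALL_COLS = [
    "locus_id",
    "status",
    "genotype",
    "allele1_copy_number",
    "allele2_copy_number",
    "contigs",
    "support_fractions",
    "multiallelic_suspect",
]


def write_calls(calls: Sequence[GenotypeCall], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_CALL_COLS) + "\n")
        for c in calls:
            a1 = f"{c.allele1_copy_number:g}" if c.allele1_copy_number is not None else "."
            a2 = f"{c.allele2_copy_number:g}" if c.allele2_copy_number is not None else "."
            fh.write(
                f"{c.locus_id}\t{c.status}\t{c.genotype or '.'}\t{a1}\t{a2}\t"
                f"{','.join(c.contig_ids) or '.'}\t"
                f"{','.join(f'{f:.3f}' for f in c.support_fractions) or '.'}\t"
                f"{int(c.multiallelic_suspect)}\n"
            )


def read_calls(path: Union[str, Path]) -> list[GenotypeCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            calls.append(
                GenotypeCall(
                    locus_id=f[0],
                    status=f[1],
                    genotype="" if f[2] == "." else f[2],
                    allele1_copy_number=None if f[3] == "." else float(f[3]),
                    allele2_copy_number=None if f[4] == "." else float(f[4]),
                    contig_ids=[] if f[5] == "." else f[5].split(","),
                    support_fractions=[]
                    if f[6] == "."
                    else [float(x) for x in f[6].split(",")],
                    multiallelic_suspect=bool(int(f[7])),
                )
            )
    return calls


def write_vcf(
    calls: Sequence[GenotypeCall],
    loci: Sequence[MicrosatelliteLocus],
    path: Union[str, Path],
) -> None:
    """Minimal VCF-like output with symbolic STR alleles and copy numbers."""
    by_id = {l.locus_id: l for l in loci}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=RU,Number=1,Type=String,Description="Repeat unit">\n')
        fh.write('##INFO=<ID=REFCN,Number=1,Type=Float,Description="Reference copy number">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=CN,Number=.,Type=Float,Description="Allele copy numbers">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for c in calls:
            loc = by_id.get(c.locus_id)
            if loc is None or c.status != CALLED:
                continue
            gt = {"hom_ref": "0/0", "hom_alt": "1/1", "het": "0/1" if c.genotype == "het" and len(c.contig_ids) < 2 else "1/2"}
            cn = ",".join(f"{a:g}" for a in c.alleles)
            fh.write(
                f"{loc.chrom}\t{loc.start + 1}\t{c.locus_id}\tN\t<STR>\t.\tPASS\t"
                f"RU={loc.unit};REFCN={loc.copy_number:g}\tGT:CN\t"
                f"{gt.get(c.genotype, './.')}:{cn}\n"
            )
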