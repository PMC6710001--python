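"""Built-in greedy overlap-layout-consensus assembler for locus read sets.

The assembler exists so the pipeline is hermetic and testable; external
assemblers (SGA, Minia, Pamir, or any command template) can be substituted
through :func:`run_external_assembler` with the same contract: read
sequences in, ranked contigs out.

Layout is greedy merge in decreasing overlap-length order with lexicographic
tie-breaking, with one repeat-aware refinement.  Overlaps whose overlapping
sequence is a pure run of the locus unit carry no positional information: any
shift congruent modulo the unit length matches equally well, which is what
makes tandem tracts collapse in naive assemblers.  We therefore merge
anchored (non-periodic) overlaps first, and resolve the remaining periodic
join between the left- and right-anchored arms by a coverage-mass estimate:
the number of fully-periodic reads, divided by the local read-start density,
estimates the tract span, which is then snapped to the phase-consistent
grid.  Without a density hint the assembler falls back to the maximal
feasible overlap (the shortest consistent tract).
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

from .sequtils import is_periodic, revcomp, rotations

__all__ = [
    "AssemblyParams",
    "OverlapEdge",
    "Contig",
    "find_overlaps",
    "layout_and_consensus",
    "run_external_assembler",
    "ExternalToolError",
]


@dataclass(frozen=True)
class AssemblyParams:
    """Knobs of the internal assembler.

    ``min_overlap`` (40 bp) exceeds twice the longest unit in a filtered
    catalog, so a single unit repetition can never fake an overlap.  ``unit``
    and ``read_density`` (read starts per bp across both haplotypes) enable
    the repeat-aware layout; both are optional.
    """

    min_overlap: int = 40
    max_overlap_mismatches: int = 0
    min_reads_per_contig: int = 2
    seed: int = 0
    unit: str | None = None
    read_density: float | None = None

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be positive")


@dataclass(frozen=True)
class OverlapEdge:
    from_read: str
    to_read: str
    overlap_length: int
    orientation: str = "forward"  # or "reverse-complement"
    mismatches: int = 0
    containment: bool = False  # to_read contained in from_read


@dataclass
class Contig:
    contig_id: str
    sequence: str
    n_supporting_reads: int
    member_read_ids: list[str] = field(default_factory=list)


def _normalize(reads: Sequence) -> list[tuple[str, str]]:
    out = []
    for i, r in enumerate(reads):
        if isinstance(r, str):
            out.append((f"r{i:06d}", r.upper()))
        else:
            rid, seq = r
            out.append((str(rid), seq.upper()))
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _suffix_prefix_overlaps(
    nodes: list[tuple[str, str]], params: AssemblyParams
) -> list[tuple[str, str, int]]:
    """All maximal suffix->prefix overlaps >= min_overlap among nodes.

    Exact overlaps use a prefix-seed index (fast path); with a mismatch
    budget every shift of every ordered pair is scanned (small inputs only).
    Returns (from_id, to_id, overlap_length), the maximal overlap per pair.
    """
    k = params.min_overlap
    best: dict[tuple[str, str], int] = {}
    if params.max_overlap_mismatches == 0:
        prefix_index: dict[str, list[tuple[str, str]]] = {}
        for rid, seq in nodes:
            if len(seq) >= k:
                prefix_index.setdefault(seq[:k], []).append((rid, seq))
        for rid_a, seq_a in nodes:
            # longest overlap first: smallest suffix start i
            for i in range(1, len(seq_a) - k + 1):
                for rid_b, seq_b in prefix_index.get(seq_a[i : i + k], ()):
                    if rid_b == rid_a:
                        continue
                    o = len(seq_a) - i
                    if len(seq_b) >= o and seq_b[:o] == seq_a[i:]:
                        key = (rid_a, rid_b)
                        if key not in best:  # first hit is the longest
                            best[key] = o
    else:
        for rid_a, seq_a in nodes:
            for rid_b, seq_b in nodes:
                if rid_a == rid_b:
                    continue
                for o in range(min(len(seq_a), len(seq_b)), k - 1, -1):
                    if _hamming(seq_a[-o:], seq_b[:o]) <= params.max_overlap_mismatches:
                        best[(rid_a, rid_b)] = o
                        break
    return [(a, b, o) for (a, b), o in best.items()]


def find_overlaps(reads: Sequence, params: AssemblyParams, *, both_orientations: bool = False) -> list[OverlapEdge]:
    """Suffix-prefix and containment overlaps among reads.

    With ``both_orientations`` each read's reverse complement also enters the
    search and matching edges are labelled ``reverse-complement``.  The
    pipeline feeds reads already oriented to the reference strand, so the
    default is forward-only.
    """
    nodes = _normalize(reads)
    edges: list[OverlapEdge] = []
    # containments (including exact duplicates, reported once per pair)
    by_len = sorted(nodes, key=lambda n: (-len(n[1]), n[0]))
    for i, (rid_b, seq_b) in enumerate(by_len):
        for rid_a, seq_a in by_len[:i]:
            if len(seq_b) <= len(seq_a) and seq_b in seq_a:
                edges.append(
                    OverlapEdge(rid_a, rid_b, len(seq_b), containment=True)
                )
            elif both_orientations and revcomp(seq_b) in seq_a:
                edges.append(
                    OverlapEdge(rid_a, rid_b, len(seq_b), orientation="reverse-complement", containment=True)
                )
    contained = {e.to_read for e in edges}
    free = [n for n in nodes if n[0] not in contained]
    for a, b, o in _suffix_prefix_overlaps(free, params):
        edges.append(OverlapEdge(a, b, o, mismatches=0))
    if both_orientations:
        rc_nodes = [(f"{rid}'", revcomp(seq)) for rid, seq in free]
        fwd_ids = {rid for rid, _ in free}
        for a, b, o in _suffix_prefix_overlaps(free + rc_nodes, params):
            a_rc, b_rc = a.endswith("'"), b.endswith("'")
            if a_rc == b_rc:
                continue  # fwd-fwd already reported; rc-rc mirrors it
            edges.append(
                OverlapEdge(a.rstrip("'"), b.rstrip("'"), o, orientation="reverse-complement")
            )
    return edges


class _Chain:
    """A layout chain: reads at offsets from the chain start.

    ``head_rid``/``tail_rid`` are the reads exposed for further suffix-prefix
    merging; contained reads folded into a chain never become ends.
    """

    __slots__ = ("members", "head_rid", "tail_rid", "override_seq")

    def __init__(self, rid: str, seq: str, weight: int):
        self.members: list[tuple[int, str, str, int]] = [(0, rid, seq, weight)]
        self.head_rid = rid
        self.tail_rid = rid
        self.override_seq: str | None = None  # set by the periodic-gap join

    @property
    def length(self) -> int:
        return max(off + len(seq) for off, rid, seq, w in self.members)

    def sequence(self) -> str:
        """Per-column majority vote, weighted by read multiplicity.

        With exact overlaps every member agrees and the vote degenerates to
        concatenation; ties break to the lexicographically smallest base."""
        if self.override_seq is not None:
            return self.override_seq
        L = self.length
        counts: list[dict[str, int]] = [dict() for _ in range(L)]
        for off, _rid, seq, w in self.members:
            for j, ch in enumerate(seq):
                d = counts[off + j]
                d[ch] = d.get(ch, 0) + w
        return "".join(
            max(sorted(d), key=d.get) if d else "N" for d in counts
        )

    def weight(self) -> int:
        return sum(w for _off, _rid, _seq, w in self.members)

    def read_ids(self) -> list[str]:
        return [rid for _off, rid, _seq, _w in self.members]


def _periodic_suffix_len(seq: str, unit: str) -> int:
    """Length of the maximal suffix of ``seq`` that is a pure unit run."""
    u = len(unit)
    n = len(seq)
    if n < u or seq[n - u :] not in set(rotations(unit)):
        return 0
    i = n - u
    while i > 0 and seq[i - 1] == seq[i - 1 + u]:
        i -= 1
    return n - i


def _periodic_prefix_len(seq: str, unit: str) -> int:
    """Length of the maximal prefix of ``seq`` that is a pure unit run."""
    u = len(unit)
    n = len(seq)
    if n < u or seq[:u] not in set(rotations(unit)):
        return 0
    i = u
    while i < n and seq[i] == seq[i - u]:
        i += 1
    return i


def layout_and_consensus(reads: Sequence, params: AssemblyParams) -> list[Contig]:
    """Greedy OLC assembly of one locus's reads into ranked contigs.

    Steps: deduplicate and absorb contained reads; merge anchored overlaps
    greedily (decreasing overlap, lexicographic ties); resolve at most one
    periodic join via the coverage-mass rule (see module docstring); emit
    majority-vote consensus contigs sorted by read support, dropping contigs
    below ``min_reads_per_contig``.
    """
    nodes = _normalize(reads)
    if not nodes:
        return []

    # 1. deduplicate identical sequences
    uniq: dict[str, tuple[str, list[str]]] = {}
    for rid, seq in sorted(nodes):
        if seq in uniq:
            uniq[seq][1].append(rid)
        else:
            uniq[seq] = (rid, [rid])
    unodes = [(rid, seq) for seq, (rid, _members) in uniq.items()]
    members_of = {rid: mem for _seq, (rid, mem) in uniq.items()}

    # 2. absorb proper containments into the longest container
    unodes.sort(key=lambda n: (-len(n[1]), n[0]))
    absorbed: dict[str, tuple[str, int]] = {}  # contained rid -> (container rid, offset)
    for i, (rid_b, seq_b) in enumerate(unodes):
        for rid_a, seq_a in unodes[:i]:
            if rid_a in absorbed:
                continue
            pos = seq_a.find(seq_b)
            if pos >= 0:
                absorbed[rid_b] = (rid_a, pos)
                break
    free = [(rid, seq) for rid, seq in unodes if rid not in absorbed]

    # 3. overlap edges among free nodes, split anchored vs periodic
    raw_edges = _suffix_prefix_overlaps(free, params)
    seqs = dict(free)
    anchored, periodic = [], []
    for a, b, o in raw_edges:
        ov = seqs[b][:o]
        if params.unit and is_periodic(ov, params.unit):
            periodic.append((a, b, o))
        else:
            anchored.append((a, b, o))

    # 4. greedy chain merge on anchored edges
    chain_of: dict[str, _Chain] = {
        rid: _Chain(rid, seq, len(members_of[rid])) for rid, seq in free
    }
    seq_of = dict(unodes)
    # fold absorbed reads into their container's chain as extra members
    for rid_b in absorbed:
        container, off = _resolve(absorbed, rid_b)
        chain_of[container].members.append(
            (off, rid_b, seq_of[rid_b], len(members_of[rid_b]))
        )

    def merge(order: list[tuple[str, str, int]]) -> None:
        for a, b, o in sorted(order, key=lambda e: (-e[2], e[0], e[1])):
            ca, cb = chain_of.get(a), chain_of.get(b)
            if ca is None or cb is None or ca is cb:
                continue
            if ca.tail_rid != a or cb.head_rid != b:
                continue
            tail_off = next(off for off, rid, _s, _w in ca.members if rid == a)
            shift = tail_off + len(seq_of[a]) - o
            for off, rid, seq, w in cb.members:
                ca.members.append((off + shift, rid, seq, w))
                chain_of[rid] = ca
            ca.tail_rid = cb.tail_rid

    merge(anchored)

    chains = list({id(c): c for c in chain_of.values()}.values())

    # 5. repeat-aware resolution of the periodic gap
    if params.unit:
        chains = _resolve_periodic_gap(chains, periodic, chain_of, params)
    else:
        merge(periodic)
        chains = list({id(c): c for c in chain_of.values()}.values())

    # 6. consensus, unambiguous containment absorption, ranking
    contigs = []
    for chain in chains:
        contigs.append(
            Contig(
                contig_id="",
                sequence=chain.sequence(),
                n_supporting_reads=chain.weight(),
                member_read_ids=sorted(
                    rid2 for rid in chain.read_ids() for rid2 in members_of.get(rid, [rid])
                ),
            )
        )
    contigs = _merge_redundant_contigs(contigs, params)
    contigs = [c for c in contigs if c.n_supporting_reads >= params.min_reads_per_contig]
    contigs.sort(key=lambda c: (-c.n_supporting_reads, -len(c.sequence), c.sequence))
    for i, c in enumerate(contigs):
        c.contig_id = f"contig{i}"
    return contigs


def _merge_redundant_contigs(contigs: list[Contig], params: AssemblyParams) -> list[Contig]:
    """Fold redundant layout fragments into the contig they extend.

    Greedy path cover can emit several staggered paths through a shared
    region (e.g. the two haplotypes of a heterozygous locus share their 5'
    arm), splitting read support.  A contig is merged when it is contained
    in, or has an anchored exact suffix-prefix overlap with, exactly one
    other contig; a fragment compatible with several contigs is
    allele-ambiguous and stays separate, so its reads resolve through the
    realignment tie rule instead.  Purely periodic overlaps never merge here
    (their shift is not identifiable).
    """

    def sp_overlap(a: str, b: str) -> int:
        """Largest o with suffix(a, o) == prefix(b, o), anchored, else 0."""
        for o in range(min(len(a), len(b)) - 1, params.min_overlap - 1, -1):
            if a[-o:] == b[:o]:
                if params.unit and is_periodic(b[:o], params.unit):
                    return 0
                return o
        return 0

    # merge exact duplicates first
    by_seq: dict[str, Contig] = {}
    for c in sorted(contigs, key=lambda c: (c.sequence, -c.n_supporting_reads)):
        if c.sequence in by_seq:
            keep = by_seq[c.sequence]
            keep.n_supporting_reads += c.n_supporting_reads
            keep.member_read_ids = sorted(keep.member_read_ids + c.member_read_ids)
        else:
            by_seq[c.sequence] = c
    pool = sorted(by_seq.values(), key=lambda c: (len(c.sequence), c.sequence))

    changed = True
    while changed:
        changed = False
        for c in sorted(pool, key=lambda c: (len(c.sequence), c.sequence)):
            merges: list[tuple[Contig, str, int]] = []
            for d in pool:
                if d is c:
                    continue
                if c.sequence in d.sequence:
                    merges.append((d, "contained", 0))
                    continue
                o = sp_overlap(c.sequence, d.sequence)
                if o:
                    merges.append((d, "extends_right", o))
                o = sp_overlap(d.sequence, c.sequence)
                if o:
                    merges.append((d, "extends_left", o))
            if len({id(m[0]) for m in merges}) != 1:
                continue
            d, kind, o = merges[0]
            if kind == "extends_right":
                d.sequence = c.sequence + d.sequence[o:]
            elif kind == "extends_left":
                d.sequence = d.sequence + c.sequence[o:]
            d.n_supporting_reads += c.n_supporting_reads
            d.member_read_ids = sorted(d.member_read_ids + c.member_read_ids)
            pool.remove(c)
            changed = True
            break
    return pool


def _resolve(absorbed: dict[str, tuple[str, int]], rid: str) -> tuple[str, int]:
    off = 0
    while rid in absorbed:
        rid, pos = absorbed[rid]
        off += pos
    return rid, off


def _nearly_periodic(seq: str, unit: str, max_violations: int = 4) -> bool:
    """True if ``seq`` is a unit run up to a few isolated base errors."""
    u = len(unit)
    if len(seq) < 2 * u:
        return False
    violations = sum(1 for i in range(u, len(seq)) if seq[i] != seq[i - u])
    return violations <= max_violations


def _trusted_span(chain: _Chain) -> tuple[int, int]:
    """Columns of the chain covered by total read weight >= 2.

    Single-read chains (and chains whose every column is thin) return their
    full span: there is nothing better to fall back on.
    """
    length = chain.length
    cov = [0] * length
    for off, _rid, seq, w in chain.members:
        for j in range(off, off + len(seq)):
            cov[j] += w
    lo, hi = 0, length
    while lo < hi and cov[lo] < 2:
        lo += 1
    while hi > lo and cov[hi - 1] < 2:
        hi -= 1
    if lo >= hi:
        return 0, length
    return lo, hi


def _resolve_periodic_gap(
    chains: list[_Chain],
    periodic_edges: list[tuple[str, str, int]],
    chain_of: dict[str, _Chain],
    params: AssemblyParams,
) -> list[_Chain]:
    """Join a left-anchored and right-anchored arm across the tract.

    The join synthesizes the periodic fill at the coverage-mass length (or
    the maximal-overlap length without a density hint) and absorbs all
    fully-periodic chains as members of the merged contig.
    """
    unit = params.unit
    assert unit is not None
    u = len(unit)

    info = []
    for ch in chains:
        # measure and splice arms only up to their multi-coverage span on the
        # tract-facing side: a chain tip covered by a single read can carry
        # an uncorrected sequencing error, which would truncate the periodic
        # overhang, corrupt the phase residue and leave stray tract bases
        # beside the fill.  The far (flank) tip is kept as assembled.
        seq = ch.sequence()
        lo, hi = _trusted_span(ch)
        info.append(
            {
                "chain": ch,
                "seq": seq,
                "as_left": seq[:hi],  # right tip trimmed
                "as_right": seq[lo:],  # left tip trimmed
                "full": is_periodic(seq, unit),
                "suf": _periodic_suffix_len(seq[:hi], unit),
                "pre": _periodic_prefix_len(seq[lo:], unit),
            }
        )
    # tract-interior mass: strictly periodic chains plus nearly-periodic ones
    # (an interior read with a sequencing error breaks strict periodicity at
    # <= 2 positions per error; flank sequence violates it almost everywhere,
    # so a small violation budget cleanly separates the two).  Without this,
    # the mass — and hence the tract length — is deflated by roughly the
    # per-read error probability.
    internal = [d for d in info if d["full"] or _nearly_periodic(d["seq"], unit)]
    # an arm must be a real assembly (enough read support) that genuinely
    # dangles into the tract (periodic overhang of at least two units);
    # flank sequence is periodic by chance for ~u bases often enough that a
    # 1-unit overhang would let complete contigs masquerade as arms and be
    # spliced into chimeras
    min_overhang = 2 * u
    lefts = [
        d
        for d in info
        if not d["full"]
        and d["suf"] >= min_overhang
        and d["chain"].weight() >= max(2, params.min_reads_per_contig)
    ]
    rights = [
        d
        for d in info
        if not d["full"]
        and d["pre"] >= min_overhang
        and d["chain"].weight() >= max(2, params.min_reads_per_contig)
    ]
    if not lefts or not rights:
        return chains

    left = max(lefts, key=lambda d: (d["chain"].weight(), d["suf"], d["seq"]))
    rights = [d for d in rights if d is not left]
    if not rights:
        return chains
    right = max(rights, key=lambda d: (d["chain"].weight(), d["pre"], d["seq"]))

    lseq, rseq = left["as_left"], right["as_right"]
    s_l, s_r = left["suf"], right["pre"]
    r0 = lseq[len(lseq) - s_l : len(lseq) - s_l + u]
    if len(r0) < u:
        return chains
    # phase of the right arm's periodic prefix relative to r0
    delta = None
    probe = rseq[: min(s_r, u)]
    for d in range(u):
        if all(probe[i] == r0[(d + i) % u] for i in range(len(probe))):
            delta = d
            break
    if delta is None:
        return chains  # incompatible phases; leave arms separate

    read_len = max(
        (len(seq) for ch in chains for _o, _r, seq, _w in ch.members), default=150
    )
    mass = sum(d["chain"].weight() for d in internal)
    # tract span T must satisfy T = s_r + delta (mod u) and T >= max(s_l, s_r)
    t_min = max(s_l, s_r)
    residue = (s_r + delta) % u
    if mass > 0 and params.read_density and params.read_density > 0:
        # fully-periodic reads start anywhere in the tract's interior:
        # E[mass] = density * (T - read_len + 1), so invert and snap to grid
        t_raw = (read_len - 1) + mass / params.read_density
    else:
        # no interior reads: the tract barely exceeds what the anchored arms
        # cover, and the arms' own periodic reach is the best estimate
        t_raw = t_min
    t = int(round((t_raw - residue) / u)) * u + residue
    while t < t_min:
        t += u

    fill = "".join(r0[i % u] for i in range(t))
    merged_seq = lseq[: len(lseq) - s_l] + fill + rseq[s_r:]

    lchain, rchain = left["chain"], right["chain"]
    new = _Chain(lchain.head_rid, "", 0)
    new.members = list(lchain.members)
    new.tail_rid = rchain.tail_rid
    new.override_seq = merged_seq
    rshift = len(merged_seq) - len(rseq)
    for off, rid, seq, w in rchain.members:
        new.members.append((off + rshift, rid, seq, w))
    # internal chains are consumed as support for the fill
    for d in internal:
        for off, rid, seq, w in d["chain"].members:
            pos = merged_seq.find(seq)
            new.members.append((pos if pos >= 0 else len(lseq) - s_l, rid, seq, w))
    consumed = {id(lchain), id(rchain)} | {id(d["chain"]) for d in internal}
    out = [c for c in chains if id(c) not in consumed] + [new]
    for _off, rid, _seq, _w in new.members:
        chain_of[rid] = new
    return out


class ExternalToolError(RuntimeError):
    """External assembler missing or failed."""


_TOOL_TEMPLATES = {
    "sga": "sga assemble {input} -o {outdir}/contigs.fa",
    "minia": "minia -in {input} -out {outdir}/minia",
    "pamir": "pamir assemble {input} -o {outdir}",
}


def run_external_assembler(
    tool_spec: str,
    fastq_path: Union[str, Path],
    outdir: Union[str, Path],
    *,
    contig_fasta: str | None = None,
) -> list[Contig]:
    """Run an external assembler on one locus FASTQ and parse its contigs.

    ``tool_spec`` is ``sga``/``minia``/``pamir`` (default command lines) or a
    custom command template with ``{input}`` and ``{outdir}`` placeholders.
    Contigs are read from ``contig_fasta`` (default: any ``*.fa``/``*.fasta``
    in ``outdir``); read-support counts are left at 0 and filled later by
    realignment in the genotyper.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    template = _TOOL_TEMPLATES.get(tool_spec, tool_spec)
    cmd = template.format(input=str(fastq_path), outdir=str(outdir))
    prog = cmd.split()[0]
    if shutil.which(prog) is None:
        raise ExternalToolError(f"assembler binary not found on PATH: {prog!r}")
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise ExternalToolError(
            f"{prog} exited with {proc.returncode}: {proc.stderr.strip()[:500]}"
        )
    fasta = Path(contig_fasta) if contig_fasta else None
    if fasta is None:
        candidates = sorted(outdir.glob("*.fa")) + sorted(outdir.glob("*.fasta"))
        fasta = candidates[0] if candidates else None
    if fasta is None or not fasta.exists():
        return []
    return parse_contig_fasta(fasta)


def parse_contig_fasta(path: Union[str, Path]) -> list[Contig]:
    """FASTA -> Contig records; a ``reads=N`` token in the header is honored."""
    contigs: list[Contig] = []
    name, seq_parts = None, []

    def flush() -> None:
        if name is None:
            return
        m = re.search(r"reads=(\d+)", name)
        contigs.append(
            Contig(
                contig_id=name.split()[0],
                sequence="".join(seq_parts).upper(),
                n_supporting_reads=int(m.group(1)) if m else 0,
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                flush()
                name, seq_parts = line[1:], []
            elif line:
                seq_parts.append(line)
        flush()
    return contigs
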