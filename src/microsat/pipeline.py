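"""End-to-end pipeline orchestration: simulate, call, evaluate, sweep.

The five pipeline stages (align/place, extract, preprocess, assemble,
genotype) run per locus behind three entry points mirroring the command-line
interface.  One global seed deterministically derives every module seed, and
each run can write a manifest (inputs, hashes, seed, config dump) so results
are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml

from . import catalog as catalog_mod
from .assemble import AssemblyParams, Contig, layout_and_consensus
from .catalog import MicrosatelliteLocus, filter_loci, parse_repeat_table, read_catalog, write_catalog
from .diploid import SimulationConfig, TruthRecord, read_truth, simulate_diploid, write_truth
from .evaluate import EvaluationRecord, binned_metrics, score_call
from .extract import LocusReadSet, apply_reference_rule, collect_locus_reads, write_locus_summary
from .genotype import GenotypeCall, GenotypeParams, assign_reads_to_contigs, call_genotype, read_calls, write_calls
from .liftover import read_liftover, write_liftover
from .reads import ReadSimConfig, simulate_reads, truth_place_alignments, write_fastq

logger = logging.getLogger("microsat")

__all__ = ["PipelineConfig", "run_simulate", "run_call", "run_evaluate", "run_sweep"]


@dataclass
class PipelineConfig:
    """All module configurations plus the global seed that derives them."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    reads: ReadSimConfig = field(default_factory=ReadSimConfig)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    genotyping: GenotypeParams = field(default_factory=GenotypeParams)
    window: int = 350
    include_flanks: bool = False
    tolerance: float = 0.25
    bin_edges: list[int] | None = None

    def __post_init__(self) -> None:
        # one global seed -> independent, reproducible module streams
        ss = np.random.SeedSequence(self.seed)
        sim_seed, read_seed, asm_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
        )
        self.simulation = replace(self.simulation, seed=sim_seed)
        self.reads = replace(self.reads, seed=read_seed)
        self.assembly = replace(self.assembly, seed=asm_seed)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub_cls in (
            ("simulation", SimulationConfig),
            ("reads", ReadSimConfig),
            ("assembly", AssemblyParams),
            ("genotyping", GenotypeParams),
        ):
            if key in raw:
                kwargs[key] = sub_cls(**raw.pop(key))
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "simulation": asdict(self.simulation),
            "reads": asdict(self.reads),
            "assembly": asdict(self.assembly),
            "genotyping": asdict(self.genotyping),
            "window": self.window,
            "include_flanks": self.include_flanks,
            "tolerance": self.tolerance,
            "bin_edges": self.bin_edges,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, config: PipelineConfig, files: Sequence[Path], extra: dict | None = None) -> None:
    manifest = {
        "config": config.to_dict(),
        "files": {str(p.name): _sha256(p) for p in files if p.exists()},
    }
    if extra:
        manifest.update(extra)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _read_fasta(path: Union[str, Path]) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _write_fasta(seqs: dict[str, str], path: Union[str, Path]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def run_simulate(
    reference: Union[str, Path, dict[str, str]],
    repeat_table: Union[str, Path, Sequence[MicrosatelliteLocus], None],
    config: PipelineConfig,
    outdir: Union[str, Path],
    *,
    one_based: bool = False,
) -> dict[str, Path]:
    """Catalog -> diploid haplotypes -> reads -> truth placements.

    ``repeat_table`` may be an annotation table path (filtered here) or an
    already-filtered locus list.  Writes haplotype FASTAs, paired FASTQ, the
    truth table, liftover map, truth-placement SAM, the filtered catalog and
    a manifest into ``outdir``; returns the file map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = reference if isinstance(reference, dict) else _read_fasta(reference)
    if repeat_table is None:
        raise ValueError("a repeat table or locus list is required")
    if isinstance(repeat_table, (str, Path)):
        loci = filter_loci(parse_repeat_table(repeat_table, one_based=one_based))
    else:
        loci = list(repeat_table)
    logger.info("simulate: %d loci over %d sequence(s)", len(loci), len(ref))

    maternal, paternal, truth, maps = simulate_diploid(ref, loci, config.simulation)
    haplotypes = {(chrom, 1): seq for chrom, seq in maternal.items()}
    haplotypes.update({(chrom, 2): seq for chrom, seq in paternal.items()})
    pairs = simulate_reads(haplotypes, config.reads, truth_records=truth)

    files: dict[str, Path] = {}
    files["catalog"] = outdir / "catalog.tsv"
    write_catalog(loci, files["catalog"])
    files["maternal"] = outdir / "haplotype_maternal.fasta"
    files["paternal"] = outdir / "haplotype_paternal.fasta"
    _write_fasta(maternal, files["maternal"])
    _write_fasta(paternal, files["paternal"])
    files["truth"] = outdir / "truth.tsv"
    write_truth(truth, files["truth"])
    files["liftover"] = outdir / "liftover.tsv"
    write_liftover(maps, files["liftover"])
    fq1, fq2 = write_fastq(pairs, outdir / "reads")
    files["fastq_1"], files["fastq_2"] = fq1, fq2
    files["truth_sam"] = outdir / "truth_placements.sam"
    truth_place_alignments(
        pairs,
        maps,
        {chrom: len(seq) for chrom, seq in ref.items()},
        files["truth_sam"],
        read_length=config.reads.read_length,
    )
    _write_manifest(outdir, config, list(files.values()), {"n_loci": len(loci), "n_pairs": len(pairs)})
    return files


def call_locus(
    read_set: LocusReadSet,
    reference: dict[str, str],
    config: PipelineConfig,
) -> tuple[GenotypeCall, list[Contig]]:
    """Preprocess -> assemble -> genotype for one locus."""
    locus = read_set.locus
    apply_reference_rule(read_set, include_flanks=config.include_flanks)
    density = _local_read_density(read_set, config)
    params = replace(config.assembly, unit=locus.unit, read_density=density)
    contigs = layout_and_consensus(
        list(zip(read_set.assembly_read_ids, read_set.assembly_reads)), params
    )
    from .genotype import flank_normalized_template

    pad = config.window + config.reads.read_length
    templates = {
        c.contig_id: flank_normalized_template(c, locus, reference, config.genotyping, pad)
        for c in contigs
    }
    supports = assign_reads_to_contigs(
        read_set.assembly_reads, contigs, config.genotyping, templates
    )
    call = call_genotype(
        supports,
        read_set.has_reference_allele,
        locus,
        reference,
        config.genotyping,
        n_reads=len(read_set.reads) + len(read_set.flank_reads),
        n_reference_identical=read_set.n_reference_identical,
    )
    logger.debug(
        "locus %s: reads=%d flank=%d ref_frac=%.2f contigs=%d -> %s %s",
        locus.locus_id,
        len(read_set.reads),
        len(read_set.flank_reads),
        read_set.ref_fraction,
        len(contigs),
        call.status,
        call.genotype,
    )
    return call, contigs


def _local_read_density(read_set: LocusReadSet, config: PipelineConfig) -> float | None:
    """Read-start density (reads/bp, both haplotypes) from the flank reads.

    Flank-only reads start uniformly over the window flanks (exactly
    ``window`` candidate start positions on each side); their count divided
    by that span estimates the local depth without knowing the nominal
    coverage, which also works for externally aligned data.
    """
    span = 2 * config.window
    n = len(read_set.flank_reads)
    if n == 0:
        return None
    return n / span


def run_call(
    alignments: Union[str, Path],
    catalog: Union[str, Path, Sequence[MicrosatelliteLocus]],
    reference: Union[str, Path, dict[str, str]],
    config: PipelineConfig,
    outdir: Union[str, Path],
) -> dict[str, Path]:
    """Extract -> preprocess -> assemble -> genotype over a catalog.

    ``alignments`` is a SAM/BAM (truth placements or an external aligner's
    output).  Per-locus failures are logged and recorded as NO_ASSEMBLY
    rather than aborting the run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = reference if isinstance(reference, dict) else _read_fasta(reference)
    loci = read_catalog(catalog) if isinstance(catalog, (str, Path)) else list(catalog)

    read_sets = collect_locus_reads(alignments, loci, window=config.window)
    calls: list[GenotypeCall] = []
    for rs in read_sets:
        try:
            call, _contigs = call_locus(rs, ref, config)
        except Exception:  # pragma: no cover - defensive per-locus isolation
            logger.exception("locus %s failed; recorded as NO_ASSEMBLY", rs.locus_id)
            call = GenotypeCall(locus_id=rs.locus_id, genotype="", status="NO_ASSEMBLY")
        calls.append(call)

    files = {
        "calls": outdir / "calls.tsv",
        "locus_summary": outdir / "locus_summary.tsv",
    }
    write_calls(calls, files["calls"])
    write_locus_summary(read_sets, files["locus_summary"])
    _write_manifest(outdir, config, list(files.values()), {"n_loci": len(loci)})
    n_called = sum(1 for c in calls if c.status == "CALLED")
    logger.info("call: %d/%d loci called", n_called, len(calls))
    return files


def run_evaluate(
    truth: Union[str, Path, Sequence[TruthRecord]],
    calls: Union[str, Path, Sequence[GenotypeCall]],
    catalog: Union[str, Path, Sequence[MicrosatelliteLocus]],
    config: PipelineConfig,
    outdir: Union[str, Path],
    *,
    plot: bool = False,
):
    """Score calls against truth; returns (records, metrics DataFrame)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_records = read_truth(truth) if isinstance(truth, (str, Path)) else list(truth)
    call_records = read_calls(calls) if isinstance(calls, (str, Path)) else list(calls)
    loci = read_catalog(catalog) if isinstance(catalog, (str, Path)) else list(catalog)
    by_locus = {l.locus_id: l for l in loci}
    call_by_locus = {c.locus_id: c for c in call_records}
    missing = [t.locus_id for t in truth_records if t.locus_id not in by_locus]
    if missing:
        raise KeyError(f"truth loci missing from catalog: {missing[:5]}...")

    records: list[EvaluationRecord] = []
    for t in truth_records:
        records.append(
            score_call(t, call_by_locus.get(t.locus_id), by_locus[t.locus_id], config.tolerance)
        )
    metrics = binned_metrics(records, config.bin_edges)
    metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    if plot:
        from .evaluate import plot_tpr_by_region_size

        plot_tpr_by_region_size(metrics, outdir / "tpr_by_region_size.png")
    return records, metrics


def run_sweep(
    reference: Union[str, Path, dict[str, str]],
    repeat_table: Union[str, Path, Sequence[MicrosatelliteLocus]],
    config: PipelineConfig,
    outdir: Union[str, Path],
    coverages: Sequence[float] = (40, 60, 80),
):
    """Coverage titration: simulate once, downsample, call and evaluate.

    Haplotypes and genotypes are simulated once (they are the experiment's
    truth), reads are generated once at the deepest coverage, and each
    shallower depth is a nested random subsample of the same fragments —
    the standard paired design for coverage titrations, which measures the
    effect of depth rather than resampling noise.  Returns a summary frame
    with one row per coverage.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = reference if isinstance(reference, dict) else _read_fasta(reference)
    if isinstance(repeat_table, (str, Path)):
        loci = filter_loci(parse_repeat_table(repeat_table))
    else:
        loci = list(repeat_table)

    max_cov = max(float(c) for c in coverages)
    deep_config = replace(config)
    deep_config.reads = replace(config.reads, coverage=max_cov)
    maternal, paternal, truth, maps = simulate_diploid(ref, loci, deep_config.simulation)
    haplotypes = {(chrom, 1): seq for chrom, seq in maternal.items()}
    haplotypes.update({(chrom, 2): seq for chrom, seq in paternal.items()})
    pairs = simulate_reads(haplotypes, deep_config.reads, truth_records=truth)
    subsample_rng = np.random.default_rng(deep_config.reads.seed + 1)
    order = subsample_rng.permutation(len(pairs))
    ref_lengths = {chrom: len(seq) for chrom, seq in ref.items()}

    rows = []
    for cov in sorted(float(c) for c in coverages):
        covdir = outdir / f"cov{cov:g}x"
        covdir.mkdir(parents=True, exist_ok=True)
        keep = int(round(len(pairs) * cov / max_cov))
        subset = [pairs[i] for i in sorted(order[:keep])]
        cov_config = replace(config)
        cov_config.reads = replace(config.reads, coverage=cov)
        write_catalog(loci, covdir / "catalog.tsv")
        write_truth(truth, covdir / "truth.tsv")
        sam = covdir / "truth_placements.sam"
        truth_place_alignments(subset, maps, ref_lengths, sam, config.reads.read_length)
        run_call(sam, covdir / "catalog.tsv", ref, cov_config, covdir)
        _records, metrics = run_evaluate(
            covdir / "truth.tsv", covdir / "calls.tsv", covdir / "catalog.tsv", cov_config, covdir
        )
        overall = metrics[(metrics.stratum == "all") & (metrics.bin == "overall")].iloc[0]
        rows.append(
            {
                "coverage": cov,
                "n_simulated": int(overall.n_simulated),
                "n_full_hits": int(overall.n_full_hits),
                "tpr": float(overall.tpr),
                "partial_tpr": float(overall.partial_tpr),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "sweep_summary.tsv", sep="\t", index=False)
    return summary
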