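import warnings

import pytest

from microsat.catalog import MicrosatelliteLocus
from microsat.pipeline import PipelineConfig, run_call, run_evaluate, run_simulate
from microsat.synth import SyntheticCatalogConfig, make_reference_with_loci

warnings.filterwarnings("ignore", category=UserWarning)


def make_locus(
    chrom="chr1", start=100, end=120, unit="ACAG", copy_number=5.0
) -> MicrosatelliteLocus:
    return MicrosatelliteLocus(
        locus_id=f"{chrom}:{start}-{end}",
        chrom=chrom,
        start=start,
        end=end,
        unit=unit,
        copy_number=copy_number,
    )


@pytest.fixture(scope="session")
def small_world():
    """A 40 kb synthetic chromosome with 10 planted loci."""
    return make_reference_with_loci(
        SyntheticCatalogConfig(length=40_000, n_loci=10, seed=5)
    )


@pytest.fixture(scope="session")
def small_run(small_world, tmp_path_factory):
    """Full simulate+call+evaluate on the small world (shared across tests)."""
    ref, loci = small_world
    outdir = tmp_path_factory.mktemp("small_run")
    cfg = PipelineConfig(seed=9)
    files = run_simulate(ref, loci, cfg, outdir)
    run_call(files["truth_sam"], files["catalog"], ref, cfg, outdir)
    records, metrics = run_evaluate(
        files["truth"], outdir / "calls.tsv", files["catalog"], cfg, outdir
    )
    return {
        "ref": ref,
        "loci": loci,
        "config": cfg,
        "outdir": outdir,
        "files": files,
        "records": records,
        "metrics": metrics,
    }
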