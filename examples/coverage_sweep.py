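"""Effect of sequencing depth on genotyping accuracy.

Simulates one set of diploid expansions, generates reads once at 80x, and
re-genotypes nested subsamples at 40x and 60x — a paired titration, so the
printed TPR differences measure depth itself rather than resampling noise.
Full-hit TPR should be non-decreasing in coverage, with most of the gain
between 40x and 60x.
"""

from microsat.pipeline import PipelineConfig, run_sweep
from microsat.synth import SyntheticCatalogConfig, make_reference_with_loci

ref, loci = make_reference_with_loci(
    SyntheticCatalogConfig(length=100_000, n_loci=30, seed=7)
)
summary = run_sweep(
    ref, loci, PipelineConfig(seed=3), "example_output/sweep", coverages=(40, 60, 80)
)
print(summary.to_string(index=False))
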