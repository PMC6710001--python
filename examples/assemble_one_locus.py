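"""Assemble and size a single expanded repeat tract from raw reads.

Plants an ACAG microsatellite (6 reference copies) in random sequence,
expands it by 12 extra units on both haplotypes, tiles the expanded region
with error-free 150 bp reads, assembles them with the internal greedy OLC
assembler, and reads the copy number back off the contig via the flank
anchors.  The expanded tract (72 bp) is shorter than a read here, so
assembly is exact and the measured copy number equals the truth.
"""

import numpy as np

from microsat.assemble import AssemblyParams, layout_and_consensus
from microsat.catalog import MicrosatelliteLocus
from microsat.diploid import expand_region
from microsat.genotype import estimate_copy_number

rng = np.random.default_rng(11)
flank = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

unit, ref_copies, n_extra = "ACAG", 6, 12
reference = flank(300) + unit * ref_copies + flank(300)
locus = MicrosatelliteLocus(
    locus_id="demo", chrom="demo", start=300, end=300 + 4 * ref_copies,
    unit=unit, copy_number=float(ref_copies),
)

haplotype = expand_region(reference, locus, n_extra)
print(f"reference tract: {ref_copies} x {unit} ({4 * ref_copies} bp)")
print(f"expanded tract:  {ref_copies + n_extra} copies "
      f"(+{n_extra * 4} bp inserted at the 5' boundary)")

window = haplotype[locus.start - 150 : locus.end + n_extra * 4 + 150]
reads = [window[i : i + 150] for i in range(0, len(window) - 150 + 1, 5)]
contigs = layout_and_consensus(reads, AssemblyParams(unit=unit))
top = contigs[0]
copies = estimate_copy_number(top, locus, reference)
print(f"reads assembled: {len(reads)} -> {len(contigs)} contig(s); "
      f"best contig {len(top.sequence)} bp, {top.n_supporting_reads} reads")
print(f"copy number from contig: {copies} (truth {ref_copies + n_extra})")
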