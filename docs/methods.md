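# Methods

`microsat` genotypes microsatellites (short tandem repeats, STRs) from short
paired-end reads by local assembly: reads near an annotated repeat tract are
extracted, filtered, assembled into contigs with a repeat-aware greedy
overlap-layout-consensus (OLC) algorithm, and the contigs are converted to a
diploid genotype with per-allele copy numbers. A self-contained simulation
stack (diploid expansion simulator, paired-end read simulator with truth
placements) provides ground truth for benchmarking, and the evaluation module
scores calls as full hits, partial hits and misses, binned by repeat region
size. This note records the model, the parameters that matter, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Locus catalog

The unit of analysis is a catalog of microsatellite loci derived from a
Tandem Repeats Finder / UCSC `simpleRepeat`-style annotation table.
Annotations are kept when the repeat is perfect (`percent_match == 100`) and
both the unit length and the copy number are strictly greater than 3; both
inequalities are strict, so 4 bp units at 4 copies are the smallest loci
considered. Coordinates are 0-based half-open internally; native TRF output
(1-based starts) is converted with `one_based=True`. Region length — the
quantity used to bin accuracy — is `end − start`, cross-checked against
`round(copy_number × unit_length)`. Overlapping annotations are kept but
flagged; downstream stages treat them independently.

## Diploid expansion model

Each catalog locus receives a diploid genotype draw:

* homozygous-reference with probability `p_hom_ref` (default 0),
* heterozygous with probability `p_het` among polymorphic loci (default 0.5),
* homozygous-alternate otherwise.

An expansion inserts `N` extra copies of the repeat unit at the tract's 5′
boundary, with `N` uniform on `{1..30}`. A homozygous-alternate locus shares
one `N` across both haplotypes; a heterozygous locus draws two distinct `N`
values, or keeps one reference allele with probability `p_het_ref_allele`
(default 0: both alleles differ from the reference). Insertion uses the unit
rotation observed at the tract start, so the expanded tract stays in phase
and both flanks are untouched; only expansions are modelled, not
contractions, and no SNP/indel background is added. The simulator emits both
haplotype sequences, a truth table (genotype, per-allele copy numbers, tract
coordinates per haplotype) and a liftover map of the inserted segments. Exact
bookkeeping holds by construction:
`len(haplotype) − len(reference) = Σ N × unit_length`.

## Read simulation and truth placement

Fragments are drawn uniformly along each haplotype with Normal(350 bp, 35 bp)
lengths; reads are 150 bp, FR-oriented, with flat Q30 qualities and i.i.d.
per-base substitution errors (default 0.001/base — a generic short-read
figure; indel errors, GC bias and duplicates are not modelled). The pair
count per haplotype is `round(coverage × L / (2 × 2 × read_length))`, so the
nominal coverage is the diploid total. An optional PCR-stutter knob
(off by default) adds or removes one repeat unit from a fragment overlapping
a tract with the given probability.

Because every fragment's origin is known, the simulator can place each read
at its true reference-projected position, producing a coordinate-sorted SAM
whose CIGARs carry an insertion operation wherever the read crosses an
expanded segment (a read entirely inside an insertion is anchored at the
tract start with a single `I` op), and `NM` equal to inserted bases plus
simulated substitutions. This truth-placement SAM stands in for an external
aligner and makes the downstream stages exactly testable; any coordinate-
sorted SAM/BAM from a real aligner can be substituted.

## Extraction and the reference rule

Reads are captured for a locus when their alignment span overlaps the window
`[start − w, end + w)` (default `w` = 350 bp, the mean fragment length). A
read is *reference-identical* iff its CIGAR is a single match run and
`NM == 0`; soft clips, indels, or any mismatch disqualify it. The ≥50%
reference rule is evaluated over the reads that overlap the repeat tract
itself (or carry an insertion at its boundary): if at least half of them are
reference-identical, the locus is flagged as carrying a reference allele and
those reads are removed from the assembly input. Flank-only reads are
excluded from both the rule's denominator and the assembly input by default
(`include_flanks` re-admits them): they are reference-identical for every
genotype, so counting them would flag nearly every locus and, worse, strip
the reference-identical reads that cover the *unmodified* 3′ part of an
expanded tract — amputating the right junction from the assembly.

## Assembly

The internal assembler is a greedy OLC path cover with one repeat-aware
refinement. After deduplicating identical reads (multiplicities retained as
weights) and absorbing contained reads, suffix–prefix overlaps of at least
`min_overlap` (default 40 bp, comfortably above twice the longest catalog
unit) are merged in decreasing overlap order with lexicographic
tie-breaking; consensus is a weighted per-column majority vote.

Overlaps whose overlapping sequence is a pure run of the locus unit carry no
positional information: any shift congruent modulo the unit length matches
equally well, which is why tandem tracts collapse in naive assemblers.
Anchored (non-periodic) overlaps are therefore merged first. The remaining
join between a left-anchored arm (unique flank + periodic overhang) and a
right-anchored arm is resolved by a coverage-mass estimate: the number of
fully-periodic reads `M` satisfies `E[M] = ρ (T − read_length + 1)` for
tract span `T` and local read-start density `ρ` (estimated from the flank
reads), so `T̂ = read_length − 1 + M/ρ`, snapped to the phase-consistent
grid `T ≡ s_r + δ (mod u)` and clamped to the geometric minimum
`max(s_l, s_r)`; with `M = 0` the geometric minimum itself is used. The fill
between the arms is synthesized from the unit rotation, and the interior
chains are absorbed as support. Robustness details: arms must carry at least
`min_reads_per_contig` reads and a periodic overhang of ≥ 2 units
(single error reads with accidental periodic suffixes otherwise seed
chimeras); arms are measured and spliced over their multi-coverage columns
on the tract-facing side (a single-coverage tip can carry an uncorrected
error that corrupts the phase); and the interior mass also counts
nearly-periodic chains (≤ 4 periodicity violations), since an interior read
with one substitution would otherwise drop out and deflate `T̂` by roughly
the per-read error probability.

After layout, fragments contained in — or anchored-overlapping with —
exactly one other contig are folded into it; fragments compatible with
several contigs are allele-ambiguous and stay separate so that their reads
resolve through the realignment tie rule. Contigs with fewer than
`min_reads_per_contig` (default 2) supporting reads are dropped; survivors
are ranked by read support. External assemblers (SGA, Minia, Pamir, or any
command template with `{input}`/`{outdir}` placeholders) can be substituted
through `run_external_assembler` with the same reads-in/ranked-contigs-out
contract.

### Identifiability limit

A tract longer than about `2 × read_length − flank anchor` cannot be sized
combinatorially from single-end reads: every overlap across it is periodic
and length is known only modulo the unit. In that regime the copy number
rests entirely on the Poisson coverage-mass estimate, whose standard
deviation (`√M/ρ` ≈ 8–17 bp at 60× for 180–320 bp tracts) often exceeds half
a unit, so calls there are right only with moderate probability and improve
slowly (∝ 1/√coverage). This is an information limit of the data, not of the
implementation; read pairs or longer reads would be required to do better.
Heterozygous loci inherit a second difficulty: the two alleles differ only in
tract length, share their entire 5′ arm, and (when the length difference is a
unit multiple) even their 3′ junction reads, so allele-discriminating reads
can be scarce — consistent with the much lower heterozygous accuracy that
mapping- and assembly-based callers show in this problem domain.

## Genotyping

Reads are realigned to every contig; each read supports the contig with the
best semi-global score (+1 match, −1 mismatch, −2 gap; exact-substring fast
path, edlib alignment otherwise, reads beyond 20% edit distance are
unalignable; ties leave the read unassigned). Two refinements make the
support counts mean what the decision rule assumes:

* **Flank normalization.** Contigs are aligned against templates whose
  flanks are extended with reference sequence (located via the same anchors
  as the copy-number read-off). Flanks are non-polymorphic under the model,
  so a flank read carries no allele information; without normalization it
  would follow whichever contig's layout happened to reach further.
  Byte-identical templates are deduplicated so copies of one allele do not
  tie away its own reads.
* **Allele clustering.** Contigs whose copy-number estimates agree within
  0.5 copies are pooled (greedy, centered on the strongest contig — no chain
  merging, so two real alleles one copy apart never coalesce through a
  bridge fragment). The layout stage can emit several staggered fragments of
  one allele; what identifies an allele here is its copy number.

The decision rule then follows the top two allele clusters: one usable
cluster → homozygous; second cluster below 30% of the reads assigned to the
top two → homozygous for the best; otherwise heterozygous (boundary
inclusive: exactly 30% is heterozygous). An absolute-count mode
(`het_min_reads`) is available since a fraction-vs-count reading of the
threshold is ambiguous. If the locus was flagged as carrying a reference
allele, the reference copy number fills one allele slot and an alternate
allele must both differ from the reference copy number and carry at least
the heterozygosity threshold of the remaining read mass (alt-assigned plus
reference-identical reads) — otherwise error-read assemblies would convert
homozygous-reference loci into false heterozygotes. Two strong alternate
clusters under a reference flag are reported as heterozygous and flagged
multi-allelic-suspect.

Copy number is read off a contig by locating the 20 bp reference flank
(exact match, then one mismatch) and measuring the maximal tandem run of the
unit — any rotation — adjacent to the anchor; with both anchors present the
inter-anchor distance is used, which also captures fractional trailing
units. A contig with no anchor is unusable for the locus.

## Evaluation

Truth and call alleles are compared as pairs under the best order-free
assignment with a copy-number tolerance (default 0.25, i.e. agreement after
rounding to the nearest half unit; set 0 for strictly integer comparisons):
both alleles matched → full hit; exactly one → partial hit; otherwise miss.
A homozygous call occupies both allele slots, so a heterozygous call matching
a homozygous truth once is a partial hit, mirroring the heterozygous
definition. Genotype concordance compares only the heterozygous/homozygous
classification. Metrics are tabulated per region-size bin (15 bp bins over
20–230 bp by default, overflow bin beyond) and overall, stratified by true
genotype; partial-or-better counts include full hits, and a strict
partial-only column is also emitted.

## The coverage sweep

The sweep simulates haplotypes and genotypes once, generates reads once at
the deepest requested coverage, and evaluates each shallower depth on a
nested random subsample of the same fragments — the standard paired design
for coverage titrations (equivalent to downsampling one deep sequencing
run). Independent per-coverage read sets would confound the small deep-
coverage gains with resampling noise at benchmark-sized catalogs.

## Synthetic study conditions

The default benchmark is a 100 kb random reference carrying 30 loci spaced
at least 1 kb apart (capture windows stay disjoint). Unit lengths are drawn
as 4 bp (60%), 5 bp (25%), 6 bp (15%) — tetranucleotides dominate
perfect-match catalogs — and reference copy numbers as 4 + Geometric(0.35)
with a fractional trailing unit, capped so region length stays within the
20–220 bp range a chromosome-scale catalog shows. Tract boundaries are
forced to break the repeat periodicity so each annotation is a maximal run,
as a tandem repeat finder would report it. Genotype and read-simulation
defaults are as above (p_het = 0.5, both het alleles alternate, N uniform on
1–30, 150 bp reads, 350 ± 35 bp fragments).

What passing on this benchmark shows: the bookkeeping (coordinates,
liftover, CIGARs), the filtering and decision rules, and the repeat-aware
assembly behave exactly as specified, and copy numbers are recovered exactly
wherever the data determine them. What it does not show: robustness to
alignment artifacts of a real mapper, PCR stutter (available as a knob but
off by default), indel sequencing errors, SNP-heterozygous flanks,
contractions, or catalogs of imperfect repeats — all outside the model.

## Problem sizes and determinism

The shipped tests and the acceptance script run the benchmark at 100 kb / 30
loci and coverages 40–80×, sizes at which every stage is exercised end to
end in seconds per run. One global seed drives everything: the pipeline
derives per-module seeds from it via `numpy.random.SeedSequence`, rerunning
with the same configuration is byte-identical (manifests record input hashes
and the config), and different seeds give different read sets.
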