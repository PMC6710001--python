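"""Benchmark scoring: full hits, partial hits and TPR by region size.

A call is a FULL_HIT when both true allele copy numbers are recovered (under
the comparison tolerance, order-free), a PARTIAL_HIT when exactly one is, and
a MISS otherwise.  Genotype concordance compares only the heterozygous vs
homozygous classification, ignoring copy numbers.  Metrics are reported
overall and binned by reference region size (copy number x unit length),
stratified by true genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .catalog import MicrosatelliteLocus
from .diploid import TruthRecord
from .genotype import CALLED, GenotypeCall

__all__ = [
    "FULL_HIT",
    "PARTIAL_HIT",
    "MISS",
    "EvaluationRecord",
    "score_call",
    "binned_metrics",
    "default_bin_edges",
    "plot_tpr_by_region_size",
]

FULL_HIT = "FULL_HIT"
PARTIAL_HIT = "PARTIAL_HIT"
MISS = "MISS"


@dataclass(frozen=True)
class EvaluationRecord:
    locus_id: str
    truth_genotype: str
    called_genotype: str | None
    truth_alleles: tuple[float, float]
    called_alleles: tuple[float, ...]
    outcome: str
    genotype_concordant: bool
    region_size: int
    reason: str = ""


def _as_pair(alleles: Sequence[float]) -> tuple[float, float] | None:
    """Diploid view of a call: homozygous calls occupy both slots."""
    if len(alleles) == 0:
        return None
    if len(alleles) == 1:
        return (alleles[0], alleles[0])
    return (alleles[0], alleles[1])


def _n_matched(truth: tuple[float, float], called: tuple[float, float], tol: float) -> int:
    """Best order-free assignment of called to true alleles (0, 1 or 2)."""

    def ok(a: float, b: float) -> bool:
        return abs(a - b) <= tol + 1e-9

    best = 0
    for c in (called, called[::-1]):
        best = max(best, ok(truth[0], c[0]) + ok(truth[1], c[1]))
    return best


def score_call(
    truth: TruthRecord,
    call: GenotypeCall | None,
    locus: MicrosatelliteLocus,
    tolerance: float = 0.25,
) -> EvaluationRecord:
    """Score one locus.

    ``tolerance`` is the maximum copy-number deviation that still counts as
    a correct allele (0.25 by default, i.e. agreement after rounding to the
    nearest half unit; use 0 for strictly integer simulations).
    """
    region_size = round(locus.copy_number * locus.unit_length)
    truth_pair = (truth.maternal_copy_number, truth.paternal_copy_number)
    if call is None or call.status != CALLED:
        return EvaluationRecord(
            locus_id=truth.locus_id,
            truth_genotype=truth.genotype,
            called_genotype=None,
            truth_alleles=truth_pair,
            called_alleles=(),
            outcome=MISS,
            genotype_concordant=False,
            region_size=region_size,
            reason=call.status if call is not None else "no call",
        )
    called_pair = _as_pair(call.alleles)
    matched = _n_matched(truth_pair, called_pair, tolerance) if called_pair else 0
    outcome = FULL_HIT if matched == 2 else PARTIAL_HIT if matched == 1 else MISS
    concordant = (truth.genotype == "het") == (call.genotype == "het")
    return EvaluationRecord(
        locus_id=truth.locus_id,
        truth_genotype=truth.genotype,
        called_genotype=call.genotype,
        truth_alleles=truth_pair,
        called_alleles=call.alleles,
        outcome=outcome,
        genotype_concordant=concordant,
        region_size=region_size,
    )


def default_bin_edges(width: int = 15, lo: int = 20, hi: int = 220) -> list[int]:
    """Region-size bin edges: ``width`` bp bins spanning the catalog range."""
    return list(range(lo, hi + width, width))


def binned_metrics(
    records: Sequence[EvaluationRecord],
    bin_edges: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-bin and overall hit counts and rates, stratified by genotype.

    Rows: one per (bin x stratum) plus overall rows; strata are ``all``,
    ``hom`` and ``het``.  Records outside the bin range land in an overflow
    bin.  Columns: n_simulated, n_full_hits, n_partial_hits (strict),
    n_partial_or_better, tpr (full hits / simulated), partial_tpr
    (partial-or-better / simulated), genotype_concordance.
    """
    edges = list(bin_edges) if bin_edges is not None else default_bin_edges()

    def bin_label(size: int) -> str:
        for lo, hi in zip(edges, edges[1:]):
            if lo <= size < hi:
                return f"[{lo},{hi})"
        if edges and size < edges[0]:
            return f"<{edges[0]}"
        return f">={edges[-1]}" if edges else "all-sizes"

    rows = []
    recs = list(records)
    strata = {
        "all": recs,
        "hom": [r for r in recs if r.truth_genotype in ("hom_ref", "hom_alt")],
        "het": [r for r in recs if r.truth_genotype == "het"],
    }
    labels = [f"[{lo},{hi})" for lo, hi in zip(edges, edges[1:])]
    extra = sorted({bin_label(r.region_size) for r in recs} - set(labels))
    for stratum, srecs in strata.items():
        groups = {lbl: [] for lbl in labels + extra}
        for r in srecs:
            groups[bin_label(r.region_size)].append(r)
        for lbl in labels + extra + ["overall"]:
            sub = srecs if lbl == "overall" else groups[lbl]
            n = len(sub)
            full = sum(r.outcome == FULL_HIT for r in sub)
            partial = sum(r.outcome == PARTIAL_HIT for r in sub)
            conc = sum(r.genotype_concordant for r in sub)
            rows.append(
                {
                    "stratum": stratum,
                    "bin": lbl,
                    "n_simulated": n,
                    "n_full_hits": full,
                    "n_partial_hits": partial,
                    "n_partial_or_better": full + partial,
                    "tpr": full / n if n else 0.0,
                    "partial_tpr": (full + partial) / n if n else 0.0,
                    "genotype_concordance": conc / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows)


def overall_tpr(metrics: pd.DataFrame, stratum: str = "all") -> float:
    row = metrics[(metrics.stratum == stratum) & (metrics.bin == "overall")]
    return float(row.tpr.iloc[0]) if len(row) else 0.0


def plot_tpr_by_region_size(
    metrics: pd.DataFrame, path: Union[str, Path], stratum: str = "all"
) -> None:
    """Bar plot of full-hit and partial-or-better TPR per region-size bin."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = metrics[(metrics.stratum == stratum) & (metrics.bin != "overall")]
    x = np.arange(len(sub))
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(sub)), 4))
    ax.bar(x - 0.2, sub.tpr, width=0.4, label="full hit TPR")
    ax.bar(x + 0.2, sub.partial_tpr, width=0.4, label="partial-or-better TPR")
    ax.set_xticks(x)
    ax.set_xticklabels(sub.bin, rotation=45, ha="right")
    ax.set_xlabel("reference region size (bp)")
    ax.set_ylabel("true positive rate")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
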