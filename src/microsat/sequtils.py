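"""Small sequence helpers shared across the pipeline.

Tandem-tract arithmetic lives here: rotations of a repeat unit, maximal
periodic runs, and phase detection.  These are the primitives behind both the
simulator's truth bookkeeping and the genotyper's copy-number read-off, so
they are written once and property-tested once.
"""

from __future__ import annotations

__all__ = [
    "revcomp",
    "rotations",
    "matching_rotation",
    "periodic_run_length",
    "is_periodic",
    "max_tandem_run",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def rotations(unit: str) -> list[str]:
    """All cyclic rotations of ``unit`` (deduplicated, order-preserving)."""
    seen: dict[str, None] = {}
    for i in range(len(unit)):
        seen.setdefault(unit[i:] + unit[:i])
    return list(seen)


def matching_rotation(seq: str, unit: str) -> str | None:
    """Rotation of ``unit`` that ``seq`` starts with, or None."""
    for rot in rotations(unit):
        if seq.startswith(rot):
            return rot
    return None


def periodic_run_length(seq: str, start: int, period: int) -> int:
    """Length of the maximal run at ``start`` where seq[i] == seq[i - period].

    The first ``period`` bases seed the run; the run then extends while the
    periodicity holds.  Returns 0 if fewer than ``period`` bases remain.
    """
    n = len(seq)
    if start + period > n:
        return max(0, n - start)
    i = start + period
    while i < n and seq[i] == seq[i - period]:
        i += 1
    return i - start


def is_periodic(seq: str, unit: str) -> bool:
    """True if ``seq`` is entirely a run of some rotation of ``unit``.

    Sequences shorter than one unit count as periodic when they are a prefix
    of some rotation (they carry no phase-breaking information).
    """
    u = len(unit)
    if len(seq) < u:
        return any(rot.startswith(seq) for rot in rotations(unit))
    if matching_rotation(seq, unit) is None:
        return False
    return all(seq[i] == seq[i - u] for i in range(u, len(seq)))


def max_tandem_run(seq: str, start: int, unit: str) -> int:
    """Maximal tandem run of ``unit`` (any rotation) anchored at ``start``.

    Returns the run length in bases; the run must begin with a full rotation
    of the unit, then extends base-by-base while periodicity holds.  This is
    the measurement used to convert an assembled tract back to a copy number.
    """
    u = len(unit)
    if matching_rotation(seq[start : start + u], unit) is None:
        return 0
    return periodic_run_length(seq, start, u)
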