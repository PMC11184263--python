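"""Assembly and annotation summary statistics.

N50 is the length of the sequence at which the cumulative length of the
descending-sorted sequences first reaches half the assembly total. GC
percent excludes N from the denominator (standard practice for gapped
assemblies). Completeness percentages and sequencing throughput reproduce
the reporting arithmetic of genome-paper summary tables; rounding is
half-up so printed values are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .io import Assembly


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AssemblyStats:
    total_bp: int
    n_sequences: int
    n50_bp: int
    gc_percent: float
    bp_in_sequences_ge_25kb: int
    n_gap_bp: int


def n50(lengths: list[int]) -> int:
    """Smallest length L (of a member sequence) such that sequences >= L
    cover at least half the total."""
    if not lengths:
        raise ValueError("n50 of an empty assembly is undefined")
    total = sum(lengths)
    cum = 0
    for length in sorted(lengths, reverse=True):
        cum += length
        if 2 * cum >= total:
            return length
    raise AssertionError("unreachable")


def compute_stats(asm: Assembly) -> AssemblyStats:
    if len(asm) == 0:
        raise ValueError("cannot compute statistics of an empty assembly")
    lengths = [len(r) for r in asm]
    gc = at = gap = 0
    for rec in asm:
        s = rec.residues
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
        gap += s.count("N")
    denom = gc + at
    gc_percent = _round_half_up(100.0 * gc / denom, 2) if denom else 0.0
    return AssemblyStats(
        total_bp=sum(lengths),
        n_sequences=len(lengths),
        n50_bp=n50(lengths),
        gc_percent=gc_percent,
        bp_in_sequences_ge_25kb=sum(x for x in lengths if x >= 25000),
        n_gap_bp=gap,
    )


def completeness_percent(n_found: int, n_total: int) -> float:
    """100*n_found/n_total, half-up to 2 decimals (BUSCO/CEGMA style)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_found <= n_total:
        raise ValueError("need 0 <= n_found <= n_total")
    return _round_half_up(100.0 * n_found / n_total, 2)


def gigabases(read_pairs: int, read_length: int, paired: bool = True) -> float:
    """Total sequenced gigabases from a read(-pair) count, half-up to one
    decimal."""
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    factor = 2 if paired else 1
    return _round_half_up(read_pairs * read_length * factor / 1e9, 1)
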