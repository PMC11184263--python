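"""Hybrid-scaffolding preparation.

Artificial mate-pair libraries are extracted from a donor assembly to carry
its contiguity into a scaffolder (SSPACE-style): a fixed-length fragment is
tiled along each donor sequence and the two fragment ends become a read
pair. Scaffolds are broken at large N-gaps (runs strictly longer than the
policy's ``max_gap``) and short pieces are length-filtered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .io import Assembly, SequenceRecord

# insert-size presets, by donor assembly type
SHORT_READ_INSERTS = (2000, 5000, 10000, 15000)
LONG_READ_INSERTS = (2000, 5000, 10000, 20000, 50000, 75000, 100000)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MatePairConfig:
    """Parameters of an in-silico mate-pair library run."""

    insert_sizes: tuple[int, ...] = SHORT_READ_INSERTS
    read_length: int = 100
    step: int = 500
    orientation: str = "FR"
    max_n_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.orientation not in {"FR", "RF"}:
            raise ValueError("orientation must be FR or RF")
        if not 0.0 <= self.max_n_fraction <= 1.0:
            raise ValueError("max_n_fraction must lie in [0,1]")
        for ins in self.insert_sizes:
            if ins < 2 * self.read_length:
                raise ValueError(
                    f"insert size {ins} < 2 x read_length "
                    f"{self.read_length}"
                )


@dataclass
class MatePair:
    pair_id: str
    read1: str
    read2: str
    donor_id: str
    donor_start: int  # 1-based start of the fragment on the donor
    insert_size: int


@dataclass
class GapBreakPolicy:
    """Break scaffolds at N-runs strictly longer than ``max_gap`` and drop
    resulting pieces shorter than ``min_piece_length``."""

    max_gap: int = 5000
    min_piece_length: int = 200

    def __post_init__(self) -> None:
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")


@dataclass
class BreakReport:
    n_input: int = 0
    n_split: int = 0
    n_pieces: int = 0
    n_dropped_short: int = 0
    removed_gaps: list[tuple[str, int, int]] = field(default_factory=list)
    dropped_pieces: list[tuple[str, str]] = field(default_factory=list)


def make_mate_pairs(donor: Assembly, cfg: MatePairConfig
                    ) -> dict[int, list[MatePair]]:
    """Tile fragments along each donor sequence and emit end-read pairs.

    For each insert size, fragments start at 1, 1+step, 1+2*step, ... while
    they fit; read1 is the first ``read_length`` bases of the fragment and
    read2 the last. Under FR orientation read2 is reverse-complemented;
    under RF read1 is. Pairs where either read exceeds ``max_n_fraction``
    N content are dropped (the per-library drop count is retained on the
    returned lists as ``.n_dropped`` via :func:`make_mate_pairs_with_report`).
    """
    libs, _ = make_mate_pairs_with_report(donor, cfg)
    return libs


def make_mate_pairs_with_report(donor: Assembly, cfg: MatePairConfig
                                ) -> tuple[dict[int, list[MatePair]],
                                           dict[int, int]]:
    libs: dict[int, list[MatePair]] = {ins: [] for ins in cfg.insert_sizes}
    dropped: dict[int, int] = {ins: 0 for ins in cfg.insert_sizes}
    max_n = cfg.max_n_fraction * cfg.read_length
    for rec in donor:
        seq = rec.residues
        length = len(seq)
        for ins in cfg.insert_sizes:
            if length < ins:
                continue
            start = 1
            while start + ins - 1 <= length:
                frag = seq[start - 1:start - 1 + ins]
                r1 = frag[:cfg.read_length]
                r2 = frag[-cfg.read_length:]
                if cfg.orientation == "FR":
                    r2 = revcomp(r2)
                else:
                    r1 = revcomp(r1)
                if r1.count("N") > max_n or r2.count("N") > max_n:
                    dropped[ins] += 1
                else:
                    base = f"{rec.id}|{start}|{ins}"
                    libs[ins].append(MatePair(
                        pair_id=base, read1=r1, read2=r2,
                        donor_id=rec.id, donor_start=start, insert_size=ins,
                    ))
                start += cfg.step
    return libs, dropped


_GAP_RE = re.compile(r"N+")


def break_at_gaps(asm: Assembly, policy: GapBreakPolicy | None = None
                  ) -> tuple[Assembly, BreakReport]:
    """Split scaffolds at N-runs strictly longer than ``policy.max_gap``.

    Pieces are renamed ``<orig>.<k>`` left to right when a scaffold is
    split; pieces shorter than ``min_piece_length`` are dropped and counted.
    N-runs of length <= max_gap stay untouched inside their piece.
    """
    policy = policy or GapBreakPolicy()
    report = BreakReport(n_input=len(asm))
    out: list[SequenceRecord] = []
    for rec in asm:
        seq = rec.residues
        big_gaps = [m for m in _GAP_RE.finditer(seq)
                    if m.end() - m.start() > policy.max_gap]
        if not big_gaps:
            pieces = [seq]
        else:
            report.n_split += 1
            pieces = []
            pos = 0
            for m in big_gaps:
                pieces.append(seq[pos:m.start()])
                report.removed_gaps.append((rec.id, m.start() + 1, m.end()))
                pos = m.end()
            pieces.append(seq[pos:])
        kept = []
        for piece in pieces:
            if not piece:
                continue
            if len(piece) < policy.min_piece_length:
                report.n_dropped_short += 1
                report.dropped_pieces.append((rec.id, piece))
                continue
            kept.append(piece)
        if len(big_gaps) == 0 and kept:
            out.append(rec)
            report.n_pieces += 1
        else:
            # number pieces left-to-right among the kept ones
            for k, piece in enumerate(kept, start=1):
                out.append(SequenceRecord(
                    id=f"{rec.id}.{k}", residues=piece, mode="nucleotide"))
                report.n_pieces += 1
    return Assembly(records=out, name=asm.name), report


def filter_min_length(asm: Assembly, min_len: int) -> Assembly:
    """Keep sequences with length >= ``min_len`` (order preserved)."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return Assembly(records=[r for r in asm if len(r) >= min_len],
                    name=asm.name)


def write_mate_pair_libraries(libs: dict[int, list[MatePair]],
                              out_dir: str | Path,
                              orientation: str = "FR",
                              error_fraction: float = 0.25) -> Path:
    """Write per-insert two-file FASTA libraries plus an SSPACE-style
    library manifest (`lib<insert> <f1> <f2> <insert> <error> <orient>`)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "libraries.txt"
    with open(manifest, "w") as mf:
        for ins in sorted(libs):
            f1 = out_dir / f"lib{ins}_1.fasta"
            f2 = out_dir / f"lib{ins}_2.fasta"
            with open(f1, "w") as h1, open(f2, "w") as h2:
                for mp in libs[ins]:
                    h1.write(f">{mp.pair_id}/1\n{mp.read1}\n")
                    h2.write(f">{mp.pair_id}/2\n{mp.read2}\n")
            mf.write(f"lib{ins} {f1.name} {f2.name} {ins} "
                     f"{error_fraction} {orientation}\n")
    return manifest
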