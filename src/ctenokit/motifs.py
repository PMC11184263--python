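"""Chitinase genome scanning and reciprocal-best-hit classification.

True chitinases carry the chitin-degrading catalytic signature
FDG(X)DXDXE; chitinase-like proteins share the Glyco_hydro_18 domain but
lack the active site. The signature is scanned as a peptide pattern over
the proteome or over all six reading frames of a whole genome (no intron
splicing: a motif interrupted by an intron is missed), and candidate
proteins are classified by combining reciprocal best hits against the two
human true-chitinase queries, the domain-table evidence and the motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .io import Assembly, DomainHit, HitTable, SequenceRecord
from .rescue import translate_codons
from .scaffold import revcomp

FRAMES = (1, 2, 3, -1, -2, -3)

GLYCO_HYDRO_18 = "Glyco_hydro_18"


@dataclass(frozen=True)
class MotifPattern:
    """Ordered motif over elements: a literal residue, ``*`` -> any
    non-stop, ``?`` -> optional any non-stop."""

    elements: tuple[str, ...]
    strict_x: bool = False  # make X fail the non-stop classes too

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("motif needs at least one element")
        for el in self.elements:
            if el not in {"*", "?"} and not re.fullmatch(r"[A-Z]", el):
                raise ValueError(f"bad motif element {el!r}")

    def to_regex(self) -> re.Pattern[str]:
        cls = "[^*X]" if self.strict_x else "[^*]"
        parts = []
        for el in self.elements:
            if el == "*":
                parts.append(cls)
            elif el == "?":
                parts.append(cls + "?")
            else:
                parts.append(re.escape(el))
        return re.compile("".join(parts))


#: the canonical chitin-degrading catalytic site FDG(X)DXDXE
CHITINASE_MOTIF = MotifPattern(
    elements=("F", "D", "G", "?", "D", "*", "D", "*", "E"))


@dataclass(frozen=True)
class MotifHit:
    source_id: str
    level: str  # "protein" or "genome"
    matched_peptide: str
    aa_start: int  # 1-based within the (frame) translation
    frame: int | None = None
    genomic_start: int | None = None  # 1-based forward strand, inclusive
    genomic_end: int | None = None


def six_frame_translate(seq: SequenceRecord | str) -> dict[int, str]:
    """Translate all six frames (standard code; stops ``*``, ambiguous
    codons ``X``; trailing 1-2 nt dropped)."""
    s = seq.residues if isinstance(seq, SequenceRecord) else seq.upper()
    if len(s) < 3:
        raise ValueError("sequence shorter than one codon")
    rc = revcomp(s)
    return {
        1: translate_codons(s),
        2: translate_codons(s[1:]),
        3: translate_codons(s[2:]),
        -1: translate_codons(rc),
        -2: translate_codons(rc[1:]),
        -3: translate_codons(rc[2:]),
    }


def scan_peptide(source_id: str, peptide: str,
                 pattern: MotifPattern = CHITINASE_MOTIF) -> list[MotifHit]:
    """Leftmost non-overlapping matches of the motif in one peptide."""
    rx = pattern.to_regex()
    return [
        MotifHit(source_id=source_id, level="protein",
                 matched_peptide=m.group(0), aa_start=m.start() + 1)
        for m in rx.finditer(peptide)
    ]


def scan_genome(genome: Assembly,
                pattern: MotifPattern = CHITINASE_MOTIF) -> list[MotifHit]:
    """Scan all six frame translations of every sequence; hits carry
    1-based inclusive forward-strand genomic coordinates."""
    rx = pattern.to_regex()
    hits: list[MotifHit] = []
    for rec in genome:
        length = len(rec)
        translations = six_frame_translate(rec)
        for frame in FRAMES:
            offset = abs(frame) - 1
            for m in rx.finditer(translations[frame]):
                aa_start = m.start() + 1
                span_nt = 3 * len(m.group(0))
                strand_start = offset + 3 * m.start() + 1
                strand_end = strand_start + span_nt - 1
                if frame > 0:
                    g_start, g_end = strand_start, strand_end
                else:
                    g_start = length - strand_end + 1
                    g_end = length - strand_start + 1
                hits.append(MotifHit(
                    source_id=rec.id, level="genome",
                    matched_peptide=m.group(0), aa_start=aa_start,
                    frame=frame, genomic_start=g_start, genomic_end=g_end,
                ))
    return hits


def scan_motif(target: Assembly | SequenceRecord | str,
               pattern: MotifPattern = CHITINASE_MOTIF,
               source_id: str = "peptide") -> list[MotifHit]:
    """Scan a peptide (string / peptide record) or a nucleotide assembly."""
    if isinstance(target, Assembly):
        return scan_genome(target, pattern)
    if isinstance(target, SequenceRecord):
        if target.mode == "peptide":
            return scan_peptide(target.id, target.residues, pattern)
        return scan_genome(Assembly(records=[target]), pattern)
    return scan_peptide(source_id, target, pattern)


def best_hits(table: HitTable) -> tuple[dict[str, str], list[str]]:
    """Best subject per query by bitscore (ties: smaller E-value, then
    lexicographic subject id). Returns (best map, queries that had ties)."""
    best: dict[str, "tuple[float, float, str]"] = {}
    tied: set[str] = set()
    for h in table:
        key = (-h.bitscore, h.evalue, h.subject_id)
        cur = best.get(h.query_id)
        if cur is None or key < cur:
            best[h.query_id] = key
    # second pass: log queries whose top bitscore needed a tie-break
    for h in table:
        win = best[h.query_id]
        if -h.bitscore == win[0] and h.subject_id != win[2]:
            tied.add(h.query_id)
    return {q: k[2] for q, k in best.items()}, sorted(tied)


def reciprocal_best_hits(ab: HitTable, ba: HitTable
                         ) -> set[tuple[str, str]]:
    """(a, b) pairs where b is a's best hit and a is b's best hit."""
    best_ab, _ = best_hits(ab)
    best_ba, _ = best_hits(ba)
    return {(a, b) for a, b in best_ab.items() if best_ba.get(b) == a}


@dataclass
class ChitinaseCall:
    protein_id: str
    classification: str  # chitinase | chitinase_like | neither
    rbh_to: str | None = None
    has_domain: bool = False
    has_catalytic_motif: bool = False
    domain_hits: list[DomainHit] = field(default_factory=list)


def classify_chitinases(proteins: Assembly,
                        rbh_pairs: set[tuple[str, str]],
                        domains: list[DomainHit],
                        true_chitinase_queries: set[str] | None = None,
                        domain_evalue: float = 0.05,
                        pattern: MotifPattern = CHITINASE_MOTIF,
                        domain_name: str = GLYCO_HYDRO_18
                        ) -> list[ChitinaseCall]:
    """Classify each protein as chitinase / chitinase-like / neither.

    chitinase: reciprocal best hit to a true-chitinase query AND the
    catalytic motif present. chitinase_like: significant Glyco_hydro_18
    domain (independent E-value strictly < ``domain_evalue``) AND no motif.
    """
    rbh_of: dict[str, str] = {}
    for prot, query in rbh_pairs:
        if true_chitinase_queries is None or query in true_chitinase_queries:
            rbh_of[prot] = query
    dom_by_prot: dict[str, list[DomainHit]] = {}
    for d in domains:
        if d.domain_name == domain_name and \
                d.independent_evalue < domain_evalue:
            dom_by_prot.setdefault(d.protein_id, []).append(d)
    calls = []
    for rec in proteins:
        has_motif = bool(scan_peptide(rec.id, rec.residues, pattern))
        doms = dom_by_prot.get(rec.id, [])
        rbh_to = rbh_of.get(rec.id)
        if rbh_to is not None and has_motif:
            cls = "chitinase"
        elif doms and not has_motif:
            cls = "chitinase_like"
        else:
            cls = "neither"
        calls.append(ChitinaseCall(
            protein_id=rec.id, classification=cls, rbh_to=rbh_to,
            has_domain=bool(doms), has_catalytic_motif=has_motif,
            domain_hits=doms,
        ))
    return calls


def write_motif_hits_bed(hits: list[MotifHit], path: str) -> None:
    """BED-like export (half-open, 0-based start — the only half-open
    coordinates in the package, flagged in the header)."""
    with open(path, "w") as fh:
        fh.write("# columns: seq, start (0-based half-open), end, frame, "
                 "peptide\n")
        for h in hits:
            start0 = (h.genomic_start or h.aa_start) - 1
            end = h.genomic_end if h.genomic_end is not None \
                else h.aa_start - 1 + len(h.matched_peptide)
            fh.write(f"{h.source_id}\t{start0}\t{end}\t"
                     f"{h.frame if h.frame is not None else '.'}\t"
                     f"{h.matched_peptide}\n")
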