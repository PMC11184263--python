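"""Domain types and readers/writers for the file formats the pipeline touches.

Sequences are held as plain uppercase strings with a declared alphabet
(nucleotide ``ACGTN`` or peptide: the 20 amino acids plus ``*`` and ``X``).
Coordinates are 1-based inclusive everywhere in memory and in GFF3; the only
half-open convention in the package is the BED-like motif-hit export, which
flags it in its header.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PEPTIDE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")

_ALPHABETS = {"nucleotide": NUCLEOTIDE_ALPHABET, "peptide": PEPTIDE_ALPHABET}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class SequenceRecord:
    """A named sequence with an alphabet constraint.

    ``mode`` is ``"nucleotide"`` or ``"peptide"``; residues are stored
    uppercase and validated against the corresponding alphabet.
    """

    id: str
    residues: str
    description: str = ""
    mode: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")
        self.residues = self.residues.upper()
        alphabet = _ALPHABETS[self.mode]
        bad = sorted(set(self.residues) - alphabet)
        if bad:
            raise FormatError(
                f"sequence record {self.id!r} contains characters outside the "
                f"{self.mode} alphabet: {''.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Assembly:
    """Ordered collection of sequence records with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FormatError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)

    def __contains__(self, seq_id: str) -> bool:
        return any(rec.id == seq_id for rec in self.records)

    @property
    def total_length(self) -> int:
        return sum(len(rec) for rec in self.records)

    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]


@dataclass
class GeneLocus:
    """A gene with 1-based inclusive genomic coordinates."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    transcript_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id!r}: strand must be + or -")
        if not self.transcript_ids:
            self.transcript_ids = [self.gene_id + ".t1"]

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class HitRecord:
    """One directed pairwise alignment hit (BLAST outfmt-6 row)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise FormatError("hit with empty query or subject id")
        if self.evalue < 0:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: negative E-value"
            )


class HitTable:
    """Ordered collection of :class:`HitRecord` with per-query grouping."""

    def __init__(self, hits: Iterable[HitRecord] = ()) -> None:
        self.hits: list[HitRecord] = list(hits)

    def __iter__(self) -> Iterator[HitRecord]:
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)

    def by_query(self) -> dict[str, list[HitRecord]]:
        out: dict[str, list[HitRecord]] = {}
        for hit in self.hits:
            out.setdefault(hit.query_id, []).append(hit)
        return out


@dataclass(frozen=True)
class DomainHit:
    """One hmmscan domain hit against a protein."""

    protein_id: str
    domain_name: str
    domain_accession: str
    independent_evalue: float
    ali_start: int
    ali_end: int

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise FormatError(
                f"domain hit {self.domain_name} on {self.protein_id}: "
                "ali_start > ali_end"
            )
        if self.independent_evalue < 0:
            raise FormatError("negative independent E-value")


# OrthogroupTable: orthogroup id -> column/species name -> list of member ids
OrthogroupTable = dict[str, dict[str, list[str]]]


def read_fasta(path: str | Path, mode: str = "nucleotide") -> Assembly:
    """Read a FASTA file into an :class:`Assembly`.

    Residues are uppercased; record order is preserved. Duplicate ids, empty
    sequences and alphabet violations are hard errors.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc,
                           mode=mode)
        )
    return Assembly(records=records, name=Path(path).stem)


def write_fasta(asm: Assembly | Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in asm:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_tabular_hits(path: str | Path) -> HitTable:
    """Read a 12-column tab-separated hit file (BLAST outfmt-6 dialect).

    Extra columns beyond 12 are ignored; row order is preserved; a
    non-numeric E-value or bitscore is an error reporting the line number.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=12 tab-separated "
                    f"columns, got {len(cols)}"
                )
            try:
                hits.append(HitRecord(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                ))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return HitTable(hits)


def write_tabular_hits(table: HitTable, path: str | Path) -> None:
    """Write hits as 12-column outfmt-6 rows (unused coordinates zeroed)."""
    with open(path, "w") as fh:
        for h in table:
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, h.percent_identity,
                h.alignment_length, 0, 0, 0, 0, 0, 0,
                f"{h.evalue:g}", f"{h.bitscore:g}",
            ])) + "\n")


def read_orthogroups(path: str | Path,
                     species_columns: Iterable[str] | None = None
                     ) -> OrthogroupTable:
    """Read an OrthoFinder ``Orthogroups.tsv``-dialect table.

    First column is the orthogroup id; remaining columns are species, with
    comma-separated member ids. Empty cells become empty lists, never missing
    keys. ``species_columns`` restricts (and validates) the columns kept.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or len(header) < 2:
            raise FormatError(f"{path}: missing orthogroup header row")
        all_species = header[1:]
        if species_columns is None:
            keep = list(all_species)
        else:
            keep = list(species_columns)
            missing = [s for s in keep if s not in all_species]
            if missing:
                raise FormatError(
                    f"{path}: species column(s) {missing} not in header "
                    f"{all_species}"
                )
        idx = {s: all_species.index(s) for s in keep}
        table: OrthogroupTable = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            og = cols[0]
            if og in table:
                raise FormatError(f"{path}: line {lineno}: duplicate "
                                  f"orthogroup id {og!r}")
            row: dict[str, list[str]] = {}
            for sp, i in idx.items():
                cell = cols[1 + i] if 1 + i < len(cols) else ""
                row[sp] = [m.strip() for m in cell.split(",") if m.strip()]
            table[og] = row
    return table


def write_orthogroups(table: OrthogroupTable, path: str | Path,
                      species_columns: Iterable[str] | None = None) -> None:
    """Write an :data:`OrthogroupTable` in the Orthogroups.tsv dialect."""
    if species_columns is None:
        species: list[str] = []
        for row in table.values():
            for sp in row:
                if sp not in species:
                    species.append(sp)
    else:
        species = list(species_columns)
    with open(path, "w") as fh:
        fh.write("\t".join(["Orthogroup"] + species) + "\n")
        for og, row in table.items():
            cells = [", ".join(row.get(sp, [])) for sp in species]
            fh.write("\t".join([og] + cells) + "\n")


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Read hmmscan ``--domtblout`` output (whitespace-delimited, ``#`` =
    comment). Column layout: target (domain) name/accession first, then the
    query protein; the independent (i-Evalue) column and alignment
    coordinates are taken per the hmmscan manual."""
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 23:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=23 whitespace "
                    f"columns, got {len(cols)}"
                )
            try:
                hits.append(DomainHit(
                    protein_id=cols[3],
                    domain_name=cols[0],
                    domain_accession=cols[1],
                    independent_evalue=float(cols[12]),
                    ali_start=int(cols[17]),
                    ali_end=int(cols[18]),
                ))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return hits


_GFF_ATTR_RE = re.compile(r"([^;=]+)=([^;]*)")


def _parse_attrs(field9: str) -> dict[str, str]:
    return {k.strip(): v for k, v in _GFF_ATTR_RE.findall(field9)}


def read_gff3_genes(path: str | Path) -> list[GeneLocus]:
    """Read gene features (with their mRNA children) from a GFF3 file."""
    genes: dict[str, GeneLocus] = {}
    transcripts: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 "
                                  f"columns, got {len(cols)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            a = _parse_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if not gid:
                    raise FormatError(f"{path}: line {lineno}: gene without ID")
                genes[gid] = GeneLocus(
                    gene_id=gid, scaffold_id=seqid,
                    start=int(start), end=int(end), strand=strand,
                    transcript_ids=["__pending__"],
                )
                transcripts[gid] = []
            elif ftype == "mRNA":
                parent = a.get("Parent", "")
                tid = a.get("ID", "")
                if parent in transcripts and tid:
                    transcripts[parent].append(tid)
    out = []
    for gid, locus in genes.items():
        locus.transcript_ids = transcripts[gid] or [gid + ".t1"]
        out.append(locus)
    return out


def write_gff3_genes(genes: Iterable[GeneLocus], path: str | Path,
                     source: str = "ctenokit") -> None:
    """Write gene + mRNA features to GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([
                g.scaffold_id, source, "gene", str(g.start), str(g.end),
                ".", g.strand, ".", f"ID={g.gene_id}",
            ]) + "\n")
            for tid in g.transcript_ids:
                fh.write("\t".join([
                    g.scaffold_id, source, "mRNA", str(g.start), str(g.end),
                    ".", g.strand, ".", f"ID={tid};Parent={g.gene_id}",
                ]) + "\n")


def read_de_table(path: str | Path) -> "tuple[dict[str, tuple[float, float]], Mapping[str, str]]":
    """Read a DE table: optional ``# key=value`` metadata header lines, then
    a ``gene_id<TAB>log2fc<TAB>fdr`` header and rows.

    Returns (mapping gene -> (log2fc, fdr) keeping the minimum-FDR row per
    gene, metadata dict).
    """
    meta: dict[str, str] = {}
    rows: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for k, v in re.findall(r"(\w+)=([^\s;]+)", line):
                    meta[k] = v
                continue
            cols = line.split("\t")
            if cols[0] in {"gene_id", "gene"}:
                continue
            if len(cols) < 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 columns")
            try:
                gene, lfc, fdr = cols[0], float(cols[1]), float(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if not 0.0 <= fdr <= 1.0:
                raise FormatError(f"{path}: line {lineno}: FDR outside [0,1]")
            if gene not in rows or fdr < rows[gene][1]:
                rows[gene] = (lfc, fdr)
    return rows, meta
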