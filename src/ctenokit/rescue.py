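"""Missed-gene rescue.

Gene predictors miss real loci; when an orthogroup contains transcripts of
the focal species plus protein models of outgroup species but no focal
protein model, that orthogroup evidences an unannotated gene. The pipeline
confirms novelty (no significant alignment of the transcripts to existing
gene models), extracts the single longest open reading frame per candidate,
and keeps candidates whose coding region aligns to exactly one genomic
scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .io import (Assembly, HitTable, OrthogroupTable, SequenceRecord,
                 write_fasta)
from .scaffold import revcomp

REJECT_REASONS = {"has_model_hit", "no_orf", "multi_scaffold", "no_alignment"}

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> dict[str, str]:
    # standard genetic code, built from Biopython's table once
    from Bio.Data.CodonTable import standard_dna_table
    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


def translate_codons(seq: str) -> str:
    """Translate a nucleotide string codon-by-codon; any codon containing a
    character outside ACGT (e.g. N) becomes X; trailing 1-2 nt dropped."""
    if not _CODON_TABLE:
        _CODON_TABLE.update(_build_codon_table())
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        out.append(_CODON_TABLE.get(seq[i:i + 3], "X"))
    return "".join(out)


@dataclass
class OrfModel:
    """The single longest ORF of a transcript.

    ``nt_start``/``nt_end`` are 1-based on the translated strand (the
    reverse complement for negative frames); the peptide excludes the stop.
    """

    transcript_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    nt_start: int
    nt_end: int
    peptide: str
    has_start_codon: bool

    def __post_init__(self) -> None:
        if "*" in self.peptide:
            raise ValueError("ORF peptide contains an internal stop")
        if len(self.peptide) * 3 != self.nt_end - self.nt_start + 1:
            raise ValueError("ORF span does not match peptide length")


@dataclass
class RescueCandidate:
    orthogroup_id: str
    transcript_ids: list[str]
    supporting_species: list[str]
    status: str = "candidate"
    orf: OrfModel | None = None
    scaffold: str | None = None
    alternate_orfs: list[OrfModel] = field(default_factory=list)

    @property
    def rejected(self) -> bool:
        return self.status.startswith("rejected:")


def find_candidates(ogs: OrthogroupTable, focal_model_col: str,
                    focal_transcript_col: str,
                    outgroup_cols: list[str]) -> list[RescueCandidate]:
    """Orthogroups with no focal protein model, at least one focal
    transcript and at least one outgroup member are rescue candidates."""
    needed = [focal_model_col, focal_transcript_col] + list(outgroup_cols)
    out: list[RescueCandidate] = []
    for og_id, row in ogs.items():
        missing = [c for c in needed if c not in row]
        if missing:
            raise KeyError(f"orthogroup table lacks column(s) {missing}")
        if row[focal_model_col]:
            continue
        if not row[focal_transcript_col]:
            continue
        support = [c for c in outgroup_cols if row[c]]
        if not support:
            continue
        out.append(RescueCandidate(
            orthogroup_id=og_id,
            transcript_ids=list(row[focal_transcript_col]),
            supporting_species=support,
        ))
    return out


def confirm_novel(cands: list[RescueCandidate], hits: HitTable,
                  evalue_cutoff: float = 1e-6) -> list[RescueCandidate]:
    """Reject candidates any of whose transcripts aligns to an existing gene
    model with E-value strictly below the cutoff."""
    by_query = hits.by_query()
    for cand in cands:
        if cand.status != "candidate":
            continue
        significant = any(
            h.evalue < evalue_cutoff
            for t in cand.transcript_ids
            for h in by_query.get(t, ())
        )
        cand.status = "rejected:has_model_hit" if significant else "confirmed"
    return cands


def longest_orf(transcript: SequenceRecord, allow_partial: bool = True,
                min_codons: int = 30) -> OrfModel | None:
    """Single longest ORF over all six reading frames.

    An ORF is a maximal stop-free codon run ending at a stop codon or at
    the end of the frame. With ``allow_partial`` the run that begins at the
    frame start may lack ATG (flagged ``has_start_codon=False``); every
    other run is trimmed to start at its first ATG. Ties break by frame
    order +1,+2,+3,-1,-2,-3 then smaller start position. Returns ``None``
    when no ORF reaches ``min_codons``.
    """
    seq = transcript.residues
    frames = [(+1, seq, 0), (+2, seq, 1), (+3, seq, 2)]
    rc = revcomp(seq)
    frames += [(-1, rc, 0), (-2, rc, 1), (-3, rc, 2)]
    best: OrfModel | None = None
    for frame, strand_seq, offset in frames:
        pep = translate_codons(strand_seq[offset:])
        run_start = 0  # codon index where the current stop-free run began
        n = len(pep)
        while run_start < n:
            stop = pep.find("*", run_start)
            run_end = n if stop == -1 else stop  # run = [run_start, run_end)
            candidates = []
            run = pep[run_start:run_end]
            if run:
                if allow_partial and run_start == 0:
                    candidates.append((run_start, run))
                elif run.startswith("M"):
                    candidates.append((run_start, run))
                if not candidates:
                    m = run.find("M")
                    if m != -1:
                        candidates.append((run_start + m, run[m:]))
            for codon_start, orf_pep in candidates:
                if len(orf_pep) < min_codons:
                    continue
                nt_start = offset + 3 * codon_start + 1
                model = OrfModel(
                    transcript_id=transcript.id, frame=frame,
                    nt_start=nt_start,
                    nt_end=nt_start + 3 * len(orf_pep) - 1,
                    peptide=orf_pep,
                    has_start_codon=orf_pep.startswith("M"),
                )
                if best is None or len(model.peptide) > len(best.peptide):
                    best = model
            if stop == -1:
                break
            run_start = run_end + 1
    return best


def extract_orfs(cands: list[RescueCandidate], transcripts: Assembly,
                 allow_partial: bool = True, min_codons: int = 30
                 ) -> list[RescueCandidate]:
    """For each confirmed candidate, keep the longest ORF over all its
    transcripts (alternates recorded), or reject with ``no_orf``."""
    for cand in cands:
        if cand.status != "confirmed":
            continue
        models = []
        for tid in cand.transcript_ids:
            if tid not in transcripts:
                continue
            orf = longest_orf(transcripts[tid], allow_partial=allow_partial,
                              min_codons=min_codons)
            if orf is not None:
                models.append(orf)
        if not models:
            cand.status = "rejected:no_orf"
            continue
        models.sort(key=lambda m: -len(m.peptide))
        cand.orf = models[0]
        cand.alternate_orfs = models[1:]
        cand.status = "orf_extracted"
    return cands


def place_on_genome(cands: list[RescueCandidate], genome_hits: HitTable
                    ) -> list[RescueCandidate]:
    """Keep candidates whose coding region aligns to exactly one scaffold."""
    by_query = genome_hits.by_query()
    for cand in cands:
        if cand.status != "orf_extracted" or cand.orf is None:
            continue
        hits = by_query.get(cand.orf.transcript_id, [])
        scaffolds = {h.subject_id for h in hits}
        if not scaffolds:
            cand.status = "rejected:no_alignment"
        elif len(scaffolds) > 1:
            cand.status = "rejected:multi_scaffold"
        else:
            cand.scaffold = scaffolds.pop()
            cand.status = "placed"
    return cands


def emit_rescued_models(cands: list[RescueCandidate],
                        transcripts: Assembly,
                        gff_path: str | Path,
                        pep_path: str | Path) -> int:
    """Write gene/mRNA/CDS features (transcript coordinates) and peptides
    for placed candidates; ids are namespaced ``rescue.<orthogroup>``.

    CDS coordinates are on the forward transcript; for negative-frame ORFs
    the strand is ``-``. ORFs without a start codon carry a
    ``partial=5prime`` attribute. Returns the number of models written.
    """
    n = 0
    peptides = []
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cand in cands:
            if cand.status != "placed" or cand.orf is None:
                continue
            orf = cand.orf
            tlen = len(transcripts[orf.transcript_id])
            if orf.frame > 0:
                start, end, strand = orf.nt_start, orf.nt_end, "+"
            else:
                start = tlen - orf.nt_end + 1
                end = tlen - orf.nt_start + 1
                strand = "-"
            gid = f"rescue.{cand.orthogroup_id}"
            attrs_extra = "" if orf.has_start_codon else ";partial=5prime"
            rows = [
                (orf.transcript_id, "gene", start, end, strand,
                 f"ID={gid};scaffold={cand.scaffold}"),
                (orf.transcript_id, "mRNA", start, end, strand,
                 f"ID={gid}.mRNA;Parent={gid}"),
                (orf.transcript_id, "CDS", start, end, strand,
                 f"ID={gid}.cds;Parent={gid}.mRNA;frame={orf.frame:+d}"
                 f"{attrs_extra}"),
            ]
            for seqid, ftype, s, e, st, attrs in rows:
                fh.write("\t".join([seqid, "ctenokit", ftype, str(s), str(e),
                                    ".", st, "0" if ftype == "CDS" else ".",
                                    attrs]) + "\n")
            peptides.append(SequenceRecord(id=gid, residues=orf.peptide,
                                           mode="peptide"))
            n += 1
    write_fasta(peptides, pep_path)
    return n


def status_counts(cands: list[RescueCandidate]) -> dict[str, int]:
    out: dict[str, int] = {}
    for cand in cands:
        out[cand.status] = out.get(cand.status, 0) + 1
    return out
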