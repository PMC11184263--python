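"""Missed-gene rescue: candidate logic, ORF extraction, placement."""

import numpy as np
import pytest
from Bio.Seq import Seq

from ctenokit.io import (Assembly, HitRecord, HitTable, SequenceRecord,
                         read_fasta)
from ctenokit.rescue import (confirm_novel, emit_rescued_models,
                             extract_orfs, find_candidates, longest_orf,
                             place_on_genome, status_counts,
                             translate_codons)


def hit(q, s, evalue=1e-50):
    return HitRecord(query_id=q, subject_id=s, percent_identity=95.0,
                     alignment_length=100, evalue=evalue, bitscore=200.0)


class TestFindCandidates:
    def table(self, models, transcripts, out_a, out_b=()):
        return {"OG1": {"M": list(models), "T": list(transcripts),
                        "A": list(out_a), "B": list(out_b)}}

    def test_model_present_blocks(self):
        assert find_candidates(self.table(["g1"], ["t1"], ["x"]),
                               "M", "T", ["A", "B"]) == []

    def test_needs_outgroup_support(self):
        assert find_candidates(self.table([], ["t1"], [], []),
                               "M", "T", ["A", "B"]) == []

    def test_candidate_records_support(self):
        (cand,) = find_candidates(self.table([], ["t1", "t2"], [], ["y"]),
                                  "M", "T", ["A", "B"])
        assert cand.transcript_ids == ["t1", "t2"]
        assert cand.supporting_species == ["B"]

    def test_missing_column_is_error(self):
        with pytest.raises(KeyError):
            find_candidates(self.table([], ["t1"], ["x"]), "M", "T", ["Z"])

    def test_planted_targets_all_found(self, ortho_sim):
        cands = find_candidates(ortho_sim.runs["i1.5"], "Bova_prot",
                                "Bova_tx", ["Ml", "Hc"])
        assert {c.orthogroup_id for c in cands} == \
            set(ortho_sim.manifest["rescue_targets"])


class TestConfirmNovel:
    def make(self, tx="t1"):
        from ctenokit.rescue import RescueCandidate
        return RescueCandidate(orthogroup_id="OG1", transcript_ids=[tx],
                               supporting_species=["A"])

    @pytest.mark.parametrize("evalue,expected", [
        (1e-7, "rejected:has_model_hit"),  # strictly below cutoff
        (1e-6, "confirmed"),               # boundary: not < 1e-6
    ])
    def test_strict_cutoff(self, evalue, expected):
        (cand,) = confirm_novel([self.make()],
                                HitTable([hit("t1", "g1", evalue)]))
        assert cand.status == expected

    def test_absent_transcript_confirmed(self):
        (cand,) = confirm_novel([self.make("t9")],
                                HitTable([hit("t1", "g1")]))
        assert cand.status == "confirmed"


def oracle_longest_orf(seq: str, allow_partial: bool, min_codons: int):
    """Exhaustive 6-frame enumeration using Biopython translation,
    independent of the package's scanner. Returns (peptide, frame,
    nt_start) or None."""
    frames = []
    for frame, s in [(1, seq), (2, seq[1:]), (3, seq[2:])]:
        frames.append((frame, s))
    rc = str(Seq(seq).reverse_complement())
    for frame, s in [(-1, rc), (-2, rc[1:]), (-3, rc[2:])]:
        frames.append((frame, s))
    best = None
    frame_rank = {1: 0, 2: 1, 3: 2, -1: 3, -2: 4, -3: 5}
    for frame, s in frames:
        s = s[:len(s) - len(s) % 3]
        pep = "".join(
            "X" if set(s[i:i + 3]) - set("ACGT")
            else str(Seq(s[i:i + 3]).translate())
            for i in range(0, len(s), 3))
        offset = abs(frame) - 1
        start = 0
        while start <= len(pep):
            stop = pep.find("*", start)
            end = len(pep) if stop == -1 else stop
            run = pep[start:end]
            options = []
            if run:
                if (allow_partial and start == 0) or run.startswith("M"):
                    options.append((start, run))
                elif "M" in run:
                    m = run.index("M")
                    options.append((start + m, run[m:]))
            for cstart, orf in options:
                if len(orf) < min_codons:
                    continue
                key = (-len(orf), frame_rank[frame], offset + 3 * cstart + 1)
                if best is None or key < best[0]:
                    best = (key, orf, frame, offset + 3 * cstart + 1)
            if stop == -1:
                break
            start = end + 1
    if best is None:
        return None
    return best[1], best[2], best[3]


class TestLongestOrf:
    def test_direct_translation(self):
        orf = longest_orf(SequenceRecord(id="t", residues="ATGAAATAA"),
                          allow_partial=False, min_codons=1)
        assert (orf.peptide, orf.frame, orf.has_start_codon) == \
            ("MK", 1, True)
        assert (orf.nt_start, orf.nt_end) == (1, 6)

    def test_revcomp_flips_frame_sign(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = "".join(np.array(list("ACGT"))[
                rng.integers(0, 4, size=600)])
            rc = str(Seq(seq).reverse_complement())
            a = longest_orf(SequenceRecord(id="f", residues=seq))
            b = longest_orf(SequenceRecord(id="r", residues=rc))
            assert (a is None) == (b is None)
            if a is not None:
                assert a.peptide == b.peptide
                assert a.frame == -b.frame

    @pytest.mark.parametrize("allow_partial", [True, False])
    def test_matches_exhaustive_enumeration(self, allow_partial):
        rng = np.random.default_rng(17 if allow_partial else 18)
        for _ in range(150):
            length = int(rng.integers(30, 900))
            seq = "".join(np.array(list("ACGTN"))[
                rng.integers(0, 5, size=length)])
            got = longest_orf(SequenceRecord(id="t", residues=seq),
                              allow_partial=allow_partial, min_codons=10)
            expect = oracle_longest_orf(seq, allow_partial, 10)
            if expect is None:
                assert got is None
            else:
                assert (got.peptide, got.frame, got.nt_start) == expect


class TestPlacement:
    def make_extracted(self, tx="t1"):
        from ctenokit.rescue import OrfModel, RescueCandidate
        cand = RescueCandidate(orthogroup_id="OG1", transcript_ids=[tx],
                               supporting_species=["A"],
                               status="orf_extracted")
        cand.orf = OrfModel(transcript_id=tx, frame=1, nt_start=1,
                            nt_end=90, peptide="M" * 30,
                            has_start_codon=True)
        return cand

    def test_multi_scaffold_rejected(self):
        (cand,) = place_on_genome(
            [self.make_extracted()],
            HitTable([hit("t1", "s1"), hit("t1", "s2")]))
        assert cand.status == "rejected:multi_scaffold"

    def test_multiple_hsps_one_scaffold_placed(self):
        (cand,) = place_on_genome(
            [self.make_extracted()],
            HitTable([hit("t1", "s1"), hit("t1", "s1"), hit("t1", "s1")]))
        assert cand.status == "placed" and cand.scaffold == "s1"

    def test_no_alignment_rejected(self):
        (cand,) = place_on_genome([self.make_extracted()], HitTable([]))
        assert cand.status == "rejected:no_alignment"


class TestPipeline:
    def run_pipeline(self, ortho_sim):
        cands = find_candidates(ortho_sim.runs["i1.5"], "Bova_prot",
                                "Bova_tx", ["Ml", "Hc"])
        cands = confirm_novel(cands, ortho_sim.model_hits)
        cands = extract_orfs(cands, ortho_sim.transcripts)
        return place_on_genome(cands, ortho_sim.genome_hits)

    def test_noise_free_recall_and_precision(self, ortho_sim):
        cands = self.run_pipeline(ortho_sim)
        placed = {c.orthogroup_id for c in cands if c.status == "placed"}
        assert placed == set(ortho_sim.manifest["rescue_targets"])
        for c in cands:
            if c.status == "placed":
                target = ortho_sim.manifest["rescue_targets"][
                    c.orthogroup_id]
                assert c.scaffold == target["scaffold"]

    def test_stage_counts_reconcile(self, ortho_sim):
        cands = self.run_pipeline(ortho_sim)
        counts = status_counts(cands)
        assert sum(counts.values()) == len(cands)
        terminal = {"placed", "rejected:has_model_hit", "rejected:no_orf",
                    "rejected:multi_scaffold", "rejected:no_alignment"}
        assert set(counts) <= terminal

    def test_emitted_cds_translates_back(self, tmp_path, ortho_sim):
        cands = self.run_pipeline(ortho_sim)
        gff = tmp_path / "rescued.gff3"
        pep = tmp_path / "rescued.pep.fasta"
        n = emit_rescued_models(cands, ortho_sim.transcripts, gff, pep)
        assert n == len(ortho_sim.manifest["rescue_targets"])
        peptides = read_fasta(pep, mode="peptide")
        cds_rows = [line.split("\t") for line in gff.read_text().splitlines()
                    if "\tCDS\t" in line]
        assert len(cds_rows) == n
        for row in cds_rows:
            seqid, start, end, strand = row[0], int(row[3]), int(row[4]), \
                row[6]
            sub = ortho_sim.transcripts[seqid].residues[start - 1:end]
            if strand == "-":
                sub = str(Seq(sub).reverse_complement())
            gid = row[8].split("Parent=")[1].split(";")[0].rsplit(
                ".mRNA", 1)[0]
            assert translate_codons(sub) == peptides[gid].residues

    def test_empty_input_writes_valid_header(self, tmp_path, ortho_sim):
        gff = tmp_path / "empty.gff3"
        pep = tmp_path / "empty.pep.fasta"
        assert emit_rescued_models([], ortho_sim.transcripts, gff, pep) == 0
        assert gff.read_text() == "##gff-version 3\n"

    def test_partial_orf_flagged(self, tmp_path):
        from ctenokit.rescue import OrfModel, RescueCandidate
        tx = SequenceRecord(id="tx", residues="AAA" * 40)
        cand = RescueCandidate(orthogroup_id="OGX", transcript_ids=["tx"],
                               supporting_species=["A"], status="placed")
        cand.scaffold = "s1"
        cand.orf = OrfModel(transcript_id="tx", frame=1, nt_start=1,
                            nt_end=90, peptide="K" * 30,
                            has_start_codon=False)
        gff = tmp_path / "p.gff3"
        emit_rescued_models([cand], Assembly(records=[tx]), gff,
                            tmp_path / "p.pep")
        assert "partial=5prime" in gff.read_text()
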