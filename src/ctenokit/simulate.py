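"""Seeded generators for every input the pipeline consumes.

The simulated study system is a pair of ctenophore-like genomes: a focal
species ("Bo") assembled into scaffolds, possibly gapped and carrying
planted translocations, and a partner species ("Ml") with intact
chromosomes that serves both as the synteny reference and as the DE
comparison partner. Orthology ground truth (one-to-one pairs, paralog
families with planted tree cherries, isoform expansions, unannotated
genes), planted catalytic motifs and planted conserved-DE genes are all
recorded in a manifest so every downstream recovery claim is checkable.

All randomness flows through one ``numpy.random.Generator`` per call;
the same seed reproduces every output byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import Assembly, GeneLocus, HitRecord, HitTable, OrthogroupTable, \
    SequenceRecord
from .motifs import MotifPattern
from .scaffold import revcomp

_BASES = np.array(list("ACGT"))

RUN_LABELS = ("i1.5", "i5", "i8", "i10")  # MCL inflation settings emulated

FOCAL_MODEL_COL = "Bova_prot"
FOCAL_TX_COL = "Bova_tx"
PARTNER_COL = "Ml"
OUTGROUP_COL = "Hc"


@dataclass
class SimManifest:
    """Ground truth for one simulation; JSON-serializable."""

    seed: int
    data: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, **self.data}, fh, indent=1,
                      default=list)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass
class TwoSpeciesSim:
    assembly_a: Assembly | None
    assembly_b: Assembly | None
    genes_a: list[GeneLocus]
    genes_b: list[GeneLocus]
    manifest: SimManifest


def simulate_two_species_genomes(seed: int,
                                 n_chromosomes: int = 13,
                                 n_genes: int = 260,
                                 translocation_rate: float = 0.0,
                                 fragmentation: int = 3,
                                 placement_noise_rate: float = 0.0,
                                 gene_length: int = 300,
                                 spacing: int = 200,
                                 plant_gaps: bool = False,
                                 big_gap_length: int = 6000,
                                 build_sequences: bool = True
                                 ) -> TwoSpeciesSim:
    """Simulate a fragmented focal genome and an intact partner genome
    with known linkage.

    Genes are laid out chromosome by chromosome; the focal species splits
    each chromosome's genes over ``fragmentation`` scaffolds. A
    translocated scaffold moves a block of its genes' partner orthologs to
    a different chromosome; ``placement_noise_rate`` instead reassigns
    individual partner genes uniformly. ``plant_gaps`` inserts one N-run
    longer than 5 kb into every third scaffold (recorded in the manifest).
    """
    if n_chromosomes < 1 or n_genes < n_chromosomes or fragmentation < 1:
        raise ValueError("bad simulation parameters")
    rng = np.random.default_rng(seed)
    per_chrom = [n_genes // n_chromosomes] * n_chromosomes
    for i in range(n_genes % n_chromosomes):
        per_chrom[i] += 1

    pairs: list[tuple[str, str]] = []
    gene_chrom_b: dict[str, int] = {}   # partner-side chromosome index
    gene_scaffold: dict[str, str] = {}
    scaffold_chrom: dict[str, int] = {}
    scaffold_genes: dict[str, list[str]] = {}
    g = 0
    scaf_i = 0
    for j in range(n_chromosomes):
        chrom_genes = []
        for _ in range(per_chrom[j]):
            bo, ml = f"Bo_g{g}", f"Ml_g{g}"
            pairs.append((bo, ml))
            gene_chrom_b[ml] = j
            chrom_genes.append(bo)
            g += 1
        n_frag = min(fragmentation, len(chrom_genes))
        blocks = np.array_split(np.array(chrom_genes, dtype=object), n_frag)
        for block in blocks:
            sid = f"Bo_scaf{scaf_i}"
            scaffold_chrom[sid] = j
            scaffold_genes[sid] = list(block)
            for bo in block:
                gene_scaffold[bo] = sid
            scaf_i += 1

    # planted translocations: move a trailing block of a scaffold's partner
    # orthologs to another chromosome
    bo_to_ml = dict(pairs)
    translocations = []
    n_trans = int(round(translocation_rate * len(scaffold_chrom)))
    if n_trans:
        eligible = [s for s, genes in scaffold_genes.items()
                    if len(genes) >= 12]
        chosen = rng.choice(eligible, size=min(n_trans, len(eligible)),
                            replace=False)
        for sid in chosen:
            genes = scaffold_genes[sid]
            n_move = max(5, int(np.ceil(0.25 * len(genes))))
            moved = genes[-n_move:]
            src = scaffold_chrom[sid]
            dst = int(rng.choice([c for c in range(n_chromosomes)
                                  if c != src]))
            for bo in moved:
                gene_chrom_b[bo_to_ml[bo]] = dst
            translocations.append({"scaffold": sid, "from_chrom": src,
                                   "to_chrom": dst, "genes": list(moved)})

    # placement noise: individual partner genes to a uniform chromosome
    noisy_genes = []
    if placement_noise_rate > 0:
        n_noise = int(round(placement_noise_rate * len(pairs)))
        idx = rng.choice(len(pairs), size=n_noise, replace=False)
        for i in idx:
            ml = pairs[i][1]
            gene_chrom_b[ml] = int(rng.integers(0, n_chromosomes))
            noisy_genes.append(ml)

    # partner-side layout: chromosomes in index order, genes in id order
    genes_b: list[GeneLocus] = []
    chrom_lengths_b: dict[str, int] = {}
    by_chrom: dict[int, list[str]] = {}
    for ml, j in gene_chrom_b.items():
        by_chrom.setdefault(j, []).append(ml)
    for j in range(n_chromosomes):
        cid = f"Ml_chr{j}"
        pos = spacing + 1
        for ml in sorted(by_chrom.get(j, []),
                         key=lambda x: int(x.split("g")[1])):
            genes_b.append(GeneLocus(
                gene_id=ml, scaffold_id=cid, start=pos,
                end=pos + gene_length - 1, strand="+",
                transcript_ids=[ml + ".t1"]))
            pos += gene_length + spacing
        chrom_lengths_b[cid] = pos - 1 if pos > spacing + 1 else spacing

    # focal-side layout, with optional planted big gaps
    genes_a: list[GeneLocus] = []
    scaffold_lengths_a: dict[str, int] = {}
    gap_positions: list[tuple[str, int, int]] = []
    seqs_a: list[SequenceRecord] = []
    for sid, genes in scaffold_genes.items():
        pos = spacing + 1
        parts: list[str] = []
        if build_sequences:
            parts.append(_random_seq(rng, spacing))
        gap_after = len(genes) // 2 if (
            plant_gaps and int(sid.replace("Bo_scaf", "")) % 3 == 0
            and len(genes) >= 2) else None
        for k, bo in enumerate(genes):
            genes_a.append(GeneLocus(
                gene_id=bo, scaffold_id=sid, start=pos,
                end=pos + gene_length - 1, strand="+",
                transcript_ids=[bo + ".t1"]))
            if build_sequences:
                parts.append(_random_seq(rng, gene_length))
            pos += gene_length
            if gap_after is not None and k + 1 == gap_after:
                gap_positions.append((sid, pos, pos + big_gap_length - 1))
                if build_sequences:
                    parts.append("N" * big_gap_length)
                pos += big_gap_length
            if build_sequences:
                parts.append(_random_seq(rng, spacing))
            pos += spacing
        scaffold_lengths_a[sid] = pos - 1
        if build_sequences:
            seqs_a.append(SequenceRecord(id=sid, residues="".join(parts)))

    asm_a = Assembly(records=seqs_a, name="Bo") if build_sequences else None
    asm_b = None
    if build_sequences:
        seqs_b = [SequenceRecord(id=cid, residues=_random_seq(rng, length))
                  for cid, length in chrom_lengths_b.items()]
        asm_b = Assembly(records=seqs_b, name="Ml")

    manifest = SimManifest(seed=seed, data={
        "n_chromosomes": n_chromosomes,
        "pairs": pairs,
        "gene_scaffold": gene_scaffold,
        "gene_chrom_b": {ml: j for ml, j in gene_chrom_b.items()},
        "scaffold_chrom": scaffold_chrom,
        "scaffold_lengths_a": scaffold_lengths_a,
        "chrom_lengths_b": chrom_lengths_b,
        "translocations": translocations,
        "noisy_genes": noisy_genes,
        "gap_positions": gap_positions,
    })
    return TwoSpeciesSim(assembly_a=asm_a, assembly_b=asm_b,
                         genes_a=genes_a, genes_b=genes_b,
                         manifest=manifest)


_NON_STOP_CODONS: list[str] = []
_CODONS_FOR_AA: dict[str, list[str]] = {}


def _codon_tables() -> tuple[list[str], dict[str, list[str]]]:
    if not _NON_STOP_CODONS:
        from Bio.Data.CodonTable import standard_dna_table
        for codon, aa in standard_dna_table.forward_table.items():
            if set(codon) <= set("ACGT"):
                _NON_STOP_CODONS.append(codon)
                _CODONS_FOR_AA.setdefault(aa, []).append(codon)
        for aa in _CODONS_FOR_AA.values():
            aa.sort()
        _NON_STOP_CODONS.sort()
    return _NON_STOP_CODONS, _CODONS_FOR_AA


def _planted_orf(rng: np.random.Generator, n_codons: int) -> str:
    non_stop, _ = _codon_tables()
    body = "".join(rng.choice(non_stop)
                   for _ in range(n_codons - 1))
    return "ATG" + body + "TAA"


@dataclass
class OrthogroupSim:
    runs: dict[str, OrthogroupTable]
    tree_newicks: list[str]
    transcripts: Assembly
    model_hits: HitTable
    genome_hits: HitTable
    manifest: SimManifest


def simulate_orthogroups(seed: int, genome_manifest: SimManifest,
                         n_runs: int = 4,
                         misclustering_rate: float = 0.0,
                         missing_annotation_rate: float = 0.1,
                         isoform_rate: float = 0.1,
                         cherry_rate: float = 0.1) -> OrthogroupSim:
    """Build per-run orthogroup tables, gene trees, rescue-target
    transcripts and the two hit tables the rescue stage consumes.

    Ortholog pairs from the genome simulation are partitioned into rescue
    targets (focal model missing, transcript present), isoform expansions
    (focal member replaced by two ``.t`` isoforms), cherry cases (an extra
    focal paralog and an outgroup member force tree-based rescue) and
    plain direct one-to-ones. Per run, ``misclustering_rate`` swaps
    partner members between adjacent orthogroups, which later runs expose
    as conflicts.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = [tuple(p) for p in
                                    genome_manifest["pairs"]]
    gene_scaffold: dict[str, str] = dict(genome_manifest["gene_scaffold"])
    n = len(pairs)
    n_missing = int(round(missing_annotation_rate * n))
    n_iso = int(round(isoform_rate * n))
    n_cherry = int(round(cherry_rate * n))
    if n_missing + n_iso + n_cherry > n:
        raise ValueError("partition rates sum past 1")
    order = rng.permutation(n)
    missing_idx = set(order[:n_missing].tolist())
    iso_idx = set(order[n_missing:n_missing + n_iso].tolist())
    cherry_idx = set(
        order[n_missing + n_iso:n_missing + n_iso + n_cherry].tolist())

    base: OrthogroupTable = {}
    rescue_targets: dict[str, dict[str, str]] = {}
    isoform_pairs: list[tuple[str, str]] = []
    cherry_pairs: list[tuple[str, str]] = []
    direct_pairs: list[tuple[str, str]] = []
    tree_newicks: list[str] = []
    transcripts: list[SequenceRecord] = []
    genome_hit_rows: list[HitRecord] = []

    for i, (bo, ml) in enumerate(pairs):
        og = f"OG{i:05d}"
        if i in missing_idx:
            tx = f"{bo}_tx1"
            base[og] = {FOCAL_MODEL_COL: [], FOCAL_TX_COL: [tx],
                        PARTNER_COL: [ml], OUTGROUP_COL: []}
            n_codons = int(rng.integers(40, 80))
            orf = _planted_orf(rng, n_codons)
            utr5 = _random_seq(rng, 20)
            utr3 = _random_seq(rng, 20)
            transcripts.append(SequenceRecord(id=tx,
                                              residues=utr5 + orf + utr3))
            scaffold = gene_scaffold[bo]
            genome_hit_rows.append(HitRecord(
                query_id=tx, subject_id=scaffold, percent_identity=99.0,
                alignment_length=len(orf), evalue=1e-50, bitscore=500.0))
            rescue_targets[og] = {"transcript": tx, "gene": bo,
                                  "scaffold": scaffold, "partner": ml}
        elif i in iso_idx:
            base[og] = {FOCAL_MODEL_COL: [f"{bo}.t1", f"{bo}.t2"],
                        FOCAL_TX_COL: [], PARTNER_COL: [ml],
                        OUTGROUP_COL: []}
            isoform_pairs.append((bo, ml))
        elif i in cherry_idx:
            par, out = f"Bo_par{i}", f"Hc_g{i}"
            base[og] = {FOCAL_MODEL_COL: [bo, par], FOCAL_TX_COL: [],
                        PARTNER_COL: [ml], OUTGROUP_COL: [out]}
            cherry_pairs.append((bo, ml))
            lens = rng.uniform(0.8, 1.4, size=4)
            ilens = rng.uniform(1.5, 2.5, size=2)
            tree_newicks.append(
                f"(({bo}:{lens[0]:.4f},{ml}:{lens[1]:.4f}):{ilens[0]:.4f},"
                f"({par}:{lens[2]:.4f},{out}:{lens[3]:.4f}):{ilens[1]:.4f});"
            )
        else:
            base[og] = {FOCAL_MODEL_COL: [bo], FOCAL_TX_COL: [],
                        PARTNER_COL: [ml], OUTGROUP_COL: []}
            direct_pairs.append((bo, ml))

    runs: dict[str, OrthogroupTable] = {}
    perturbed: dict[str, list[str]] = {}
    labels = list(RUN_LABELS[:n_runs]) if n_runs <= len(RUN_LABELS) else \
        [f"run{i}" for i in range(n_runs)]
    og_ids = sorted(base)
    for label in labels:
        table: OrthogroupTable = {
            og: {col: list(members) for col, members in row.items()}
            for og, row in base.items()}
        touched: list[str] = []
        if misclustering_rate > 0:
            for k, og in enumerate(og_ids[:-1]):
                if rng.random() < misclustering_rate:
                    nxt = og_ids[k + 1]
                    a, b = table[og][PARTNER_COL], table[nxt][PARTNER_COL]
                    table[og][PARTNER_COL], table[nxt][PARTNER_COL] = \
                        list(b), list(a)
                    touched += [og, nxt]
        runs[label] = table
        perturbed[label] = touched

    manifest = SimManifest(seed=seed, data={
        "direct_pairs": direct_pairs,
        "isoform_pairs": isoform_pairs,
        "cherry_pairs": cherry_pairs,
        "rescue_targets": rescue_targets,
        "perturbed": perturbed,
        "all_pairs": pairs,
    })
    return OrthogroupSim(
        runs=runs, tree_newicks=tree_newicks,
        transcripts=Assembly(records=transcripts, name="Bova_tx"),
        model_hits=HitTable([]),  # rescue targets have no model hits
        genome_hits=HitTable(genome_hit_rows),
        manifest=manifest,
    )


def simulate_de_tables(seed: int, pairs: list[tuple[str, str]],
                       n_conserved_per_direction: int = 10,
                       effect_mean: float = 3.0,
                       effect_sd: float = 0.5,
                       null_sd: float = 0.5
                       ) -> tuple[dict[str, tuple[float, float]],
                                  dict[str, tuple[float, float]],
                                  SimManifest]:
    """Two DE tables sharing planted conserved genes.

    Planted genes draw log2FC from Normal(+-effect_mean, effect_sd)
    (redrawn until the strict |log2FC| >= 2 bound clears) with near-zero
    p-values, nulls from Normal(0, null_sd) with uniform p-values; the
    FDR column is Benjamini-Hochberg within each table.
    """
    if not pairs:
        raise ValueError("need at least one ortholog pair")
    if 2 * n_conserved_per_direction > len(pairs):
        raise ValueError("more planted genes than pairs")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(pairs))
    planted_up = [pairs[i] for i in idx[:n_conserved_per_direction]]
    planted_down = [pairs[i] for i in
                    idx[n_conserved_per_direction:
                        2 * n_conserved_per_direction]]

    def draw_effect(sign: float) -> float:
        while True:
            x = sign * rng.normal(effect_mean, effect_sd)
            if abs(x) >= 2.0:
                return x

    tables: list[dict[str, tuple[float, float]]] = []
    planted_set = {p for p in planted_up} | {p for p in planted_down}
    for side in (0, 1):
        genes = []
        lfcs = []
        pvals = []
        for pair in pairs:
            gene = pair[side]
            if pair in planted_set:
                sign = 1.0 if pair in set(planted_up) else -1.0
                lfc = draw_effect(sign)
                p = rng.uniform(0, 1e-12)
            else:
                lfc = rng.normal(0.0, null_sd)
                p = rng.uniform(0.0, 1.0)
            genes.append(gene)
            lfcs.append(lfc)
            pvals.append(p)
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        tables.append({g: (l, float(q))
                       for g, l, q in zip(genes, lfcs, fdr)})
    manifest = SimManifest(seed=seed, data={
        "planted_up_tissue1": planted_up,
        "planted_up_tissue2": planted_down,
    })
    return tables[0], tables[1], manifest


def plant_motifs(seed: int, genome: Assembly,
                 pattern: MotifPattern, n_sites: int,
                 strand_mix: str = "both",
                 max_retries: int = 200
                 ) -> tuple[Assembly, SimManifest]:
    """Back-translate motif realizations into a genome at recorded
    frames/strands (uniform codon choice), non-overlapping.

    ``strand_mix``: "forward", "reverse" or "both".
    """
    if strand_mix not in {"forward", "reverse", "both"}:
        raise ValueError("strand_mix must be forward/reverse/both")
    rng = np.random.default_rng(seed)
    non_stop, codons_for = _codon_tables()
    amino_acids = sorted(codons_for)
    seqs = {rec.id: list(rec.residues) for rec in genome}
    occupied: dict[str, list[tuple[int, int]]] = {r: [] for r in seqs}
    sites = []
    for _ in range(n_sites):
        # realize the pattern as a peptide, then back-translate
        peptide = []
        for el in pattern.elements:
            if el == "?":
                if rng.random() < 0.5:
                    peptide.append(str(rng.choice(amino_acids)))
            elif el == "*":
                peptide.append(str(rng.choice(amino_acids)))
            else:
                peptide.append(el)
        pep = "".join(peptide)
        nt = "".join(str(rng.choice(codons_for[aa])) for aa in pep)
        if strand_mix == "both":
            reverse = bool(rng.integers(0, 2))
        else:
            reverse = strand_mix == "reverse"
        insert = revcomp(nt) if reverse else nt
        placed = False
        for _ in range(max_retries):
            sid = str(rng.choice(sorted(seqs)))
            length = len(seqs[sid])
            if length < len(insert):
                continue
            start0 = int(rng.integers(0, length - len(insert) + 1))
            span = (start0, start0 + len(insert))
            if any(not (span[1] <= s or span[0] >= e)
                   for s, e in occupied[sid]):
                continue
            seqs[sid][span[0]:span[1]] = list(insert)
            occupied[sid].append(span)
            g_start, g_end = start0 + 1, start0 + len(insert)
            if not reverse:
                frame = (start0 % 3) + 1
            else:
                rc_start0 = length - g_end
                frame = -((rc_start0 % 3) + 1)
            sites.append({"seq_id": sid, "genomic_start": g_start,
                          "genomic_end": g_end, "frame": frame,
                          "peptide": pep})
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place a motif site without "
                               "overlap; genome too small")
    new_asm = Assembly(records=[
        SequenceRecord(id=rec.id, residues="".join(seqs[rec.id]),
                       description=rec.description)
        for rec in genome], name=genome.name)
    manifest = SimManifest(seed=seed, data={"sites": sites})
    return new_asm, manifest


def random_assembly(seed: int, n_sequences: int = 5,
                    min_len: int = 100, max_len: int = 5000,
                    name: str = "random") -> Assembly:
    """A random nucleotide assembly (test/support substrate)."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_sequences):
        length = int(rng.integers(min_len, max_len + 1))
        records.append(SequenceRecord(id=f"{name}{i}",
                                      residues=_random_seq(rng, length)))
    return Assembly(records=records, name=name)
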