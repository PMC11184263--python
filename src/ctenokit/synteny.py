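"""Macrosynteny: scaffold-to-chromosome assignment without gene order.

Each (scaffold, chromosome) cell with enough shared orthologs is tested
for enrichment with a one-sided hypergeometric test against the
genome-wide ortholog totals, Benjamini-Hochberg corrected across all
tested cells. A scaffold's primary chromosome is its most ortholog-rich
significant cell; the number of distinct primary chromosomes estimates
the chromosome count, and scaffolds with a second significant, well-
populated chromosome are flagged as putative translocations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneLocus
from .orthologs import OrthologPair


@dataclass
class OrthologPlacement:
    pair: OrthologPair
    scaffold_a: str
    position_a: float  # gene midpoint, bp
    chromosome_b: str
    position_b: float


@dataclass
class SyntenyAssignment:
    scaffold_a: str
    chromosome_b: str
    n_shared: int
    p_value: float
    q_value: float
    significant: bool


def place_orthologs(pairs: list[OrthologPair],
                    genes_a: list[GeneLocus],
                    genes_b: list[GeneLocus]
                    ) -> tuple[list[OrthologPlacement], int]:
    """One placement per pair at the gene midpoints; pairs missing from an
    annotation are skipped and counted."""
    loc_a = {g.gene_id: g for g in genes_a}
    loc_b = {g.gene_id: g for g in genes_b}
    placements = []
    skipped = 0
    for pair in pairs:
        ga, gb = loc_a.get(pair.gene_a), loc_b.get(pair.gene_b)
        if ga is None or gb is None:
            skipped += 1
            continue
        placements.append(OrthologPlacement(
            pair=pair, scaffold_a=ga.scaffold_id, position_a=ga.midpoint,
            chromosome_b=gb.scaffold_id, position_b=gb.midpoint,
        ))
    return placements, skipped


def _cell_counts(placements: list[OrthologPlacement]
                 ) -> tuple[dict[tuple[str, str], int], dict[str, int],
                            dict[str, int], int]:
    cells: dict[tuple[str, str], int] = {}
    per_scaffold: dict[str, int] = {}
    per_chromosome: dict[str, int] = {}
    for p in placements:
        key = (p.scaffold_a, p.chromosome_b)
        cells[key] = cells.get(key, 0) + 1
        per_scaffold[p.scaffold_a] = per_scaffold.get(p.scaffold_a, 0) + 1
        per_chromosome[p.chromosome_b] = \
            per_chromosome.get(p.chromosome_b, 0) + 1
    return cells, per_scaffold, per_chromosome, len(placements)


def assign_scaffolds(placements: list[OrthologPlacement],
                     alpha: float = 0.05,
                     min_orthologs: int = 3) -> list[SyntenyAssignment]:
    """Hypergeometric enrichment of every cell with >= ``min_orthologs``
    shared orthologs, BH-corrected; significant iff q <= alpha.

    When only one chromosome is observed the enrichment null is undefined
    (every cell spans the whole table); scaffolds are then force-assigned
    to that chromosome with p = q = 1.
    """
    if not placements:
        raise ValueError("assign_scaffolds needs at least one placement")
    cells, per_scaffold, per_chromosome, total = _cell_counts(placements)
    tested = [(key, k) for key, k in cells.items() if k >= min_orthologs]
    if not tested:
        return []
    if len(per_chromosome) == 1:
        return [SyntenyAssignment(scaffold_a=s, chromosome_b=c,
                                  n_shared=k, p_value=1.0, q_value=1.0,
                                  significant=True)
                for (s, c), k in sorted(tested)]
    pvals = []
    for (scaffold, chromosome), k in tested:
        n_scaffold = per_scaffold[scaffold]
        n_chromosome = per_chromosome[chromosome]
        # P(X >= k), X ~ Hypergeom(total, n_chromosome, n_scaffold)
        pvals.append(hypergeom.sf(k - 1, total, n_chromosome, n_scaffold))
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out = []
    for ((scaffold, chromosome), k), p, q, sig in \
            zip(tested, pvals, qvals, reject):
        out.append(SyntenyAssignment(
            scaffold_a=scaffold, chromosome_b=chromosome, n_shared=k,
            p_value=float(p), q_value=float(q), significant=bool(sig),
        ))
    out.sort(key=lambda a: (a.scaffold_a, a.chromosome_b))
    return out


def primary_assignments(assignments: list[SyntenyAssignment]
                        ) -> dict[str, SyntenyAssignment]:
    """Primary chromosome per scaffold: its most ortholog-rich significant
    cell (ties -> smaller q, then lexicographic chromosome id, logged)."""
    best: dict[str, SyntenyAssignment] = {}
    for a in assignments:
        if not a.significant:
            continue
        cur = best.get(a.scaffold_a)
        if cur is None:
            best[a.scaffold_a] = a
            continue
        key = (-a.n_shared, a.q_value, a.chromosome_b)
        cur_key = (-cur.n_shared, cur.q_value, cur.chromosome_b)
        if key < cur_key:
            best[a.scaffold_a] = a
        if key[:2] == cur_key[:2]:
            warnings.warn(
                f"primary-chromosome tie on scaffold {a.scaffold_a}: "
                f"{cur.chromosome_b} vs {a.chromosome_b}", stacklevel=2)
    return best


def chromosome_count(assignments: list[SyntenyAssignment]
                     ) -> tuple[int, dict[str, list[str]]]:
    """Distinct primary chromosomes with >= 1 significantly assigned
    scaffold, plus chromosome -> scaffolds membership."""
    primary = primary_assignments(assignments)
    membership: dict[str, list[str]] = {}
    for scaffold, a in primary.items():
        membership.setdefault(a.chromosome_b, []).append(scaffold)
    for scaffolds in membership.values():
        scaffolds.sort()
    if not membership:
        warnings.warn("no significant assignments; chromosome count is 0",
                      stacklevel=2)
    return len(membership), membership


def flag_translocations(assignments: list[SyntenyAssignment],
                        placements: list[OrthologPlacement],
                        min_secondary: int = 5,
                        min_fraction: float = 0.1
                        ) -> list[tuple[str, list[str], dict[str, int]]]:
    """Scaffolds with a significant secondary chromosome holding
    >= ``min_secondary`` orthologs and >= ``min_fraction`` of the
    scaffold's total."""
    cells, per_scaffold, _, _ = _cell_counts(placements)
    primary = primary_assignments(assignments)
    sig_cells = {(a.scaffold_a, a.chromosome_b)
                 for a in assignments if a.significant}
    flagged = []
    for scaffold, prim in sorted(primary.items()):
        total = per_scaffold[scaffold]
        extra = []
        for (s, c), k in cells.items():
            if s != scaffold or c == prim.chromosome_b:
                continue
            if k >= min_secondary and k / total >= min_fraction \
                    and (s, c) in sig_cells:
                extra.append(c)
        if extra:
            chroms = [prim.chromosome_b] + sorted(extra)
            counts = {c: cells[(scaffold, c)] for c in chroms}
            flagged.append((scaffold, chroms, counts))
    return flagged


def dotplot_table(placements: list[OrthologPlacement],
                  lengths_a: dict[str, int],
                  lengths_b: dict[str, int],
                  assignments: list[SyntenyAssignment] | None = None
                  ) -> list[tuple[str, str, float, float]]:
    """Oxford dot-plot rows (pair label, x on species B, y on species A)
    with cumulative-offset coordinates.

    Species-B chromosomes are laid out in id order; species-A scaffolds by
    (assigned chromosome, descending length). The layout depends only on
    the sequence sets, so reordering the input placements never changes a
    coordinate.
    """
    primary = primary_assignments(assignments) if assignments else {}
    chrom_order = sorted(lengths_b)
    offsets_b = {}
    run = 0
    for c in chrom_order:
        offsets_b[c] = run
        run += lengths_b[c]

    def scaffold_key(s: str) -> tuple:
        prim = primary.get(s)
        chrom = prim.chromosome_b if prim else "~unassigned"
        return (chrom, -lengths_a[s], s)

    offsets_a = {}
    run = 0
    for s in sorted(lengths_a, key=scaffold_key):
        offsets_a[s] = run
        run += lengths_a[s]
    rows = []
    for p in placements:
        label = f"{p.pair.gene_a}|{p.pair.gene_b}"
        x = offsets_b[p.chromosome_b] + p.position_b
        y = offsets_a[p.scaffold_a] + p.position_a
        rows.append((label, p.scaffold_a, x, y))
    return rows


def write_assignments_tsv(assignments: list[SyntenyAssignment],
                          path: str) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold_a\tchromosome_b\tn_shared\tp_value\tq_value\t"
                 "significant\n")
        for a in assignments:
            fh.write(f"{a.scaffold_a}\t{a.chromosome_b}\t{a.n_shared}\t"
                     f"{a.p_value:.6g}\t{a.q_value:.6g}\t"
                     f"{int(a.significant)}\n")


def write_dotplot_tsv(rows: list[tuple[str, str, float, float]],
                      path: str) -> None:
    with open(path, "w") as fh:
        fh.write("pair\tscaffold_a\tx_species_b\ty_species_a\n")
        for label, scaffold, x, y in rows:
            fh.write(f"{label}\t{scaffold}\t{x:g}\t{y:g}\n")
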