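"""Cross-species conserved differential-expression filter.

An ortholog pair counts as a conserved tissue-defining gene when one
species meets the strict criterion (FDR <= 0.001 and |log2FC| >= 2), the
other meets the relaxed one (FDR <= 0.01), and the fold-change signs
agree. Thresholds are inclusive. The contrast orientation (tissue1 vs
tissue2, positive = higher in tissue1) must be identical in both tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .orthologs import OrthologPair

DEFAULT_STRICT_FDR = 0.001
DEFAULT_STRICT_LFC = 2.0
DEFAULT_RELAXED_FDR = 0.01

DETable = Mapping[str, tuple[float, float]]  # gene -> (log2fc, fdr)


@dataclass
class ConservedDEGene:
    pair: OrthologPair
    direction: str  # up_tissue1 | up_tissue2
    strong_species: str  # "A" or "B"
    log2fc_a: float
    fdr_a: float
    log2fc_b: float
    fdr_b: float


def _strict(lfc: float, fdr: float, strict_fdr: float,
            strict_lfc: float) -> bool:
    return fdr <= strict_fdr and abs(lfc) >= strict_lfc


def conserved_de(de_a: DETable, de_b: DETable,
                 pairs: list[OrthologPair],
                 strict_fdr: float = DEFAULT_STRICT_FDR,
                 strict_lfc: float = DEFAULT_STRICT_LFC,
                 relaxed_fdr: float = DEFAULT_RELAXED_FDR,
                 require_direction_agreement: bool = True,
                 meta_a: Mapping[str, str] | None = None,
                 meta_b: Mapping[str, str] | None = None,
                 ) -> tuple[list[ConservedDEGene], int]:
    """Apply the conserved-DE filter over ortholog pairs.

    Returns (conserved genes, number of pairs skipped because a gene was
    absent from one of the tables). A declared contrast-orientation
    mismatch between the two tables' metadata is a hard error.
    """
    if meta_a is not None and meta_b is not None:
        ca, cb = meta_a.get("contrast"), meta_b.get("contrast")
        if ca is not None and cb is not None and ca != cb:
            raise ValueError(
                f"contrast orientation mismatch: {ca!r} vs {cb!r}")
    out: list[ConservedDEGene] = []
    skipped = 0
    for pair in pairs:
        if pair.gene_a not in de_a or pair.gene_b not in de_b:
            skipped += 1
            continue
        lfc_a, fdr_a = de_a[pair.gene_a]
        lfc_b, fdr_b = de_b[pair.gene_b]
        strong_a = _strict(lfc_a, fdr_a, strict_fdr, strict_lfc) \
            and fdr_b <= relaxed_fdr
        strong_b = _strict(lfc_b, fdr_b, strict_fdr, strict_lfc) \
            and fdr_a <= relaxed_fdr
        if not (strong_a or strong_b):
            continue
        if require_direction_agreement and \
                np.sign(lfc_a) != np.sign(lfc_b):
            continue
        # direction from the strong species (the shared sign when agreeing)
        ref_lfc = lfc_a if strong_a else lfc_b
        out.append(ConservedDEGene(
            pair=pair,
            direction="up_tissue1" if ref_lfc > 0 else "up_tissue2",
            strong_species="A" if strong_a else "B",
            log2fc_a=lfc_a, fdr_a=fdr_a, log2fc_b=lfc_b, fdr_b=fdr_b,
        ))
    return out, skipped


def pca_input_matrix(expr_a: pd.DataFrame, expr_b: pd.DataFrame,
                     pairs: list[OrthologPair]
                     ) -> tuple[pd.DataFrame, int]:
    """Join per-sample TPM tables over ortholog pairs for PCA.

    ``expr_a``/``expr_b``: genes x samples TPM, indexed by gene id. Rows
    of the result are ortholog pairs (indexed ``gene_a|gene_b``), columns
    the samples of both species, values log2(TPM+1). Pairs absent from a
    table are dropped and counted.
    """
    rows = []
    index = []
    dropped = 0
    for pair in pairs:
        if pair.gene_a not in expr_a.index or pair.gene_b not in expr_b.index:
            dropped += 1
            continue
        joined = pd.concat([expr_a.loc[pair.gene_a],
                            expr_b.loc[pair.gene_b]])
        rows.append(np.log2(joined.astype(float) + 1.0))
        index.append(f"{pair.gene_a}|{pair.gene_b}")
    if rows:
        mat = pd.DataFrame(rows, index=index)
    else:
        mat = pd.DataFrame(
            columns=list(expr_a.columns) + list(expr_b.columns))
    return mat, dropped


def write_conserved_tables(genes: list[ConservedDEGene], out_prefix: str,
                           tissue1: str = "tissue1",
                           tissue2: str = "tissue2") -> dict[str, str]:
    """Write one TSV per direction (``conserved_up_<tissue>.tsv``)."""
    paths = {}
    for direction, tissue in (("up_tissue1", tissue1),
                              ("up_tissue2", tissue2)):
        path = f"{out_prefix}conserved_up_{tissue}.tsv"
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tstrong_species\t"
                     "log2fc_a\tfdr_a\tlog2fc_b\tfdr_b\n")
            for g in genes:
                if g.direction != direction:
                    continue
                fh.write(f"{g.pair.gene_a}\t{g.pair.gene_b}\t"
                         f"{g.strong_species}\t{g.log2fc_a:g}\t{g.fdr_a:g}\t"
                         f"{g.log2fc_b:g}\t{g.fdr_b:g}\n")
        paths[direction] = path
    return paths
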