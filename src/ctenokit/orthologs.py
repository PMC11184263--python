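"""Single-copy ortholog consolidation.

One-to-one cross-species gene pairs are assembled from three sources, in
the order of trust used throughout the package:

1. *direct* — orthogroups (from clustering runs at several MCL inflations)
   with exactly one member of each focal species;
2. *tree* — midpoint-rooted gene trees in which one gene from each focal
   species forms a cherry (a two-leaf clade);
3. *isoform* — orthogroups that collapse to one locus per species once
   isoform suffixes are stripped.

A gene observed with two distinct partners anywhere is treated as
conflicting and removed together with all its pairs; the final set is a
partial matching (no gene appears twice).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable

import dendropy

from .io import OrthogroupTable

Pair = tuple[str, str]

DEFAULT_ISOFORM_PATTERN = r"\.(t|i)\d+$"
DEFAULT_SPECIES_PATTERN = r"^([A-Za-z0-9]+)_"


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    provenance: set[str] = field(default_factory=set)
    source_runs: set[str] = field(default_factory=set)

    @property
    def pair(self) -> Pair:
        return (self.gene_a, self.gene_b)


def make_isoform_map(pattern: str = DEFAULT_ISOFORM_PATTERN
                     ) -> Callable[[str], str]:
    """Transcript-id -> locus-id mapper stripping a trailing isoform suffix
    (default ``.t<digits>`` / ``.i<digits>``)."""
    rx = re.compile(pattern)

    def mapper(transcript_id: str) -> str:
        locus = rx.sub("", transcript_id)
        return locus if locus else transcript_id

    return mapper


def make_species_parser(pattern: str = DEFAULT_SPECIES_PATTERN
                        ) -> Callable[[str], str]:
    """Leaf-label -> species parser from a one-group prefix regex."""
    rx = re.compile(pattern)

    def parser(label: str) -> str:
        m = rx.match(label)
        if not m:
            raise ValueError(f"cannot parse species from leaf label {label!r}")
        return m.group(1)

    return parser


def direct_one_to_ones(run: OrthogroupTable, species_a: str, species_b: str
                       ) -> set[Pair]:
    """Pairs from orthogroups holding exactly one member of each focal
    species (members of other species ignored)."""
    pairs: set[Pair] = set()
    for row in run.values():
        if species_a not in row or species_b not in row:
            raise KeyError(
                f"orthogroup table lacks species column "
                f"{species_a!r} or {species_b!r}"
            )
        a, b = row[species_a], row[species_b]
        if len(a) == 1 and len(b) == 1:
            pairs.add((a[0], b[0]))
    return pairs


def union_runs(runs: dict[str, set[Pair]]
               ) -> tuple[dict[Pair, set[str]], set[str]]:
    """Union pair sets across clustering runs.

    A gene appearing with two or more distinct partners across runs is a
    conflict; conflicting genes and all their pairs are removed. Returns
    (surviving pair -> contributing run labels, conflicting genes).
    """
    if not runs:
        raise ValueError("union_runs needs at least one run")
    sources: dict[Pair, set[str]] = {}
    for label, pairs in runs.items():
        for pair in pairs:
            sources.setdefault(pair, set()).add(label)
    partners_a: dict[str, set[str]] = {}
    partners_b: dict[str, set[str]] = {}
    for a, b in sources:
        partners_a.setdefault(a, set()).add(b)
        partners_b.setdefault(b, set()).add(a)
    conflicts = {g for g, ps in partners_a.items() if len(ps) > 1}
    conflicts |= {g for g, ps in partners_b.items() if len(ps) > 1}
    surviving = {pair: labels for pair, labels in sources.items()
                 if pair[0] not in conflicts and pair[1] not in conflicts}
    return surviving, conflicts


def _leaf_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            d = pdm.distance(t1, t2)
            key = tuple(sorted((t1.label, t2.label)))
            out[key] = d
    return out


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Ties among equally longest paths break by lexicographically smallest
    (sorted) leaf-label pair. When the midpoint falls exactly on an
    internal node the tree is rooted there. All-zero branch lengths root
    at the first internal node with a warning.
    """
    tree = tree.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
        if edge.length < 0:
            raise ValueError("negative branch length")
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    dists = _leaf_distances(tree)
    max_d = max(dists.values())
    if max_d == 0:
        warnings.warn("all-zero branch lengths; rooting at first internal "
                      "node", stacklevel=2)
        internal = next(n for n in tree.preorder_node_iter()
                        if not n.is_leaf())
        tree.reroot_at_node(internal, update_bipartitions=False)
        return tree
    u_label, v_label = min(k for k, d in dists.items() if d == max_d)
    by_label = {leaf.taxon.label: leaf for leaf in leaves}
    u, v = by_label[u_label], by_label[v_label]
    # node path u -> mrca -> v
    u_anc = [u] + list(u.ancestor_iter())
    v_anc = [v] + list(v.ancestor_iter())
    v_set = {id(n): i for i, n in enumerate(v_anc)}
    mrca_i = next(i for i, n in enumerate(u_anc) if id(n) in v_set)
    mrca = u_anc[mrca_i]
    path_nodes = u_anc[:mrca_i + 1] + list(
        reversed(v_anc[:v_set[id(mrca)]]))
    half = max_d / 2.0
    walked = 0.0
    for i in range(len(path_nodes) - 1):
        near, far = path_nodes[i], path_nodes[i + 1]
        if far is near.parent_node:
            edge, head_is_far = near.edge, False
        else:
            edge, head_is_far = far.edge, True
        length = edge.length
        if walked + length < half:
            walked += length
            continue
        offset = half - walked  # distance into this edge, from `near`
        at_node = None
        if offset == 0.0:
            at_node = near
        elif offset == length:
            at_node = far
        if at_node is not None and not at_node.is_leaf():
            tree.reroot_at_node(at_node, update_bipartitions=False)
            return tree
        # split the edge; length1 is the tail(parent)-side segment
        if head_is_far:
            length1, length2 = offset, length - offset
        else:
            length1, length2 = length - offset, offset
        tree.reroot_at_edge(edge, length1=length1, length2=length2,
                            update_bipartitions=False)
        return tree
    raise AssertionError("midpoint not found on the maximal path")


def _cherries(tree: dendropy.Tree,
              species_of: Callable[[str], str],
              species_a: str, species_b: str) -> set[Pair]:
    pairs: set[Pair] = set()
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if len(children) != 2 or not all(c.is_leaf() for c in children):
            continue
        # undo newick's unquoted-label space convention
        labels = [c.taxon.label.replace(" ", "_") for c in children]
        species = [species_of(lab) for lab in labels]
        if set(species) == {species_a, species_b}:
            if species[0] == species_a:
                pairs.add((labels[0], labels[1]))
            else:
                pairs.add((labels[1], labels[0]))
    return pairs


def cherry_rescue(trees: Iterable[dendropy.Tree], species_a: str,
                  species_b: str,
                  species_parser: Callable[[str], str] | None = None,
                  min_leaves: int = 4,
                  pre_rooted: bool = False) -> set[Pair]:
    """Pairs from cherries of one species-A and one species-B gene.

    Trees smaller than ``min_leaves`` are skipped (the consolidation is run
    on orthogroups with four or more genes); unrooted trees are
    midpoint-rooted first. Genes occurring in more than one cherry across
    the tree set are ambiguous and dropped.
    """
    species_of = species_parser or make_species_parser()
    all_pairs: list[Pair] = []
    for tree in trees:
        if len(tree.leaf_nodes()) < min_leaves:
            continue
        rooted = tree if pre_rooted else midpoint_root(tree)
        all_pairs.extend(_cherries(rooted, species_of, species_a, species_b))
    partners_a: dict[str, set[str]] = {}
    partners_b: dict[str, set[str]] = {}
    for a, b in all_pairs:
        partners_a.setdefault(a, set()).add(b)
        partners_b.setdefault(b, set()).add(a)
    ambiguous = {a for a, ps in partners_a.items() if len(ps) > 1}
    ambiguous |= {b for b, ps in partners_b.items() if len(ps) > 1}
    return {(a, b) for a, b in all_pairs
            if a not in ambiguous and b not in ambiguous}


def isoform_rescue(run: OrthogroupTable,
                   iso: Callable[[str], str] | None,
                   species_a: str, species_b: str) -> set[Pair]:
    """Locus pairs from orthogroups that collapse to exactly one locus per
    focal species once isoform suffixes are stripped."""
    iso = iso or make_isoform_map()
    pairs: set[Pair] = set()
    for row in run.values():
        if species_a not in row or species_b not in row:
            raise KeyError("orthogroup table lacks a focal species column")
        loci_a = {iso(m) for m in row[species_a]}
        loci_b = {iso(m) for m in row[species_b]}
        if len(loci_a) == 1 and len(loci_b) == 1:
            pairs.add((loci_a.pop(), loci_b.pop()))
    return pairs


def finalize(direct: dict[Pair, set[str]] | set[Pair],
             tree_pairs: set[Pair],
             isoform_pairs: set[Pair]
             ) -> tuple[list[OrthologPair], set[str]]:
    """Merge the three sources into a final one-pair-per-gene set.

    Identical pairs from several sources merge their provenance; a gene
    appearing with different partners in different sources is removed
    entirely and reported. Returns (final pairs, removed genes).
    """
    if isinstance(direct, set):
        direct = {pair: set() for pair in direct}
    merged: dict[Pair, OrthologPair] = {}
    for provenance, pairs in (("direct", direct),
                              ("tree", tree_pairs),
                              ("isoform", isoform_pairs)):
        for pair in pairs:
            entry = merged.setdefault(
                pair, OrthologPair(gene_a=pair[0], gene_b=pair[1]))
            entry.provenance.add(provenance)
            if provenance == "direct":
                entry.source_runs |= direct[pair]
    partners_a: dict[str, set[str]] = {}
    partners_b: dict[str, set[str]] = {}
    for a, b in merged:
        partners_a.setdefault(a, set()).add(b)
        partners_b.setdefault(b, set()).add(a)
    removed = {a for a, ps in partners_a.items() if len(ps) > 1}
    removed |= {b for b, ps in partners_b.items() if len(ps) > 1}
    final = [p for (a, b), p in merged.items()
             if a not in removed and b not in removed]
    order = {"direct": 0, "tree": 1, "isoform": 2}
    final.sort(key=lambda p: (min(order[x] for x in p.provenance),
                              p.gene_a, p.gene_b))
    _assert_partial_matching(final)
    return final, removed


def _assert_partial_matching(pairs: list[OrthologPair]) -> None:
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    for p in pairs:
        if p.gene_a in seen_a or p.gene_b in seen_b:
            raise AssertionError(
                f"final ortholog set is not a partial matching: "
                f"{p.gene_a}/{p.gene_b} repeated"
            )
        seen_a.add(p.gene_a)
        seen_b.add(p.gene_b)


def read_newick_trees(paths: Iterable[str]) -> list[dendropy.Tree]:
    """Read one newick tree per file, each in its own taxon namespace."""
    trees = []
    for path in paths:
        trees.append(dendropy.Tree.get(path=str(path), schema="newick",
                                       preserve_underscores=True))
    return trees


def write_pairs_tsv(pairs: list[OrthologPair], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tprovenance\tsource_runs\n")
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t"
                     f"{','.join(sorted(p.provenance))}\t"
                     f"{','.join(sorted(p.source_runs))}\n")


def read_pairs_tsv(path: str) -> list[OrthologPair]:
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_a"):
            raise ValueError(f"{path}: expected a gene_a/gene_b header")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2 or not cols[0]:
                continue
            prov = set(cols[2].split(",")) if len(cols) > 2 and cols[2] else set()
            runs = set(cols[3].split(",")) if len(cols) > 3 and cols[3] else set()
            pairs.append(OrthologPair(gene_a=cols[0], gene_b=cols[1],
                                      provenance=prov, source_runs=runs))
    return pairs
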