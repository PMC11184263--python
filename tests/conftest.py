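"""Shared fixtures: small seeded simulations reused across test modules."""

import dendropy
import numpy as np
import pytest

from ctenokit.simulate import (simulate_orthogroups,
                               simulate_two_species_genomes)


@pytest.fixture(scope="session")
def genome_sim():
    """Small two-species genome with sequences and planted gaps."""
    return simulate_two_species_genomes(
        seed=11, n_chromosomes=5, n_genes=60, fragmentation=2,
        plant_gaps=True, build_sequences=True)


@pytest.fixture(scope="session")
def ortho_sim(genome_sim):
    """Orthogroup tables / trees / rescue inputs over the genome sim."""
    return simulate_orthogroups(seed=12, genome_manifest=genome_sim.manifest)


def random_tree(rng: np.random.Generator, n_leaves: int) -> dendropy.Tree:
    """Random binary tree with uniform branch lengths, built by random
    pair-merging (independent of any package code)."""
    taxa = dendropy.TaxonNamespace([f"L{i}" for i in range(n_leaves)])
    nodes = []
    for taxon in taxa:
        node = dendropy.Node(taxon=taxon)
        node.edge.length = float(rng.uniform(0.1, 2.0))
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.1, 2.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    return tree
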