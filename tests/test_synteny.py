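"""Macrosynteny: placement, enrichment, chromosome count, translocations."""

import math
import warnings

import numpy as np
import pytest

from ctenokit.io import GeneLocus
from ctenokit.orthologs import OrthologPair
from ctenokit.synteny import (OrthologPlacement, assign_scaffolds,
                              chromosome_count, dotplot_table,
                              flag_translocations, place_orthologs,
                              primary_assignments)
from ctenokit.simulate import simulate_two_species_genomes


def pair(a, b):
    return OrthologPair(gene_a=a, gene_b=b)


def placement(scaffold, chromosome, i=0):
    return OrthologPlacement(pair=pair(f"a{scaffold}_{chromosome}_{i}",
                                       f"b{scaffold}_{chromosome}_{i}"),
                             scaffold_a=scaffold, position_a=100.0 * i + 50,
                             chromosome_b=chromosome,
                             position_b=100.0 * i + 50)


def hypergeom_oracle(k, N, K, n):
    """Exact upper-tail P(X >= k) by direct combinatorial summation."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / math.comb(N, n)


class TestPlaceOrthologs:
    def test_midpoint_positions(self):
        ga = [GeneLocus(gene_id="a1", scaffold_id="s1", start=100, end=200,
                        strand="+")]
        gb = [GeneLocus(gene_id="b1", scaffold_id="c1", start=11, end=20,
                        strand="-")]
        (p,), skipped = place_orthologs([pair("a1", "b1")], ga, gb)
        assert p.position_a == 150 and p.position_b == 15.5
        assert skipped == 0

    def test_missing_gene_skipped(self):
        placements, skipped = place_orthologs([pair("a1", "b1")], [], [])
        assert placements == [] and skipped == 1

    def test_simulated_coordinates_match_manifest(self, genome_sim):
        pairs = [pair(a, b) for a, b in genome_sim.manifest["pairs"]]
        placements, skipped = place_orthologs(pairs, genome_sim.genes_a,
                                              genome_sim.genes_b)
        assert skipped == 0 and len(placements) == len(pairs)
        scaffold_of = genome_sim.manifest["gene_scaffold"]
        for p in placements:
            assert p.scaffold_a == scaffold_of[p.pair.gene_a]


class TestAssignScaffolds:
    def test_concentrated_scaffold_p_equals_oracle(self):
        placements = [placement("s1", "chr1", i) for i in range(20)]
        # background: 20 orthologs spread over other scaffolds/chromosomes
        for j in range(20):
            placements.append(placement(f"bg{j}", f"chr{1 + j % 13}", j))
        assignments = assign_scaffolds(placements)
        (cell,) = [a for a in assignments if a.scaffold_a == "s1"]
        per_chrom = sum(1 for p in placements if p.chromosome_b == "chr1")
        expect = hypergeom_oracle(20, len(placements), per_chrom, 20)
        assert cell.p_value == pytest.approx(expect, rel=1e-9)
        assert cell.significant

    def test_min_orthologs_floor(self):
        placements = [placement("s1", f"chr{j}", j) for j in range(3)]
        placements += [placement(f"bg{j}", "chrX", j) for j in range(10)]
        assignments = assign_scaffolds(placements, min_orthologs=3)
        assert all(a.scaffold_a != "s1" for a in assignments)

    def test_bh_matches_step_up_rule(self):
        sim = simulate_two_species_genomes(61, n_chromosomes=6,
                                           n_genes=240, fragmentation=3,
                                           placement_noise_rate=0.05,
                                           build_sequences=False)
        pairs = [pair(a, b) for a, b in sim.manifest["pairs"]]
        placements, _ = place_orthologs(pairs, sim.genes_a, sim.genes_b)
        assignments = assign_scaffolds(placements, alpha=0.05)
        ps = sorted((a.p_value, a.significant) for a in assignments)
        m = len(ps)
        # textbook step-up: largest k with p_(k) <= k*alpha/m
        k_star = 0
        for k, (p, _) in enumerate(ps, start=1):
            if p <= 0.05 * k / m:
                k_star = k
        for i, (p, sig) in enumerate(ps):
            assert sig == (i < k_star)
        # BH q-values are monotone in p-rank
        qs = [a.q_value for a in sorted(assignments,
                                        key=lambda a: a.p_value)]
        assert qs == sorted(qs)

    def test_label_permutation_destroys_significance(self):
        sim = simulate_two_species_genomes(62, n_chromosomes=8,
                                           n_genes=320, fragmentation=2,
                                           build_sequences=False)
        pairs = [pair(a, b) for a, b in sim.manifest["pairs"]]
        placements, _ = place_orthologs(pairs, sim.genes_a, sim.genes_b)
        rng = np.random.default_rng(63)
        chroms = [p.chromosome_b for p in placements]
        clean = 0
        n_reps = 20
        for _ in range(n_reps):
            perm = rng.permutation(chroms)
            shuffled = [OrthologPlacement(
                pair=p.pair, scaffold_a=p.scaffold_a,
                position_a=p.position_a, chromosome_b=c,
                position_b=p.position_b)
                for p, c in zip(placements, perm)]
            assignments = assign_scaffolds(shuffled)
            if not any(a.significant for a in assignments):
                clean += 1
        assert clean >= int(0.95 * n_reps)


class TestChromosomeCount:
    def test_planted_thirteen(self):
        sim = simulate_two_species_genomes(64, n_genes=650,
                                           fragmentation=4,
                                           build_sequences=False)
        pairs = [pair(a, b) for a, b in sim.manifest["pairs"]]
        placements, _ = place_orthologs(pairs, sim.genes_a, sim.genes_b)
        count, membership = chromosome_count(assign_scaffolds(placements))
        assert count == 13
        # mutually exclusive: every scaffold has exactly one primary
        all_scaffolds = [s for ss in membership.values() for s in ss]
        assert len(all_scaffolds) == len(set(all_scaffolds))

    def test_single_chromosome_toy(self):
        placements = [placement("s1", "chr1", i) for i in range(10)]
        count, membership = chromosome_count(assign_scaffolds(placements))
        assert count == 1 and membership == {"chr1": ["s1"]}

    def test_empty_significant_set_warns(self):
        with pytest.warns(UserWarning):
            count, _ = chromosome_count([])
        assert count == 0


class TestTranslocations:
    def test_rule_definition(self):
        placements = [placement("s1", "chr1", i) for i in range(24)]
        placements += [placement("s1", "chr7", 100 + i) for i in range(6)]
        placements += [placement(f"bg{j}", f"chr{j % 13}", j)
                       for j in range(400)]
        assignments = assign_scaffolds(placements)
        flagged = flag_translocations(assignments, placements)
        (entry,) = [f for f in flagged if f[0] == "s1"]
        assert set(entry[1]) == {"chr1", "chr7"}
        assert entry[2] == {"chr1": 24, "chr7": 6}

    def test_small_secondary_not_flagged(self):
        placements = [placement("s1", "chr1", i) for i in range(29)]
        placements += [placement("s1", "chr7", 100)]
        placements += [placement(f"bg{j}", f"chr{j % 13}", j)
                       for j in range(400)]
        assignments = assign_scaffolds(placements)
        assert all(f[0] != "s1"
                   for f in flag_translocations(assignments, placements))

    def test_planted_translocations_recovered(self):
        sim = simulate_two_species_genomes(65, n_genes=520,
                                           fragmentation=2,
                                           translocation_rate=0.15,
                                           build_sequences=False)
        pairs = [pair(a, b) for a, b in sim.manifest["pairs"]]
        placements, _ = place_orthologs(pairs, sim.genes_a, sim.genes_b)
        assignments = assign_scaffolds(placements)
        flagged = {f[0] for f in flag_translocations(assignments,
                                                     placements)}
        planted = {t["scaffold"] for t in
                   sim.manifest["translocations"]}
        assert planted == flagged

    def test_no_translocations_in_null_sim(self):
        sim = simulate_two_species_genomes(66, n_genes=260,
                                           fragmentation=2,
                                           translocation_rate=0.0,
                                           build_sequences=False)
        pairs = [pair(a, b) for a, b in sim.manifest["pairs"]]
        placements, _ = place_orthologs(pairs, sim.genes_a, sim.genes_b)
        assignments = assign_scaffolds(placements)
        assert flag_translocations(assignments, placements) == []


class TestDotplot:
    def lengths(self):
        return {"s1": 1000, "s2": 500}, {"c1": 2000, "c2": 800}

    def test_prefix_sum_offsets(self):
        la, lb = self.lengths()
        rows = dotplot_table([placement("s2", "c2", 0)], la, lb)
        (row,) = rows
        # c2 offset = len(c1) = 2000; s2 sorts after s1 (both unassigned,
        # longer first) so its offset is 1000
        assert row[2] == pytest.approx(2000 + 50)
        assert row[3] == pytest.approx(1000 + 50)

    def test_empty(self):
        assert dotplot_table([], *self.lengths()) == []

    def test_input_order_invariance(self):
        la, lb = self.lengths()
        ps = [placement("s1", "c1", 1), placement("s2", "c2", 2)]
        fwd = dotplot_table(ps, la, lb)
        rev = dotplot_table(ps[::-1], la, lb)
        assert sorted(fwd) == sorted(rev)
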