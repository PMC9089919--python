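"""K80 distances, neighbor joining, identical-allele grouping, and species
monophyly, each checked against an independent oracle."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drbkit.phylo import (
    DistanceMatrix,
    Node,
    PhyloTree,
    identical_allele_groups,
    k80_distance,
    neighbor_joining,
    species_monophyly,
)


def seq_with(P_count, Q_count, n=100):
    """A pair of sequences with the given transition/transversion counts."""
    a = "A" * n
    b = "G" * P_count + "C" * Q_count + "A" * (n - P_count - Q_count)
    return a, b


class TestK80:
    def test_identical_sequences(self):
        assert k80_distance("ACGT" * 10, "ACGT" * 10)[0] == 0.0

    def test_transitions_only_worked_example(self):
        d, P, Q = k80_distance(*seq_with(10, 0))
        assert (P, Q) == (0.1, 0.0)
        assert d == pytest.approx(0.11157, abs=5e-6)

    def test_transversions_only_closed_form(self):
        d, P, Q = k80_distance(*seq_with(0, 10))
        assert (P, Q) == (0.0, 0.1)
        # -1/2 ln((1-2P-Q) sqrt(1-2Q)) = -1/2 ln(0.9*sqrt(0.8))
        assert d == pytest.approx(-0.5 * np.log(0.9 * np.sqrt(0.8)), abs=1e-12)
        assert d == pytest.approx(0.108465, abs=5e-6)

    def test_saturation_is_flagged_infinite(self):
        d, *_ = k80_distance("A" * 10, "G" * 10)
        assert np.isinf(d)

    def test_gapped_columns_excluded_pairwise(self):
        d, P, Q = k80_distance("AC-GT", "ACNGA")
        assert (P, Q) == (0.0, 0.25)  # 4 comparable columns, one tv

    def test_monotone_in_P_and_Q(self):
        base = k80_distance(*seq_with(5, 5))[0]
        assert k80_distance(*seq_with(6, 5))[0] > base
        assert k80_distance(*seq_with(5, 6))[0] > base


def random_tree(rng, n_tips, min_bl=0.05, max_bl=1.0):
    nodes = [Node(name=f"t{i}", length=rng.uniform(min_bl, max_bl)) for i in range(n_tips)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = Node(length=rng.uniform(min_bl, max_bl),
                      children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return PhyloTree(Node(children=nodes))


class TestNeighborJoining:
    def test_fewer_than_three_taxa_errors(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]])))

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], D))
        names, pd = tree.patristic_distances()
        idx = {n: i for i, n in enumerate(names)}
        for (i, a), (j, b) in itertools.combinations(enumerate(["a", "b", "c"]), 2):
            assert pd[idx[a], idx[b]] == pytest.approx(D[i, j])

    def test_additive_matrix_recovered_exactly(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            tree = random_tree(rng, int(rng.integers(4, 9)))
            names, pd = tree.patristic_distances()
            nj = neighbor_joining(DistanceMatrix(names, pd))
            names2, pd2 = nj.patristic_distances()
            order = [names2.index(n) for n in names]
            assert np.allclose(pd2[np.ix_(order, order)], pd, atol=1e-10)

    def test_ultrametric_quartet_topology_matches_minimum_pairing_oracle(self):
        # ((a,b),(c,d)) ultrametric: the correct split minimizes the sum of
        # within-pair distances over the three possible pairings
        D = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 4],
                [6, 6, 4, 0.0],
            ]
        )
        names = ["a", "b", "c", "d"]
        pairings = {
            frozenset({frozenset({"a", "b"}), frozenset({"c", "d"})}): D[0, 1] + D[2, 3],
            frozenset({frozenset({"a", "c"}), frozenset({"b", "d"})}): D[0, 2] + D[1, 3],
            frozenset({frozenset({"a", "d"}), frozenset({"b", "c"})}): D[0, 3] + D[1, 2],
        }
        best = min(pairings, key=pairings.get)
        assert best == frozenset({frozenset({"a", "b"}), frozenset({"c", "d"})})
        tree = neighbor_joining(DistanceMatrix(names, D))
        two_sided_splits = {frozenset(s) for s in tree.bipartitions() if len(s) == 2}
        assert {frozenset({"a", "b"}), frozenset({"c", "d"})} <= two_sided_splits

    def test_matches_reference_nj_implementation(self):
        # independent cross-check against scikit-bio on an additive matrix
        import skbio

        rng = np.random.default_rng(3)
        tree = random_tree(rng, 7)
        names, pd = tree.patristic_distances()
        ours = neighbor_joining(DistanceMatrix(names, pd))
        ref = skbio.tree.nj(skbio.DistanceMatrix(pd, ids=names))
        n1, d1 = ours.patristic_distances()
        ref_d = np.array(
            [[ref.find(a).distance(ref.find(b)) for b in n1] for a in n1]
        )
        assert np.allclose(d1, ref_d, atol=1e-8)

    def test_newick_round_trip_preserves_patristic_distances(self):
        rng = np.random.default_rng(1)
        tree = random_tree(rng, 6)
        back = PhyloTree.from_newick(tree.newick())
        n1, d1 = tree.patristic_distances()
        n2, d2 = back.patristic_distances()
        order = [n2.index(n) for n in n1]
        assert np.allclose(d2[np.ix_(order, order)], d1, atol=1e-8)


class TestIdenticalGroups:
    def test_cross_species_identical_sequences_grouped(self):
        seq = "ACGT" * 8
        groups = identical_allele_groups(
            {"A-1": seq, "B-1": seq, "A-2": "TTTT" * 8},
            {"A-1": "A", "B-1": "B", "A-2": "A"},
        )
        g = next(g for g in groups if "A-1" in g["members"])
        assert g["members"] == ["A-1", "B-1"]
        assert g["cross_species"] is True

    def test_trimmed_rule_matches_shorter_window(self):
        long_seq = "AAACCCGGGTTTACGTACGT"
        short = long_seq[3:18]  # a 15-nt window of the longer record
        groups = identical_allele_groups(
            {"long": long_seq, "short": short},
            {"long": "A", "short": "B"},
            overlap_rule="trimmed",
        )
        assert len(groups) == 1 and groups[0]["cross_species"]

    def test_full_rule_keeps_different_lengths_apart(self):
        long_seq = "AAACCCGGGTTT"
        groups = identical_allele_groups(
            {"long": long_seq, "short": long_seq[2:10]},
            {"long": "A", "short": "B"},
            overlap_rule="full",
        )
        assert len(groups) == 2

    def test_groups_form_a_partition(self):
        rng = np.random.default_rng(4)
        seqs = {}
        for i in range(20):
            seqs[f"x{i}"] = "".join(rng.choice(list("ACGT"), size=12))
        species = {k: ("A" if i % 2 else "B") for i, k in enumerate(seqs)}
        groups = identical_allele_groups(seqs, species, overlap_rule="trimmed")
        members = [m for g in groups for m in g["members"]]
        assert sorted(members) == sorted(seqs)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            identical_allele_groups({}, {})


def monophyly_oracle(tree: PhyloTree, species_of):
    """Independent check: a species is monophyletic iff removing some edge
    of the tree graph separates exactly its tips (networkx components)."""
    G = nx.Graph()
    counter = itertools.count()
    ids = {}

    def node_id(n):
        if id(n) not in ids:
            ids[id(n)] = next(counter)
        return ids[id(n)]

    tip_of = {}
    for n in tree.postorder():
        for ch in n.children:
            G.add_edge(node_id(n), node_id(ch))
        if n.is_tip():
            tip_of[node_id(n)] = n.name
    out = {}
    tips = set(tip_of.values())
    for sp in {species_of[t] for t in tips}:
        sp_tips = {t for t in tips if species_of[t] == sp}
        mono = len(sp_tips) == 1 or sp_tips == tips
        for e in list(G.edges):
            H = G.copy()
            H.remove_edge(*e)
            comps = list(nx.connected_components(H))
            for comp in comps:
                side = {tip_of[v] for v in comp if v in tip_of}
                if side == sp_tips:
                    mono = True
        out[sp] = mono
    return out


class TestMonophyly:
    def test_clean_separation_is_monophyletic(self):
        tree = PhyloTree.from_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        res = species_monophyly(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert all(v["monophyletic"] for v in res["per_species"].values())
        assert res["tsp_detected"] is False

    def test_interleaved_tips_flag_tsp(self):
        tree = PhyloTree.from_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        res = species_monophyly(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert not res["per_species"]["A"]["monophyletic"]
        assert not res["per_species"]["B"]["monophyletic"]
        assert res["tsp_detected"] is True

    def test_single_tip_species_is_vacuously_monophyletic(self):
        tree = PhyloTree.from_newick("((a1:1,a2:1):1,b1:2);")
        res = species_monophyly(tree, {"a1": "A", "a2": "A", "b1": "B"})
        assert res["per_species"]["B"]["monophyletic"]
        assert res["per_species"]["B"]["vacuous"]

    def test_agrees_with_edge_removal_oracle_on_random_trees(self):
        rng = np.random.default_rng(9)
        for trial in range(25):
            n = int(rng.integers(4, 9))
            tree = random_tree(rng, n)
            species_of = {
                f"t{i}": rng.choice(["A", "B", "C"]) for i in range(n)
            }
            if len(set(species_of.values())) < 2:
                species_of["t0"] = "A"
                species_of["t1"] = "B"
            res = species_monophyly(tree, species_of)
            oracle = monophyly_oracle(tree, species_of)
            for sp, flag in oracle.items():
                assert res["per_species"][sp]["monophyletic"] == flag, (
                    trial, sp, tree.newick(), species_of
                )
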