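"""Distances, neighbor joining, bootstrap supports and monophyly calls."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from plastibar.discriminate import (
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    evaluate_discrimination,
    is_group_monophyletic,
    neighbor_joining,
)
from plastibar.variation import AlignedMatrix, GroupAssignment


def random_additive_matrix(rng, n):
    """Random binary tree with positive branch lengths; returns
    (leaf names, path-distance matrix, set of non-trivial bipartitions)
    computed by plain graph traversal, independent of the NJ code."""
    leaves = [f"t{i}" for i in range(n)]
    nodes = {name: [] for name in leaves}  # adjacency: node -> [(nbr, w)]
    free = list(leaves)
    counter = itertools.count()
    while len(free) > 2:
        i, j = sorted(rng.choice(len(free), size=2, replace=False))
        a, b = free[j], free[i]
        new = f"i{next(counter)}"
        nodes[new] = []
        for x in (a, b):
            w = float(rng.uniform(0.05, 1.0))
            nodes[new].append((x, w))
            nodes[x].append((new, w))
        free = [x for x in free if x not in (a, b)] + [new]
    # connect the remaining free nodes
    if len(free) == 2:
        w = float(rng.uniform(0.05, 1.0))
        nodes[free[0]].append((free[1], w))
        nodes[free[1]].append((free[0], w))

    def dijkstra(src):
        dist = {src: 0.0}
        stack = [src]
        seen = {src}
        while stack:
            u = stack.pop()
            for v, w in nodes[u]:
                if v not in seen:
                    seen.add(v)
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    D = np.zeros((n, n))
    for i, a in enumerate(leaves):
        d = dijkstra(a)
        for j, b in enumerate(leaves):
            D[i, j] = d[b]
    D = (D + D.T) / 2  # remove float summation-order asymmetry

    # bipartitions by edge removal
    bips = set()
    for u in nodes:
        for v, _ in nodes[u]:
            if u < v:
                # leaves on u's side when edge (u,v) removed
                side = set()
                stack, seen = [u], {u, v}
                while stack:
                    x = stack.pop()
                    if x in leaves:
                        side.add(x)
                    for y, _ in nodes[x]:
                        if y not in seen:
                            seen.add(y)
                            stack.append(y)
                if 1 < len(side) < n - 1:
                    key = (
                        frozenset(side)
                        if leaves[0] not in side
                        else frozenset(leaves) - side
                    )
                    bips.add(key)
    return leaves, D, bips


class TestDistanceMatrix:
    def test_identical_sequences_zero(self):
        aln = AlignedMatrix(["a", "b", "c"], ["ACGTACGTAC"] * 3)
        dm = distance_matrix(aln, model="p")
        assert np.all(dm.values == 0)

    def test_p_distance_value(self):
        aln = AlignedMatrix(["a", "b"], ["AAAAAAAAAA", "AAAAAAAATT"])
        dm = distance_matrix(aln, model="p")
        assert dm.values[0, 1] == pytest.approx(0.2)

    def test_jc69_closed_form(self):
        aln = AlignedMatrix(["a", "b"], ["AAAAAAAAAA", "AAAAAAAATT"])
        dm = distance_matrix(aln, model="JC69")
        expected = -0.75 * math.log(1 - 0.8 / 3)
        assert dm.values[0, 1] == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.2326, abs=5e-4)

    def test_k2p_transitions_vs_transversions(self):
        # A<->G is a transition, A<->T a transversion; K2P corrects them
        # differently, p-distance sees them the same
        ts = AlignedMatrix(["a", "b"], ["A" * 10, "G" + "A" * 9])
        tv = AlignedMatrix(["a", "b"], ["A" * 10, "T" + "A" * 9])
        p_ts = distance_matrix(ts, model="p").values[0, 1]
        p_tv = distance_matrix(tv, model="p").values[0, 1]
        assert p_ts == pytest.approx(p_tv)
        k_ts = distance_matrix(ts, model="K2P").values[0, 1]
        k_tv = distance_matrix(tv, model="K2P").values[0, 1]
        assert k_ts != pytest.approx(k_tv)

    def test_saturation_capped_with_warning(self):
        aln = AlignedMatrix(
            ["a", "b", "c"], ["ACGTACGTACGT", "CATCCATCCATC", "ACGTACGTACGA"]
        )
        with pytest.warns(UserWarning, match="saturated"):
            dm = distance_matrix(aln, model="JC69")
        assert np.isfinite(dm.values).all()


class TestNeighborJoining:
    def test_three_taxon_pendant_lengths(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        tree = neighbor_joining(dm)
        lengths = tree.leaf_edge_lengths()
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        names = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(names, D))
        bips = tree.bipartitions()
        assert frozenset({"C", "D"}) in bips or frozenset({"A", "B"}) in bips
        path = tree.path_distances()
        assert np.allclose(path, D, atol=1e-9)

    def test_equal_distances_give_valid_tree(self):
        names = ["A", "B", "C", "D", "E"]
        D = np.ones((5, 5)) - np.eye(5)
        tree = neighbor_joining(DistanceMatrix(names, D))
        assert sorted(tree.leaf_names) == names
        # degree-3 internal structure: n-3 internal edges at most
        assert len(tree.bipartitions()) <= 2

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrices_recover_topology_and_lengths(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        names, D, true_bips = random_additive_matrix(rng, n)
        tree = neighbor_joining(DistanceMatrix(names, D))
        assert set(tree.bipartitions()) == true_bips
        assert np.allclose(tree.path_distances(), D, atol=1e-9)

    def test_matches_skbio_on_random_additive_input(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(99)
        names, D, true_bips = random_additive_matrix(rng, 7)
        ours = neighbor_joining(DistanceMatrix(names, D))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids=names))
        sk_bips = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(names) - 1:
                key = side if names[0] not in side else frozenset(names) - side
                sk_bips.add(key)
        assert set(ours.bipartitions()) == sk_bips == true_bips

    def test_newick_roundtrips_through_dendropy(self):
        rng = np.random.default_rng(5)
        names, D, true_bips = random_additive_matrix(rng, 6)
        tree = neighbor_joining(DistanceMatrix(names, D))
        dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        dt.encode_bipartitions()
        labels = {t.label for t in dt.taxon_namespace}
        assert labels == set(names)


class TestBootstrap:
    def _two_clade_alignment(self, n_fixed=20, seed=0):
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list("ACGT"), size=200))
        cols = rng.choice(200, size=n_fixed, replace=False)
        rows = []
        for i in range(8):
            chars = list(base)
            if i >= 4:
                for c in cols:
                    chars[c] = {"A": "T", "C": "G", "G": "C", "T": "A"}[chars[c]]
            # sprinkle private noise so rows are distinct
            pos = int(rng.integers(0, 200))
            if pos not in cols:
                chars[pos] = "ACGT"[(("ACGT".index(chars[pos]) + 1 + i) % 4)]
            rows.append("".join(chars))
        return AlignedMatrix([f"s{i}" for i in range(8)], rows)

    def test_overwhelming_signal_gives_high_support(self):
        aln = self._two_clade_alignment()
        st = bootstrap_support(aln, B=100, seed=1)
        key = frozenset({"s4", "s5", "s6", "s7"})
        assert st.supports.get(key, 0) >= 95

    def test_seed_stability_within_monte_carlo_error(self):
        aln = self._two_clade_alignment()
        key = frozenset({"s4", "s5", "s6", "s7"})
        s1 = bootstrap_support(aln, B=200, seed=1).supports.get(key, 0)
        s2 = bootstrap_support(aln, B=200, seed=2).supports.get(key, 0)
        assert abs(s1 - s2) < 10

    def test_single_replicate_supports_binary(self):
        aln = self._two_clade_alignment()
        st = bootstrap_support(aln, B=1, seed=3)
        assert set(st.supports.values()) <= {0.0, 100.0}

    def test_bitwise_reproducibility(self):
        aln = self._two_clade_alignment()
        a = bootstrap_support(aln, B=50, seed=7)
        b = bootstrap_support(aln, B=50, seed=7)
        assert a.supports == b.supports
        assert a.to_newick() == b.to_newick()

    def test_support_monotone_in_planted_signal(self):
        key = frozenset({"s4", "s5", "s6", "s7"})
        means = []
        for n_fixed in (0, 2, 10):
            vals = []
            for seed in range(5):
                aln = self._two_clade_alignment(n_fixed=n_fixed, seed=seed + 10)
                vals.append(
                    bootstrap_support(aln, B=200, seed=seed).supports.get(key, 0.0)
                )
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]


class TestMonophyly:
    def _tree(self):
        dm = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], dtype=float
            ),
        )
        return neighbor_joining(dm)

    def test_clade_is_monophyletic(self):
        mono, edge = is_group_monophyletic(self._tree(), ["A", "B"])
        assert mono and edge == frozenset({"C", "D"})

    def test_split_group_is_not(self):
        mono, _ = is_group_monophyletic(self._tree(), ["A", "C"])
        assert not mono

    def test_singleton_trivially_monophyletic(self):
        mono, edge = is_group_monophyletic(self._tree(), ["A"])
        assert mono and edge is None

    def test_full_leaf_set_rejected(self):
        with pytest.raises(ValueError):
            is_group_monophyletic(self._tree(), ["A", "B", "C", "D"])

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_dendropy_bipartition_check(self, seed):
        rng = np.random.default_rng(seed)
        names, D, _ = random_additive_matrix(rng, int(rng.integers(6, 12)))
        tree = neighbor_joining(DistanceMatrix(names, D))
        newick = tree.to_newick()
        dt = dendropy.Tree.get(data=newick, schema="newick")
        tns = dt.taxon_namespace
        dt.encode_bipartitions()
        for _ in range(8):
            k = int(rng.integers(1, len(names)))
            group = list(rng.choice(names, size=k, replace=False))
            if set(group) == set(names):
                continue
            mono, _ = is_group_monophyletic(tree, group)
            taxa = [tns.get_taxon(g) for g in group]
            if len(group) == 1:
                expected = True
            else:
                mrca = dt.mrca(taxa=taxa)
                expected = len(mrca.leaf_nodes()) == len(group)
                if not expected:
                    # unrooted: also accept the complement clade
                    comp = [t for t in tns if t not in taxa]
                    mrca_c = dt.mrca(taxa=comp)
                    expected = len(mrca_c.leaf_nodes()) == len(comp)
            assert mono == expected


class TestEvaluateDiscrimination:
    def test_planted_region_discriminates_all_groups(self, study_dataset):
        _, _, aln, groups, truth = study_dataset
        region = aln.slice_columns(*truth.barcode_core)
        result = evaluate_discrimination(region, groups, B=200, seed=2)
        multi = {g: v for g, v in result.verdicts.items() if v.n_samples > 1}
        assert len(multi) == 4
        assert all(v.success for v in multi.values())
        assert all(v.support > 50 for v in multi.values())

    def test_singleton_group_is_indeterminate(self, study_dataset):
        _, _, aln, groups, truth = study_dataset
        region = aln.slice_columns(*truth.barcode_core)
        result = evaluate_discrimination(region, groups, B=100, seed=2)
        v = result.verdicts["unplaced"]
        assert v.n_samples == 1 and v.monophyletic and v.success is None

    def test_permuted_labels_fail(self, study_dataset):
        _, _, aln, groups, truth = study_dataset
        region = aln.slice_columns(*truth.barcode_core)
        rng = np.random.default_rng(2)
        ids = list(groups.groups)
        labs = [groups.groups[s] for s in ids]
        permuted = GroupAssignment(dict(zip(ids, rng.permutation(labs))), set())
        result = evaluate_discrimination(region, permuted, B=200, seed=2)
        assert any(v.success is False for v in result.verdicts.values())

    def test_invariant_region_fails_all_multisample_groups(self):
        ids = ["a1", "a2", "b1", "b2"]
        aln = AlignedMatrix(ids, ["ACGT" * 50] * 4)
        groups = GroupAssignment({"a1": "G1", "a2": "G1", "b1": "G2", "b2": "G2"})
        result = evaluate_discrimination(aln, groups, B=50, seed=0)
        assert all(v.success is False for v in result.verdicts.values())
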