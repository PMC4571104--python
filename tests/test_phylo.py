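"""Tree I/O, covariance, TN93 distance and neighbor joining."""
import math

import dendropy
import numpy as np
import pytest

from phyloles.phylo import (
    Alignment,
    DistanceMatrix,
    NewickError,
    nj_tree,
    pairwise_tn93,
    parse_newick,
    patristic_distances,
    tn93_distance,
    tree_vcv,
    write_distance_matrix,
    read_distance_matrix,
    write_newick,
)
from phyloles.simulate import (
    FixtureConfig,
    simulate_alignment_tn93,
    simulate_yule_tree,
)

from conftest import random_yule_trees


class TestNewick:
    def test_minimal_two_tip_tree(self, cherry):
        assert set(cherry.tip_labels) == {"A", "B"}
        cov = tree_vcv(cherry)
        assert np.allclose(cov.tip_depths, [1.0, 1.0])

    def test_three_taxon_depths(self, three_taxon):
        cov = tree_vcv(three_taxon)
        depths = dict(zip(cov.labels, cov.tip_depths))
        assert depths["A"] == pytest.approx(2.0)
        assert depths["C"] == pytest.approx(2.0)

    def test_round_trip_34_taxa(self):
        tree = simulate_yule_tree(34, seed=5, depth=0.7, branch_jitter=0.2,
                                  ultrametric=False)
        text = write_newick(tree)
        back = parse_newick(text)
        assert set(back.tip_labels) == set(tree.tip_labels)
        c1, c2 = tree_vcv(tree), tree_vcv(back)
        order = [c2.labels.index(l) for l in c1.labels]
        assert np.allclose(c1.C, c2.C[np.ix_(order, order)], atol=1e-9)
        # second round trip is exact
        assert write_newick(parse_newick(text)) == text

    @pytest.mark.parametrize(
        "bad",
        ["((A:1,B:1):1;", "(A:1,A:1);", "(A:-1,B:1);", "(A:1);"],
        ids=["unbalanced", "duplicate-tip", "negative-length", "single-tip"],
    )
    def test_malformed_input_rejected(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad)

    def test_internal_support_labels_preserved_but_unused(self):
        tree = parse_newick("((A:1,B:1)95:1,C:2);")
        cov = tree_vcv(tree)
        assert np.isclose(cov.C[cov.labels.index("A"), cov.labels.index("B")], 1.0)


class TestVcv:
    def test_star_case(self, cherry):
        cov = tree_vcv(cherry)
        assert np.allclose(cov.C, np.eye(2))

    def test_three_taxon_entries(self, three_taxon):
        cov = tree_vcv(three_taxon)
        i = {l: k for k, l in enumerate(cov.labels)}
        assert cov.C[i["A"], i["B"]] == pytest.approx(1.0)
        assert cov.C[i["A"], i["A"]] == pytest.approx(2.0)
        assert cov.C[i["A"], i["C"]] == pytest.approx(0.0)

    def test_matches_brute_force_path_walk(self):
        """C_ij must equal the root-to-MRCA path sum found by explicitly
        walking tip-to-root paths."""
        for tree in random_yule_trees(10, 12, seed=3):
            cov = tree_vcv(tree)
            tips = tree.tip_indices()
            # root-to-node path per tip as an ordered list of nodes
            paths = {}
            for t in tips:
                path = [t]
                while tree.parent[path[-1]] >= 0:
                    path.append(tree.parent[path[-1]])
                paths[t] = list(reversed(path))
            depth = tree.depths()
            for a_i, a in enumerate(tips):
                for b_i, b in enumerate(tips):
                    shared = [u for u, v in zip(paths[a], paths[b]) if u == v]
                    assert cov.C[a_i, b_i] == pytest.approx(
                        depth[shared[-1]], abs=1e-12
                    )

    def test_psd_on_random_trees(self):
        for tree in random_yule_trees(200, 10, seed=9):
            ev = np.linalg.eigvalsh(tree_vcv(tree).C)
            assert ev.min() >= -1e-9


class TestPatristic:
    def test_trivial_distances(self, cherry, three_taxon):
        assert patristic_distances(cherry).get("A", "B") == pytest.approx(2.0)
        assert patristic_distances(three_taxon).get("A", "C") == pytest.approx(4.0)

    def test_identity_with_depths_and_graph_paths(self):
        """D = t_i + t_j - 2C_ij, cross-checked against shortest paths in
        the tree seen as a weighted graph (networkx oracle)."""
        import networkx as nx

        for tree in random_yule_trees(5, 10, seed=21):
            cov = tree_vcv(tree)
            D = patristic_distances(tree).D
            t = cov.tip_depths
            assert np.allclose(D, t[:, None] + t[None, :] - 2 * cov.C, atol=1e-12)
            G = nx.Graph()
            for node in range(tree.n_nodes):
                p = tree.parent[node]
                if p >= 0:
                    G.add_edge(node, p, weight=tree.lengths[node])
            tips = tree.tip_indices()
            for i, a in enumerate(tips):
                for j, b in enumerate(tips):
                    if i < j:
                        sp = nx.shortest_path_length(G, a, b, weight="weight")
                        assert D[i, j] == pytest.approx(sp, abs=1e-10)


def _equal_freq_pair(n_p1, n_p2, n_q, length=100):
    """Pair with identical base composition (25% each) and the given
    numbers of A<->G, C<->T and transversion differences (balanced
    swaps, so pooled frequencies stay exactly equal)."""
    assert n_p1 % 2 == n_p2 % 2 == n_q % 4 == 0
    a = list("A" * (length // 4) + "C" * (length // 4)
             + "G" * (length // 4) + "T" * (length // 4))
    b = a[:]
    qA, qC, qG, qT = 0, length // 4, length // 2, 3 * length // 4
    pos = {"A": qA, "C": qC, "G": qG, "T": qT}

    def swap(x, y, count):
        for k in range(count):
            b[pos[x] + k] = y
        pos[x] += count

    swap("A", "G", n_p1 // 2); swap("G", "A", n_p1 // 2)
    swap("C", "T", n_p2 // 2); swap("T", "C", n_p2 // 2)
    swap("A", "T", n_q // 4); swap("T", "A", n_q // 4)
    swap("C", "G", n_q // 4); swap("G", "C", n_q // 4)
    return "".join(a), "".join(b)


class TestTN93:
    def test_identical_sequences_zero(self):
        s = "ACGTACGTACGT" * 5
        res = tn93_distance(s, s)
        assert res.distance == 0.0 and res.defined

    def test_equal_frequency_reduction_to_two_parameter_formula(self):
        """With equal pooled base frequencies and P1 = P2, Q = 2 P1, the
        TN93 distance must collapse to the independently coded
        two-parameter (transition/transversion) closed form."""
        a, b = _equal_freq_pair(4, 4, 8)
        res = tn93_distance(a, b)
        assert (res.p1, res.p2, res.q) == pytest.approx((0.04, 0.04, 0.08))
        # two-parameter formula: P = total transition fraction, Q transversions
        P, Q = 0.08, 0.08
        oracle = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert res.distance == pytest.approx(oracle, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT-N"), size=80))
            b = "".join(rng.choice(list("ACGT-N"), size=80))
            ra = tn93_distance(a, b)
            rb = tn93_distance(b, a)
            if ra.defined:
                assert ra.distance == pytest.approx(rb.distance, abs=1e-12)

    def test_monotone_in_transversions(self):
        """Holding P1, P2 and frequencies fixed, the distance is
        non-decreasing in the transversion fraction."""
        prev = -np.inf
        for n_q in (0, 4, 8, 12, 16):
            a, b = _equal_freq_pair(4, 4, n_q, length=200)
            d = tn93_distance(a, b).distance
            assert d >= prev - 1e-12
            prev = d

    def test_gamma_correction_increases_distance(self):
        a, b = _equal_freq_pair(6, 6, 12, length=200)
        plain = tn93_distance(a, b).distance
        for shape in (0.2, 1.0, 5.0):
            assert tn93_distance(a, b, gamma_shape=shape).distance >= plain
        huge = tn93_distance(a, b, gamma_shape=1e6).distance
        assert huge == pytest.approx(plain, abs=1e-6)

    def test_saturation_flagged_not_nan_silently(self):
        a = "A" * 50 + "C" * 50
        b = "C" * 50 + "A" * 50  # 100% transversions
        res = tn93_distance(a, b)
        assert not res.defined
        assert math.isnan(res.distance)
        assert "saturated" in res.note

    def test_gap_handling_pairwise_vs_complete(self):
        aln = Alignment(
            labels=("x", "y", "z"),
            sequences=("ACGTACGTAA", "ACGTACGTAA", "-CGTACGTAA"),
        )
        pw = pairwise_tn93(aln, deletion="pairwise")
        comp = pairwise_tn93(aln, deletion="complete")
        assert pw.D[0, 1] == 0.0 and comp.D[0, 1] == 0.0
        assert np.all(comp.D >= 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            tn93_distance("ACGT", "ACG")

    def test_simulated_branch_length_recovered(self):
        """Distance on a pair simulated at known TN93 branch length t is
        within 3 bootstrap standard errors of t."""
        from phyloles.phylo import parse_newick

        t_true = 0.25
        tree = parse_newick(f"(A:{t_true/2},B:{t_true/2});")
        aln = simulate_alignment_tn93(
            tree, length=100_000, config=FixtureConfig(), seed=123
        )
        a, b = aln.sequences
        d = tn93_distance(a, b).distance
        # bootstrap SE over sites
        rng = np.random.default_rng(1)
        L = len(a)
        reps = []
        a_arr = np.frombuffer(a.encode(), dtype="S1")
        b_arr = np.frombuffer(b.encode(), dtype="S1")
        for _ in range(30):
            idx = rng.integers(L, size=L)
            reps.append(
                tn93_distance(
                    a_arr[idx].tobytes().decode(), b_arr[idx].tobytes().decode()
                ).distance
            )
        se = np.std(reps, ddof=1)
        assert abs(d - t_true) < 3 * se


class TestPairwise:
    def test_two_sequences(self):
        a, b = _equal_freq_pair(4, 4, 8)
        aln = Alignment(labels=("s1", "s2"), sequences=(a, b))
        dm = pairwise_tn93(aln)
        assert dm.D[0, 1] == pytest.approx(tn93_distance(a, b).distance)
        assert dm.D[0, 0] == 0.0

    def test_identical_sequences_all_zero(self):
        s = "ACGT" * 25
        aln = Alignment(labels=tuple(f"t{i}" for i in range(5)),
                        sequences=(s,) * 5)
        assert np.allclose(pairwise_tn93(aln).D, 0.0)

    def test_matches_looped_single_pairs(self):
        tree = simulate_yule_tree(10, seed=2, depth=0.4)
        aln = simulate_alignment_tn93(tree, length=500, seed=3,
                                      config=FixtureConfig())
        dm = pairwise_tn93(aln)
        for i in range(aln.n):
            for j in range(i + 1, aln.n):
                single = tn93_distance(aln.sequences[i], aln.sequences[j])
                assert dm.D[i, j] == pytest.approx(single.distance, abs=1e-12)

    def test_matrix_io_round_trip(self, tmp_path):
        D = np.array([[0.0, 0.1, np.nan], [0.1, 0.0, 0.2], [np.nan, 0.2, 0.0]])
        undef = np.isnan(D)
        dm = DistanceMatrix(labels=("a", "b", "c"), D=D, undefined=undef)
        path = tmp_path / "d.tsv"
        write_distance_matrix(dm, path)
        back = read_distance_matrix(path)
        assert back.labels == dm.labels
        assert np.allclose(back.D[~undef], D[~undef])
        assert bool(back.undefined[0, 2])


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        """Distances read off the tree ((A:2,B:3):1,(C:4,D:5)) must
        reproduce its topology and branch lengths."""
        labels = ("A", "B", "C", "D")
        D = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        tree = nj_tree(DistanceMatrix(labels=labels, D=D))
        assert tree.arbitrarily_rooted
        dm = patristic_distances(tree)
        order = [dm.labels.index(l) for l in labels]
        assert np.allclose(dm.D[np.ix_(order, order)], D, atol=1e-10)

    def test_three_taxon_unique_topology(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = nj_tree(DistanceMatrix(labels=("A", "B", "C"), D=D))
        assert set(tree.tip_labels) == {"A", "B", "C"}
        dm = patristic_distances(tree)
        order = [dm.labels.index(l) for l in "ABC"]
        assert np.allclose(dm.D[np.ix_(order, order)], D, atol=1e-10)

    def test_undefined_entries_rejected(self):
        D = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        dm = DistanceMatrix(labels=("a", "b", "c"), D=D, undefined=np.isnan(D))
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(dm)

    def test_recovers_topology_from_simulated_alignment(self):
        """NJ on TN93 distances from a long simulated alignment recovers
        the generating 8-taxon topology (Robinson-Foulds 0, dendropy
        oracle)."""
        true = simulate_yule_tree(8, seed=17, depth=0.5)
        aln = simulate_alignment_tn93(true, length=5000, seed=18,
                                      config=FixtureConfig())
        est = nj_tree(pairwise_tn93(aln))
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=write_newick(true), schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=write_newick(est), schema="newick",
                               taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == 0
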