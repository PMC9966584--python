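"""Fingerprint binning, Jaccard, from-scratch UPGMA and the strain cut."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probioscreen.data_model_io import ValidationError
from probioscreen.rapd_typing import (
    BandMatrix,
    RAPDLane,
    UndefinedSimilarityError,
    assign_strains,
    bin_fragments,
    jaccard_distance_matrix,
    jaccard_similarity,
    upgma,
    write_newick,
)


def brute_force_upgma(dist, labels):
    """Independent average-linkage oracle: clusters as frozensets, every
    inter-cluster distance recomputed from the ORIGINAL matrix each step."""
    d = np.asarray(dist, float)
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters = [(frozenset([lab]), 0.0, lab) for lab in labels]

    def avg(a, b):
        return float(np.mean([d[idx[i], idx[j]] for i in a for j in b]))

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                dv = avg(clusters[x][0], clusters[y][0])
                if best is None or dv < best[0] - 1e-15:
                    best = (dv, x, y)
        dv, x, y = best
        merged = (
            clusters[x][0] | clusters[y][0],
            dv / 2.0,
            (clusters[x], clusters[y]),
        )
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.insert(x, merged)
    return clusters[0]


def oracle_heights(node, out):
    """Flatten the oracle tree into {frozenset of members: height}."""
    members, height, payload = node
    if isinstance(payload, tuple):
        out[members] = height
        for child in payload:
            oracle_heights(child, out)
    return out


def tree_heights(node, out):
    if not node.is_leaf:
        out[frozenset(node.leaves)] = node.height
        for child in node.children:
            tree_heights(child, out)
    return out


def random_distance_matrix(rng, n):
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestBinning:
    def test_close_sizes_share_a_bin(self):
        lanes = [RAPDLane("a", (500.0,)), RAPDLane("b", (510.0,))]
        m = bin_fragments(lanes, rel_tolerance=0.05)
        assert len(m.bin_centers) == 1
        assert m.presence.tolist() == [[1], [1]]

    def test_distant_sizes_split(self):
        lanes = [RAPDLane("a", (500.0,)), RAPDLane("b", (600.0,))]
        m = bin_fragments(lanes, rel_tolerance=0.05)
        assert len(m.bin_centers) == 2

    def test_empty_lane_keeps_all_zero_row(self):
        lanes = [RAPDLane("a", (500.0,)), RAPDLane("failed", ())]
        m = bin_fragments(lanes)
        assert m.presence[1].sum() == 0
        assert m.isolate_ids == ["a", "failed"]

    def test_negative_size_rejected(self):
        with pytest.raises(ValidationError):
            RAPDLane("a", (-10.0,))

    def test_lane_contributes_at_most_one_presence_per_bin(self):
        lanes = [RAPDLane("a", (500.0, 505.0)), RAPDLane("b", (502.0,))]
        m = bin_fragments(lanes, rel_tolerance=0.05)
        assert m.presence.max() == 1


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 1, 0, 1), (1, 1, 0, 1), 1.0),
            ((1, 0, 0), (0, 1, 1), 0.0),
            ((1, 1, 0, 1), (1, 0, 1, 1), 0.5),
        ],
    )
    def test_examples(self, a, b, expected):
        assert jaccard_similarity(a, b) == expected

    def test_two_failed_lanes_undefined(self):
        with pytest.raises(UndefinedSimilarityError):
            jaccard_similarity((0, 0), (0, 0))


class TestUPGMA:
    def test_two_leaves(self):
        tree = upgma([[0, 0.4], [0.4, 0]], labels=["A", "B"])
        assert tree.root.height == pytest.approx(0.2)
        assert set(tree.root.leaves) == {"A", "B"}

    def test_three_leaf_hand_example(self):
        d = [[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]]
        tree = upgma(d, labels=["A", "B", "C"])
        heights = tree_heights(tree.root, {})
        assert heights[frozenset({"A", "B"})] == pytest.approx(0.1)
        assert heights[frozenset({"A", "B", "C"})] == pytest.approx(0.35)

    def test_matches_brute_force_oracle_up_to_n10(self, rng):
        for n in range(2, 11):
            for _ in range(5):
                d = random_distance_matrix(rng, n)
                labels = [f"L{i}" for i in range(n)]
                tree = upgma(d, labels=labels)
                got = tree_heights(tree.root, {})
                want = oracle_heights(brute_force_upgma(d, labels), {})
                assert set(got) == set(want)
                for members in want:
                    assert got[members] == pytest.approx(want[members], abs=1e-9)

    def test_matches_scipy_cophenetic(self, rng):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        d = random_distance_matrix(rng, 9)
        tree = upgma(d, labels=[str(i) for i in range(9)])
        heights = tree_heights(tree.root, {})

        def coph(i, j):
            for members, h in sorted(heights.items(), key=lambda kv: kv[1]):
                if str(i) in members and str(j) in members:
                    return 2 * h
            raise AssertionError

        expected = squareform(cophenet(linkage(squareform(d), method="average")))
        for i in range(9):
            for j in range(i + 1, 9):
                assert coph(i, j) == pytest.approx(expected[i, j], abs=1e-9)

    def test_ultrametric(self, rng):
        d = random_distance_matrix(rng, 8)
        tree = upgma(d)

        def check(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)

        check(tree.root)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            upgma([[0, 0.5], [0.4, 0]])


class TestAssignStrains:
    def test_identical_lanes_one_cluster(self):
        lanes = [RAPDLane(x, (100.0, 200.0, 300.0)) for x in "abcd"]
        m = bin_fragments(lanes)
        tree = upgma(jaccard_distance_matrix(m), labels=m.isolate_ids)
        assert len(set(assign_strains(tree).values())) == 1

    def test_exactly_85_percent_similarity_splits(self):
        # two leaves at distance 0.15 sit at exactly 85% tree similarity;
        # the rule is strictly "more than 85%"
        tree = upgma([[0, 0.15], [0.15, 0]], labels=["A", "B"])
        assert len(set(assign_strains(tree, 85.0).values())) == 2

    def test_just_above_85_percent_merges(self):
        tree = upgma([[0, 0.1499], [0.1499, 0]], labels=["A", "B"])
        assert len(set(assign_strains(tree, 85.0).values())) == 1

    def test_labels_in_first_appearance_order(self):
        lanes = [
            RAPDLane("iso1", (100.0, 200.0)),
            RAPDLane("iso2", (400.0, 800.0)),
            RAPDLane("iso3", (100.0, 200.0)),
        ]
        m = bin_fragments(lanes)
        tree = upgma(jaccard_distance_matrix(m), labels=m.isolate_ids)
        assignment = assign_strains(tree)
        assert assignment["iso1"] == "A"
        assert assignment["iso3"] == "A"
        assert assignment["iso2"] == "B"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_cutoff(self, seed):
        """Raising the cutoff can only split clusters, never merge them."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        d = random_distance_matrix(rng, n)
        tree = upgma(d)
        lo = assign_strains(tree, 60.0)
        hi = assign_strains(tree, 90.0)
        # every high-cutoff cluster is contained in a low-cutoff cluster
        for label in set(hi.values()):
            members = {k for k, v in hi.items() if v == label}
            assert len({lo[m] for m in members}) == 1


class TestNewick:
    def test_two_leaf_string(self):
        tree = upgma([[0, 0.4], [0.4, 0]], labels=["A", "B"])
        assert write_newick(tree) == "(A:0.2,B:0.2);"

    def test_single_leaf(self):
        tree = upgma([[0.0]], labels=["A"])
        assert write_newick(tree) == "A;"

    def test_round_trip_with_skbio(self, rng):
        from skbio import TreeNode
        from io import StringIO

        d = random_distance_matrix(rng, 7)
        labels = [f"L{i}" for i in range(7)]
        tree = upgma(d, labels=labels)
        parsed = TreeNode.read(StringIO(write_newick(tree)))
        assert {t.name for t in parsed.tips()} == set(labels)
        # cophenetic distances survive the round trip
        heights = tree_heights(tree.root, {})
        for members, h in heights.items():
            tips = sorted(members)[:2]
            if len(members) >= 2:
                lca_members = frozenset(
                    min(
                        (m for m in heights if set(tips) <= m),
                        key=len,
                    )
                )
                expected = 2 * heights[lca_members]
                got = parsed.find(tips[0]).distance(parsed.find(tips[1]))
                assert got == pytest.approx(expected, abs=1e-6)
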