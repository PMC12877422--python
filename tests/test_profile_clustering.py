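"""Presence matrices, Jaccard distances, merging, UPGMA and partition cuts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio.tree import TreeNode

from gagclust.family_clustering import greedy_cluster
from gagclust.profile_clustering import (
    DistanceMatrix,
    Partition,
    PresenceMatrix,
    build_presence_matrix,
    concat_presence_matrices,
    cut_dendrogram,
    hierarchical_cluster,
    jaccard_distances,
    merge_distance_matrices,
)
from gagclust.synthetic_data import random_protein

from conftest import make_record


def pm(family, species, rows):
    data = pd.DataFrame(
        rows, index=species,
        columns=[f"{family}:c{i+1}" for i in range(len(rows[0]))],
        dtype=np.int8,
    )
    return PresenceMatrix(family=family, data=data)


def dm(species, values):
    return DistanceMatrix(species=list(species), values=np.asarray(values, float))


class TestPresenceMatrix:
    def _clustering(self, rng, species_of_record):
        seq = {}
        records = []
        for rid, sp in species_of_record.items():
            group = rid[0]  # records sharing a first letter share a sequence
            seq.setdefault(group, random_protein(80, rng))
            records.append(make_record(rid, seq[group], species=sp))
        return greedy_cluster(records, 90)

    def test_membership_row(self, rng):
        clustering = self._clustering(rng, {"a1": "S1", "a2": "S2"})
        matrix = build_presence_matrix(clustering, ["S1", "S2", "S3"])
        assert matrix.data.to_numpy().tolist() == [[1], [1], [0]]

    def test_paralogs_stay_binary(self, rng):
        clustering = self._clustering(rng, {"a1": "S1", "a2": "S1"})
        matrix = build_presence_matrix(clustering, ["S1"])
        assert matrix.data.to_numpy().tolist() == [[1]]

    def test_two_cluster_pattern(self, rng):
        clustering = self._clustering(
            rng, {"a1": "S1", "a2": "S2", "b1": "S1"}
        )
        matrix = build_presence_matrix(clustering, ["S1", "S2"])
        assert sorted(matrix.data.loc["S1"]) == [1, 1]
        assert sorted(matrix.data.loc["S2"]) == [0, 1]

    def test_unknown_species_listed_in_error(self, rng):
        clustering = self._clustering(rng, {"a1": "S1", "a2": "Sx"})
        with pytest.raises(ValueError, match="Sx"):
            build_presence_matrix(clustering, ["S1"])


class TestJaccard:
    def test_identical_rows_distance_zero(self):
        d = jaccard_distances(pm("F", ["A", "B"], [[1, 1, 0], [1, 1, 0]]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_rows_distance_one(self):
        d = jaccard_distances(pm("F", ["A", "B"], [[1, 0], [0, 1]]))
        assert d.values[0, 1] == 1.0

    def test_partial_overlap(self):
        # intersection 1, union 3 -> 1 - 1/3
        d = jaccard_distances(pm("F", ["A", "B"], [[1, 1, 0], [1, 0, 1]]))
        assert d.values[0, 1] == pytest.approx(2 / 3)

    def test_empty_profile_conventions(self):
        d = jaccard_distances(pm("F", ["A", "B", "C"], [[0, 0], [0, 0], [1, 0]]))
        assert d.values[0, 1] == 0.0  # empty vs empty
        assert d.values[0, 2] == 1.0  # empty vs non-empty

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.lists(st.integers(0, 1), min_size=6, max_size=6),
            min_size=3, max_size=3,
        )
    )
    def test_triangle_inequality(self, rows):
        d = jaccard_distances(pm("F", ["A", "B", "C"], rows)).values
        for i, j, k in [(0, 1, 2), (0, 2, 1), (1, 2, 0)]:
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestMerge:
    def test_single_matrix_unchanged(self):
        m = dm("AB", [[0, 0.4], [0.4, 0]])
        merged = merge_distance_matrices([m])
        assert np.allclose(merged.values, m.values)

    def test_elementwise_mean(self):
        m1 = dm("AB", [[0, 0.2], [0.2, 0]])
        m2 = dm("AB", [[0, 0.4], [0.4, 0]])
        assert merge_distance_matrices([m1, m2]).values[0, 1] == pytest.approx(0.3)

    def test_degenerate_weights_select_first(self):
        m1 = dm("AB", [[0, 0.2], [0.2, 0]])
        m2 = dm("AB", [[0, 0.8], [0.8, 0]])
        merged = merge_distance_matrices([m1, m2], weights=[1, 0])
        assert np.allclose(merged.values, m1.values)

    def test_merge_of_identical_is_identity(self):
        m = dm("ABC", [[0, 0.1, 0.5], [0.1, 0, 0.7], [0.5, 0.7, 0]])
        merged = merge_distance_matrices([m, m, m])
        assert np.allclose(merged.values, m.values)

    def test_species_order_mismatch_rejected(self):
        m1 = dm("AB", [[0, 0.2], [0.2, 0]])
        m2 = dm("BA", [[0, 0.2], [0.2, 0]])
        with pytest.raises(ValueError, match="species order"):
            merge_distance_matrices([m1, m2])

    def test_concat_mode_shares_species_order(self):
        a = pm("F1", ["A", "B"], [[1, 0], [0, 1]])
        b = pm("F2", ["A", "B"], [[1], [1]])
        cat = concat_presence_matrices([a, b])
        assert cat.data.shape == (2, 3)
        assert jaccard_distances(cat).values[0, 1] == pytest.approx(2 / 3)


class TestHierarchical:
    def test_two_species_single_merge(self):
        d = dm("AB", [[0, 0.37], [0.37, 0]])
        dendro = hierarchical_cluster(d)
        assert dendro.linkage_matrix.shape == (1, 4)
        assert dendro.merge_heights[0] == pytest.approx(0.37)

    def test_three_species_upgma_hand_example(self):
        d = dm("ABC", [[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]])
        dendro = hierarchical_cluster(d, "average")
        assert dendro.merge_heights[0] == pytest.approx(0.1)
        assert dendro.merge_heights[1] == pytest.approx(0.8)
        part = cut_dendrogram(dendro, 2)
        assert part.assignment["A"] == part.assignment["B"]
        assert part.assignment["C"] != part.assignment["A"]

    def test_species_order_permutation_gives_isomorphic_partition(self):
        values = np.array(
            [[0, 0.1, 0.8, 0.7],
             [0.1, 0, 0.75, 0.8],
             [0.8, 0.75, 0, 0.2],
             [0.7, 0.8, 0.2, 0]]
        )
        d1 = dm("ABCD", values)
        perm = [2, 0, 3, 1]
        d2 = dm(
            [list("ABCD")[i] for i in perm], values[np.ix_(perm, perm)]
        )
        p1 = cut_dendrogram(hierarchical_cluster(d1), 2)
        p2 = cut_dendrogram(hierarchical_cluster(d2), 2)
        groups1 = {frozenset(p1.members(l)) for l in p1.labels}
        groups2 = {frozenset(p2.members(l)) for l in p2.labels}
        assert groups1 == groups2

    def test_ward_rejected(self):
        d = dm("AB", [[0, 0.5], [0.5, 0]])
        with pytest.raises(ValueError, match="ward"):
            hierarchical_cluster(d, "ward")

    def test_fewer_than_two_species_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(dm("A", [[0.0]]))

    def test_newick_round_trips_with_heights(self):
        d = dm("ABC", [[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]])
        tree = TreeNode.read([hierarchical_cluster(d).to_newick()])
        assert sorted(t.name for t in tree.tips()) == ["A", "B", "C"]


class TestCut:
    @pytest.fixture
    def dendro(self):
        d = dm(
            "ABCD",
            [[0, 0.1, 0.8, 0.7], [0.1, 0, 0.75, 0.8],
             [0.8, 0.75, 0, 0.2], [0.7, 0.8, 0.2, 0]],
        )
        return hierarchical_cluster(d)

    def test_k_equals_n_gives_singletons(self, dendro):
        part = cut_dendrogram(dendro, 4)
        assert len(set(part.assignment.values())) == 4

    def test_k_one_gives_single_cluster(self, dendro):
        part = cut_dendrogram(dendro, 1)
        assert set(part.assignment.values()) == {"C1"}

    def test_labels_follow_leaf_order(self, dendro):
        part = cut_dendrogram(dendro, 2)
        first_leaf = dendro.leaf_order[0]
        assert part.assignment[first_leaf] == "C1"
        assert sorted(set(part.assignment.values())) == ["C1", "C2"]

    def test_k_out_of_range_rejected(self, dendro):
        for k in (0, 5):
            with pytest.raises(ValueError):
                cut_dendrogram(dendro, k)


class TestEndToEnd:
    def test_two_block_gene_content_recovered_at_k2(self):
        species = [f"S{i}" for i in range(8)]
        rows = [[1, 1, 0, 0] if i % 2 == 0 else [0, 0, 1, 1] for i in range(8)]
        d = jaccard_distances(pm("F", species, rows))
        part = cut_dendrogram(hierarchical_cluster(d), 2)
        blocks = {frozenset(part.members(l)) for l in part.labels}
        assert blocks == {
            frozenset(species[0::2]), frozenset(species[1::2])
        }

    def test_distance_matrix_validation(self):
        with pytest.raises(ValueError):
            dm("AB", [[0, 0.5], [0.6, 0]])  # asymmetric
        with pytest.raises(ValueError):
            dm("AB", [[0, 1.5], [1.5, 0]])  # out of range
        with pytest.raises(ValueError):
            dm("AB", [[0.2, 0.5], [0.5, 0]])  # nonzero diagonal

    def test_partition_tsv_round_trip(self, tmp_path):
        part = Partition({"A": "C1", "B": "C2"})
        p = tmp_path / "part.tsv"
        part.to_tsv(p)
        assert Partition.from_tsv(p).assignment == part.assignment
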