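"""Levene-gated recursive clustering: linkage, recursion, planted recovery."""

import numpy as np
import pytest
from scipy.cluster import hierarchy

from axoclass.class_discovery import (
    SplitConfig,
    average_linkage_tree,
    discover_classes,
)
from axoclass.projection_null import SwapConfig
from axoclass.reconstruction_io import ProjectionMatrix
from axoclass.synthetic_fixtures import (
    ClassSpec,
    CohortSpec,
    generate_cohort,
    motor_l6_like_spec,
    presubiculum_like_spec,
    single_class_spec,
)


def brute_force_average_linkage(D):
    """Naive agglomeration oracle: repeatedly merge the closest pair under
    average linkage, lowest-index tie-break."""
    clusters = {i: [i] for i in range(len(D))}
    merges = []
    next_id = len(D)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([[D[i, j] for j in clusters[b]] for i in clusters[a]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestAverageLinkage:
    def test_two_items_single_merge(self):
        Z = average_linkage_tree(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(3.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            n = 6
            X = rng.normal(size=(n, 3))
            D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
            Z = average_linkage_tree(D)
            oracle = brute_force_average_linkage(D)
            assert np.allclose(sorted(Z[:, 2]), sorted(m[2] for m in oracle))

    def test_tight_groups_split_first(self):
        # two groups of 3: within 5 deg, across 80 deg
        D = np.full((6, 6), 80.0)
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    D[i, j] = 0.0 if i == j else 5.0
        Z = average_linkage_tree(D)
        root = hierarchy.to_tree(Z)
        left = set(root.get_left().pre_order(lambda l: l.id))
        assert left in ({0, 1, 2}, {3, 4, 5})

    def test_equidistant_triplet_equal_heights(self):
        D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        Z = average_linkage_tree(D)
        assert np.allclose(Z[:, 2], 1.0)

    def test_nan_rejected(self):
        D = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="NaN"):
            average_linkage_tree(D)


def _disjoint_two_class(n_a=20, n_b=20, seed=0):
    cols = [(f"P{j}", "ipsi") for j in range(6)]
    pa = np.array([0.5, 0.3, 0.2, 0, 0, 0])
    pb = np.array([0, 0, 0, 0.4, 0.4, 0.2])
    return CohortSpec(
        classes=[
            ClassSpec(n_neurons=n_a, profile=pa, label="a"),
            ClassSpec(n_neurons=n_b, profile=pb, label="b"),
        ],
        columns=cols,
        seed=seed,
    )


class TestDiscoverClasses:
    def test_two_planted_classes_recovered_exactly(self):
        m, truth = generate_cohort(_disjoint_two_class(seed=5))
        tree = discover_classes(m, SplitConfig(swap_cfg=SwapConfig(seed=5)))
        assert tree.n_classes == 2
        recovered = tree.assignments()
        for label, members in tree.classes.items():
            true_of_members = {truth[m.neuron_ids.index(nid)] for nid in members}
            assert len(true_of_members) == 1  # classes are pure
        assert sorted(tree.class_sizes) == [20, 20]

    def test_single_class_rarely_split(self):
        # type-I behavior: a homogeneous multinomial cohort stays one class
        splits = 0
        n_runs = 25
        for s in range(n_runs):
            m, _ = generate_cohort(single_class_spec(n_neurons=40, seed=s))
            tree = discover_classes(m, SplitConfig(swap_cfg=SwapConfig(seed=1000 + s)))
            splits += tree.n_classes > 1
        assert splits / n_runs <= 0.10  # 1 class in >= 90% of runs

    def test_motor_like_cohort_two_classes_21_31(self):
        m, _ = generate_cohort(motor_l6_like_spec(seed=3))
        tree = discover_classes(m, SplitConfig(swap_cfg=SwapConfig(seed=3)))
        assert tree.n_classes == 2
        assert sorted(tree.class_sizes) == [21, 31]

    def test_presubiculum_like_cohort_five_classes(self):
        m, truth = generate_cohort(presubiculum_like_spec(seed=7))
        tree = discover_classes(m, SplitConfig(swap_cfg=SwapConfig(seed=7)))
        assert tree.n_classes == 5
        assert sorted(tree.class_sizes) == [3, 6, 19, 27, 38]
        # membership matches the planted labels exactly
        for members in tree.classes.values():
            true_of_members = {truth[m.neuron_ids.index(nid)] for nid in members}
            assert len(true_of_members) == 1

    def test_reproducible_under_fixed_seed(self):
        m, _ = generate_cohort(_disjoint_two_class(seed=9))
        t1 = discover_classes(m, SplitConfig(swap_cfg=SwapConfig(seed=11)))
        t2 = discover_classes(m, SplitConfig(swap_cfg=SwapConfig(seed=11)))
        assert t1.classes == t2.classes
        assert np.array_equal(t1.linkage_matrix, t2.linkage_matrix)

    def test_every_neuron_assigned_once(self):
        m, _ = generate_cohort(presubiculum_like_spec(seed=2))
        tree = discover_classes(m, SplitConfig(swap_cfg=SwapConfig(seed=2)))
        assigned = [nid for members in tree.classes.values() for nid in members]
        assert sorted(assigned) == sorted(tree.neuron_ids)
        assert len(assigned) == len(set(assigned))

    def test_node_tests_computed_per_subtree(self):
        # sub-split independence: each tested node records its own subtree size
        m, _ = generate_cohort(_disjoint_two_class(seed=1))
        tree = discover_classes(m, SplitConfig(swap_cfg=SwapConfig(seed=1)))
        tested = [n for n in tree.nodes.values() if n.test is not None]
        sizes = sorted(len(n.neuron_ids) for n in tested)
        assert sizes[-1] == 40  # root over all neurons
        assert all(s < 40 for s in sizes[:-1])  # children tested on their own rows

    def test_class_labels_follow_dendrogram_order_with_sizes(self):
        m, _ = generate_cohort(_disjoint_two_class(n_a=15, n_b=25, seed=4))
        tree = discover_classes(m, SplitConfig(swap_cfg=SwapConfig(seed=4)))
        labels = list(tree.classes)
        assert [l[0] for l in labels] == ["A", "B"]
        for label, members in tree.classes.items():
            assert label == f"{label[0]}{len(members)}"

    def test_zero_count_neurons_reported_unassigned(self):
        m, _ = generate_cohort(_disjoint_two_class(seed=6))
        counts = m.counts.copy()
        counts[0] = 0
        m2 = ProjectionMatrix(m.neuron_ids, m.columns, counts)
        tree = discover_classes(m2, SplitConfig(swap_cfg=SwapConfig(seed=6)))
        assert tree.unassigned == [m.neuron_ids[0]]
        assert m.neuron_ids[0] not in tree.assignments()

    def test_too_few_neurons_rejected(self):
        m = ProjectionMatrix(["a", "b"], [("P", "both"), ("Q", "both")],
                             np.array([[1, 2], [3, 4]]))
        with pytest.raises(ValueError, match="at least"):
            discover_classes(m)
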