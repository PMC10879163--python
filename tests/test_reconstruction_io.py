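"""Reconstruction parsing, validation and projection-matrix tabulation."""

import json

import numpy as np
import pytest

from axoclass.reconstruction_io import (
    CONTRA,
    IPSI,
    NeuronReconstruction,
    ProjectionMatrix,
    ReconstructionError,
    aggregate_parcels,
    assign_hemispheres,
    build_projection_matrix,
    parse_projection_json,
    parse_swc,
    write_swc,
)
from axoclass.synthetic_fixtures import (
    TreeSpec,
    generate_cohort,
    generate_tree,
    single_class_spec,
)
from tests.conftest import BRANCHED_SWC, CHAIN_SWC


class TestParseSwc:
    def test_minimal_chain(self, chain_neuron):
        assert chain_neuron.n_points == 3
        assert chain_neuron.points[chain_neuron.root_id].structure == "soma"
        assert [p.structure for p in chain_neuron.axon_points()] == ["axon", "axon"]

    def test_point_count_equals_data_lines(self, branched_neuron):
        assert branched_neuron.n_points == len(
            [l for l in BRANCHED_SWC.splitlines() if not l.startswith("#")]
        )

    def test_leaf_count_by_traversal(self, branched_neuron):
        # oracle: leaves are points that never appear as a parent
        parents = {
            p.parent_id for p in branched_neuron.points.values() if p.parent_id
        }
        oracle_leaves = set(branched_neuron.points) - parents
        assert set(branched_neuron.leaves()) == oracle_leaves
        assert len(oracle_leaves) == 3

    @pytest.mark.parametrize(
        "bad,fragment",
        [
            ("1 1 0 0 0 1 -1\n2 2 0 0 1 1 99\n", "dangling parent"),
            ("1 1 0 0 0 1 -1\n2 1 5 5 5 1 -1\n", "one root"),
            ("1 1 0 0 0 1 -1\n2 2 0 0 1 1 3\n3 2 0 0 2 1 2\n", "not reachable"),
            ("1 1 0 0 zzz 1 -1\n", "malformed number"),
            ("1 1 0 0 0 1\n", "7 columns"),
            ("", "empty"),
        ],
    )
    def test_structural_errors(self, bad, fragment):
        with pytest.raises(ReconstructionError, match=fragment):
            parse_swc(bad)

    @pytest.mark.parametrize("seed", [0, 7, 23])
    def test_roundtrip_bit_exact(self, seed):
        tree = generate_tree(TreeSpec(n_bifurcations=5, seed=seed))
        back = parse_swc(write_swc(tree), neuron_id=tree.neuron_id)
        assert set(back.points) == set(tree.points)
        for pid, p in tree.points.items():
            q = back.points[pid]
            assert np.array_equal(p.xyz, q.xyz)
            assert p.parent_id == q.parent_id
            assert p.structure == q.structure


def _json_doc(points_per_parcel):
    """Single-neuron MouseLight-style doc: parcel -> number of axon points."""
    axon, n = [], 0
    for parcel, count in points_per_parcel.items():
        for _ in range(count):
            n += 1
            axon.append(
                {
                    "sampleNumber": n,
                    "x": float(n),
                    "y": 0.0,
                    "z": 0.0,
                    "parentNumber": -1 if n == 1 else n - 1,
                    "allenLabel": parcel,
                }
            )
    return {
        "neurons": [
            {"idString": "AA0001", "soma": {"x": 0, "y": 0, "z": 0}, "axon": axon}
        ]
    }


class TestParseProjectionJson:
    def test_points_and_parcels(self):
        doc = _json_doc({"LEC": 3, "Sub": 2})
        (neuron,) = parse_projection_json(json.dumps(doc))
        assert len(neuron.axon_points()) == 5
        assert {p.parcel for p in neuron.axon_points()} == {"LEC", "Sub"}

    def test_missing_soma_is_error(self):
        doc = {"neurons": [{"idString": "x", "axon": []}]}
        with pytest.raises(ReconstructionError, match="soma"):
            parse_projection_json(json.dumps(doc))

    def test_missing_parcel_annotation_is_error(self):
        doc = _json_doc({"LEC": 1})
        del doc["neurons"][0]["axon"][0]["allenLabel"]
        with pytest.raises(ReconstructionError, match="parcel"):
            parse_projection_json(json.dumps(doc))

    def test_nine_invaded_parcels(self):
        # one neuron whose axon spans 9 regions, mimicking a brain-wide arbor
        doc = _json_doc({f"R{i}": i + 1 for i in range(9)})
        (neuron,) = parse_projection_json(json.dumps(doc))
        assert len({p.parcel for p in neuron.axon_points()}) == 9


def _annotated(neuron, parcels):
    """Assign parcels cyclically to a tree's axon points (test helper)."""
    pts = neuron.axon_points()
    for i, p in enumerate(pts):
        p.parcel = parcels[i % len(parcels)]
    return neuron


class TestBuildProjectionMatrix:
    def test_single_parcel_counts(self, chain_neuron):
        _annotated(chain_neuron, ["P"])
        m = build_projection_matrix([chain_neuron], ["P"], hemisphere_split=False)
        assert m.counts.tolist() == [[2]]

    def test_disjoint_parcels_give_diagonal(self, chain_neuron, branched_neuron):
        _annotated(chain_neuron, ["P"])
        _annotated(branched_neuron, ["Q"])
        m = build_projection_matrix(
            [chain_neuron, branched_neuron], ["P", "Q"], hemisphere_split=False
        )
        assert m.counts[0, 1] == 0 and m.counts[1, 0] == 0
        assert m.counts[0, 0] == 2 and m.counts[1, 1] == 6

    def test_row_sums_match_flat_recount(self):
        trees = [
            _annotated(generate_tree(TreeSpec(n_bifurcations=4, seed=s)), ["A", "B"])
            for s in range(10)
        ]
        m = build_projection_matrix(trees, ["A", "B"], hemisphere_split=False)
        for row, tree in zip(m.row_sums(), trees):
            assert row == sum(
                1 for p in tree.points.values() if p.structure == "axon"
            )

    def test_hemisphere_columns_sum_to_unsplit(self, branched_neuron):
        _annotated(branched_neuron, ["P"])
        assign_hemispheres(branched_neuron, midline=0.0, axis=0)
        split = build_projection_matrix([branched_neuron], ["P"], hemisphere_split=True)
        merged = build_projection_matrix(
            [branched_neuron], ["P"], hemisphere_split=False
        )
        assert split.row_sums().tolist() == merged.row_sums().tolist()
        assert split.counts.sum() == merged.counts.sum()
        # both hemispheres are populated: the tree straddles the midline
        assert (split.counts > 0).sum() == 2

    def test_out_of_scope_points_dropped(self, branched_neuron):
        _annotated(branched_neuron, ["P", "X"])
        m = build_projection_matrix([branched_neuron], ["P"], hemisphere_split=False)
        in_scope = sum(1 for p in branched_neuron.axon_points() if p.parcel == "P")
        assert m.counts.sum() == in_scope

    def test_source_parcel_excluded_by_default(self, branched_neuron):
        _annotated(branched_neuron, ["SRC", "P"])
        m = build_projection_matrix(
            [branched_neuron], ["SRC", "P"], source_parcel="SRC", hemisphere_split=False
        )
        assert [p for p, _ in m.columns] == ["P"]
        m2 = build_projection_matrix(
            [branched_neuron],
            ["SRC", "P"],
            source_parcel="SRC",
            include_source=True,
            hemisphere_split=False,
        )
        assert [p for p, _ in m2.columns] == ["SRC", "P"]

    def test_empty_parcel_set_rejected(self, chain_neuron):
        with pytest.raises(ValueError):
            build_projection_matrix([chain_neuron], [])


class TestProjectionMatrix:
    def test_csv_roundtrip(self, tmp_path):
        m, _ = generate_cohort(single_class_spec(n_neurons=5, seed=3))
        path = tmp_path / "m.csv"
        m.to_csv(path)
        back = ProjectionMatrix.from_csv(path)
        assert back.neuron_ids == m.neuron_ids
        assert back.columns == m.columns
        assert np.array_equal(back.counts, m.counts)

    def test_aggregation_preserves_totals(self):
        m, _ = generate_cohort(single_class_spec(n_neurons=6, n_columns=6, seed=5))
        grouping = {"P0": "G", "P1": "G", "P2": "H"}
        agg = aggregate_parcels(m, grouping)
        assert agg.counts.sum() == m.counts.sum()
        assert np.array_equal(agg.row_sums(), m.row_sums())
        g_col = agg.columns.index(("G", IPSI))
        p01 = [m.columns.index(("P0", IPSI)), m.columns.index(("P1", IPSI))]
        assert np.array_equal(agg.counts[:, g_col], m.counts[:, p01].sum(axis=1))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ProjectionMatrix(["a"], [("P", "both")], np.array([[-1]]))


def test_assign_hemispheres_relative_to_soma():
    pts = parse_swc(CHAIN_SWC)
    # soma at x=0; put one axon point across a midline at x=-1
    pts.points[3].xyz = np.array([-3.0, 0.0, 2.0])
    assign_hemispheres(pts, midline=-1.0, axis=0)
    assert pts.points[2].hemisphere == IPSI
    assert pts.points[3].hemisphere == CONTRA
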