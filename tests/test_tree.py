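"""IRTree composition: decomposition tables, likelihood factorization,
and the two named model builders."""

import numpy as np
import pytest

from dimirtree import dimirt as dm
from dimirtree import tree as tr
from dimirtree import synthesis as sy


class TestDecomposition:
    @pytest.mark.parametrize(
        "y, expected",
        [(0, [0, tr.MISSING, 1]), (1, [0, tr.MISSING, 0]),
         (2, [1, 0, tr.MISSING]), (3, [1, 1, tr.MISSING])],
    )
    def test_four_point_table(self, y, expected):
        mapping = tr.build_model_ideal_ers(4, 1).mapping
        np.testing.assert_array_equal(tr.decompose_response(y, mapping), expected)

    @pytest.mark.parametrize(
        "y, expected",
        [(0, [0, tr.MISSING, 2]), (2, [0, tr.MISSING, 0]),
         (3, [1, 0, tr.MISSING]), (5, [1, 2, tr.MISSING])],
    )
    def test_six_point_table(self, y, expected):
        mapping = tr.build_model_ideal_ers(6, 1).mapping
        np.testing.assert_array_equal(tr.decompose_response(y, mapping), expected)

    def test_out_of_range_category(self):
        mapping = tr.build_model_ideal_ers(6, 1).mapping
        with pytest.raises(ValueError, match="out of range"):
            tr.decompose_response(6, mapping)

    def test_mapping_csv_roundtrip(self, tmp_path):
        mapping = tr.build_model_ideal_ers(6, 1).mapping
        path = tmp_path / "mapping.csv"
        mapping.to_csv(path)
        text = path.read_text()
        assert "-" in text  # missing-by-design cells serialize as dashes
        back = tr.TreeMapping.from_csv(path)
        np.testing.assert_array_equal(back.table, mapping.table)
        assert back.node_names == mapping.node_names


class TestTreeProbability:
    def test_categories_sum_to_one(self, small_idi_dataset):
        ds = small_idi_dataset
        traits = {"theta": 0.4, "eta": -0.8}
        total = sum(
            tr.tree_response_probability(y, traits, ds.spec, 2, ds.params)
            for y in range(6)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_product_of_aggregated_node_probabilities(self, small_idi_dataset, rng):
        """Brute-force oracle: per node, aggregate the GPCM/GGUM process
        distributions at probability level, then multiply along the
        category's path.  This exercises a fully independent compute path
        through the generation-side thresholds."""
        ds = small_idi_dataset
        items = ds.items
        for _ in range(20):
            v = {"theta": float(rng.normal()), "eta": float(rng.normal())}
            i = int(rng.integers(0, ds.design.I))
            ers = dm.ProcessSpec("dominance", "eta", np.arange(3.0), items["alpha"][i])
            trait_a = dm.ProcessSpec("ideal_point", "theta", np.arange(3.0),
                                     items["lambda2"][i], items["delta"][i])
            trait_d = dm.ProcessSpec("ideal_point", "theta", np.arange(2.0, -1.0, -1.0),
                                     items["lambda2"][i], items["delta"][i])
            agree = dm.ProcessSpec("ideal_point", "theta", np.arange(2.0),
                                   items["lambda1"][i], items["delta"][i])
            node_dists = [
                dm.process_distribution(v, agree, [items["xi1_1"][i]]).p,
                dm.aggregate_probability_form([
                    dm.process_distribution(v, ers, [items["beta1_1"][i], items["beta1_2"][i]]),
                    dm.process_distribution(v, trait_a, [items["xi2_1"][i], items["xi2_2"][i]]),
                ]).p,
                dm.aggregate_probability_form([
                    dm.process_distribution(v, ers, [items["beta2_1"][i], items["beta2_2"][i]]),
                    dm.process_distribution(v, trait_d, [items["xi3_1"][i], items["xi3_2"][i]]),
                ]).p,
            ]
            for y in range(6):
                path = tr.decompose_response(y, ds.spec.mapping)
                oracle = np.prod([node_dists[h][x] for h, x in enumerate(path) if x != tr.MISSING])
                got = tr.tree_response_probability(y, v, ds.spec, i, ds.params)
                assert got == pytest.approx(oracle, rel=1e-10)

    def test_branch_elimination(self, small_idi_dataset):
        # forcing the agreement node to X1=1 kills the disagreement branch
        ds = small_idi_dataset
        params = dict(ds.params)
        params["tau1[0,1]"] = -200.0  # p(X1=1) -> 1
        p_low = sum(
            tr.tree_response_probability(y, {"theta": 0.0, "eta": 0.0}, ds.spec, 0, params)
            for y in (0, 1, 2)
        )
        assert p_low == pytest.approx(0.0, abs=1e-60)


class TestIdealErsBuilder:
    def test_six_point_structure(self):
        spec = tr.build_model_ideal_ers(6, 2)
        assert spec.mapping.n_nodes == 3
        assert spec.mapping.node_n_categories == (2, 3, 3)
        agree, inta, intd = spec.nodes[1]
        assert [p.kind for p in agree.processes] == ["ideal_point"]
        assert [p.kind for p in inta.processes] == ["dominance", "ideal_point"]
        np.testing.assert_array_equal(intd.processes[1].weights, [2.0, 1.0, 0.0])
        # shared parameters: ERS discrimination and trait intensity
        # discrimination across the intensity nodes, location with agreement
        assert inta.processes[0].discrimination == intd.processes[0].discrimination
        assert inta.processes[1].discrimination == intd.processes[1].discrimination
        assert agree.processes[0].location == inta.processes[1].location

    def test_four_point_structure(self):
        spec = tr.build_model_ideal_ers(4, 1)
        assert spec.mapping.node_n_categories == (2, 2, 2)

    def test_sequential_variants(self):
        ers_only = tr.build_model_ideal_ers(6, 1, intensity="ers_only")
        assert [p.kind for p in ers_only.nodes[0][1].processes] == ["dominance"]
        trait_only = tr.build_model_ideal_ers(6, 1, intensity="trait_only")
        assert [p.kind for p in trait_only.nodes[0][1].processes] == ["ideal_point"]
        assert trait_only.traits == frozenset({"theta"})

    def test_odd_scale_rejected(self):
        with pytest.raises(ValueError, match="even"):
            tr.build_model_ideal_ers(5, 1)


class TestMidscaleBuilder:
    def test_mapping_paths(self):
        spec = tr.build_model_midscale(1)
        np.testing.assert_array_equal(
            tr.decompose_response(2, spec.mapping),
            [1, tr.MISSING, tr.MISSING, tr.MISSING],
        )
        np.testing.assert_array_equal(
            tr.decompose_response(4, spec.mapping), [0, 1, 1, tr.MISSING]
        )
        np.testing.assert_array_equal(
            tr.decompose_response(0, spec.mapping), [0, 0, tr.MISSING, 1]
        )

    def test_node_processes_and_reversed_weights(self):
        spec = tr.build_model_midscale(1)
        mid, agree, ext_a, ext_d = spec.nodes[0]
        assert [p.kind for p in mid.processes] == ["dominance", "ideal_point"]
        assert [p.kind for p in agree.processes] == ["dominance"]
        np.testing.assert_array_equal(ext_a.processes[1].weights, [0.0, 1.0])
        np.testing.assert_array_equal(ext_d.processes[1].weights, [1.0, 0.0])
        # shared ERS / trait-extreme discriminations across X3 and X4
        assert ext_a.processes[0].discrimination == ext_d.processes[0].discrimination
        assert ext_a.processes[1].discrimination == ext_d.processes[1].discrimination

    def test_location_tied_to_agreement_threshold(self, small_midscale_dataset):
        ds = small_midscale_dataset
        spec = ds.spec
        params = dict(ds.params)
        node0 = spec.nodes[0][0].resolve(params)
        assert node0.processes[1].location == params["beta2[0]"]
        params["beta2[0]"] += 1.0
        moved = spec.nodes[0][0].resolve(params)
        assert moved.processes[1].location == node0.processes[1].location + 1.0

    def test_midscale_probability_vanishes_at_large_distance(self, small_midscale_dataset):
        """Far from the item location the ideal-point term suppresses the
        middle category regardless of the response-style level; with a
        vanishing ideal-point discrimination, the node reduces to the pure
        MRS logistic."""
        ds = small_midscale_dataset
        node = ds.spec.nodes[0][0].resolve(ds.params)
        p_far = dm.dimirt_probs({"theta": ds.params["beta2[0]"] + 30, "eta1": 1.0}, node)
        assert p_far.p[1] == pytest.approx(0.0, abs=1e-8)
        params = dict(ds.params)
        params["lambda[0]"] = 1e-9
        node0 = ds.spec.nodes[0][0].resolve(params)
        p_mid = dm.dimirt_probs({"theta": 5.0, "eta1": 0.7}, node0)
        a1 = params["alpha1[0]"]
        lin = a1 * 0.7 - params["tau1[0,1]"]
        assert p_mid.p[1] == pytest.approx(1 / (1 + np.exp(-lin)), abs=1e-6)

    def test_all_dominance_variant(self):
        spec = tr.build_model_midscale(1, trait_midscale="dominance")
        assert [p.kind for p in spec.nodes[0][0].processes] == ["dominance", "dominance"]


def test_unregistered_trait_rejected():
    node = tr.NodeSpec(
        processes=(dm.ProcessSpec("dominance", "ghost", np.array([0.0, 1.0]), 1.0),),
        intercept_ids=("tau[0,1]",),
        name="n",
    )
    mapping = tr.TreeMapping(np.array([[0], [1]]), ("n",))
    with pytest.raises(ValueError, match="ghost"):
        tr.TreeModelSpec(mapping=mapping, nodes=((node,),), traits=frozenset({"theta"}))
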