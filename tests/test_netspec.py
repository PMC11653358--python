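"""Structure, counting, shape inference and execution of the fused graph."""

import math

import numpy as np
import pytest

from denseinceps import netspec as ns
from denseinceps.runtime import NetworkModel, softmax_cross_entropy


@pytest.fixture(scope="module")
def dense():
    return ns.build_dense_module()


@pytest.fixture(scope="module")
def inception():
    return ns.build_inception_module()


@pytest.fixture(scope="module")
def fused():
    return ns.build_fused_network()


class TestStructure:
    def test_module_and_fused_layer_counts(self, dense, inception, fused):
        assert ns.count_layers(dense) == 71
        assert ns.count_layers(inception) == 44
        assert ns.count_layers(fused) == 115

    def test_dense_block_and_convolution_counts(self, dense):
        aud = ns.audit(dense)
        assert aud.residual_block_count == 9
        assert aud.conv_layer_count == 22

    def test_dense_stem_is_3x3_stride2_depth32(self, dense):
        stem = next(l for l in dense.layers if l.kind == "convolution")
        assert (stem.filter_h, stem.filter_w, stem.stride,
                stem.out_channels) == (3, 3, 2, 32)

    def test_inception_stem_is_1x1_stride2_depth16(self, inception):
        stem = next(l for l in inception.layers if l.kind == "convolution")
        assert (stem.filter_h, stem.filter_w, stem.stride,
                stem.out_channels) == (1, 1, 2, 16)

    def test_inception_block_has_1x3_and_3x1_branches(self, inception):
        shapes = {(l.filter_h, l.filter_w) for l in inception.layers
                  if l.kind == "convolution"}
        assert (1, 3) in shapes and (3, 1) in shapes

    def test_inception_has_exactly_one_global_average_pool(self, inception):
        assert ns.audit(inception).layers_by_kind["global-average-pool"] == 1

    def test_fused_feature_dimension_is_512(self, fused):
        assert ns.audit(fused).fused_feature_dim == 512

    def test_concat_channels_are_sums_of_inputs(self, fused):
        shapes = ns.infer_shapes(fused)
        for l in fused.layers:
            if l.kind == "depth-concatenation":
                assert shapes[l.id][0] == sum(shapes[i][0] for i in l.inputs)

    def test_json_round_trip_preserves_audit(self, fused):
        clone = ns.NetworkGraph.from_json(fused.to_json())
        assert ns.audit(clone) == ns.audit(fused)

    def test_spatially_misaligned_concat_names_offender(self):
        layers = [
            ns.LayerSpec("in", "input"),
            ns.LayerSpec("c1", "convolution", ["in"], filter_h=1, filter_w=1,
                         stride=1, out_channels=4),
            ns.LayerSpec("c2", "convolution", ["in"], filter_h=3, filter_w=3,
                         stride=2, out_channels=4),
            ns.LayerSpec("bad", "depth-concatenation", ["c1", "c2"]),
        ]
        g = ns.NetworkGraph(layers, name="broken")
        with pytest.raises(ns.StructuralError, match="bad"):
            ns.infer_shapes(g)


class TestParameterCounting:
    def test_single_conv_parameter_formula(self):
        g = ns.NetworkGraph([
            ns.LayerSpec("in", "input"),
            ns.LayerSpec("c", "convolution", ["in"], filter_h=3, filter_w=3,
                         stride=2, out_channels=32),
        ])
        assert ns.count_parameters(g) == 3 * 3 * 3 * 32 + 32  # 896

    def test_batch_norm_parameter_formula(self):
        g = ns.NetworkGraph([
            ns.LayerSpec("in", "input"),
            ns.LayerSpec("c", "convolution", ["in"], filter_h=1, filter_w=1,
                         stride=1, out_channels=64),
            ns.LayerSpec("bn", "batch-norm", ["c"]),
        ])
        assert ns.count_parameters(g) - ns.count_parameters(
            ns.NetworkGraph(g.layers[:2])) == 128

    def test_fused_total_is_6_9_million_to_2_significant_figures(self, fused):
        total = ns.count_parameters(fused)
        assert round(total / 1e6, 1) == 6.9

    def test_width_scaling_preserves_layers_and_scales_parameters(self, fused):
        half = ns.build_fused_network(0.5)
        assert ns.count_layers(half) == ns.count_layers(fused)
        ratio = ns.count_parameters(half) / ns.count_parameters(fused)
        assert abs(ratio - 0.25) < 0.02


class TestFusion:
    @staticmethod
    def _vector_branch(prefix, channels):
        layers = [
            ns.LayerSpec(f"{prefix}in", "input"),
            ns.LayerSpec(f"{prefix}c", "convolution", [f"{prefix}in"],
                         filter_h=1, filter_w=1, stride=1,
                         out_channels=channels),
            ns.LayerSpec(f"{prefix}gap", "global-average-pool", [f"{prefix}c"]),
            ns.LayerSpec(f"{prefix}fl", "flatten", [f"{prefix}gap"]),
        ]
        return ns.NetworkGraph(layers, name=prefix)

    def test_fused_dimension_is_additive(self):
        g = ns.fuse_networks(self._vector_branch("a", 1),
                             self._vector_branch("b", 1), num_classes=2)
        assert ns.audit(g).fused_feature_dim == 2

    def test_image_shaped_branch_rejected(self):
        img_branch = ns.NetworkGraph([
            ns.LayerSpec("xin", "input"),
            ns.LayerSpec("xc", "convolution", ["xin"], filter_h=1, filter_w=1,
                         stride=1, out_channels=2),
        ], name="img")
        with pytest.raises(ns.StructuralError):
            ns.fuse_networks(self._vector_branch("a", 4), img_branch)

    def test_module_subtotals_reproduce_fused_total(self, dense, inception,
                                                    fused):
        # head attribution: 71 (incl. shared input) + 40 + 4-node fusion head
        assert ns.count_layers(fused) == 115
        assert ns.count_layers(dense) + ns.count_layers(inception) == 115


class TestLoss:
    def test_uniform_logits_give_log_c(self):
        assert softmax_cross_entropy(np.zeros(5), 0) == pytest.approx(
            math.log(5), abs=1e-12)

    def test_hand_evaluated_example(self):
        # logits (2,0,0), true first: -2 + ln(e^2 + 2)
        expected = -2 + math.log(math.exp(2) + 2)
        assert softmax_cross_entropy(np.array([2.0, 0.0, 0.0]), 0) == \
            pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.2395, abs=1e-4)

    def test_confident_true_class_drives_loss_to_zero(self):
        assert softmax_cross_entropy(np.array([200.0, 0.0, 0.0]), 0) < 1e-12

    def test_agrees_with_naive_evaluation_on_moderate_logits(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = rng.uniform(-10, 10, size=6)
            y = int(rng.integers(6))
            naive = -t[y] + np.log(np.exp(t).sum())
            assert softmax_cross_entropy(t, y) == pytest.approx(naive,
                                                                abs=1e-9)


@pytest.fixture(scope="module")
def model():
    return NetworkModel(ns.build_fused_network(0.125), seed=0)


@pytest.fixture(scope="module")
def batch():
    rng = np.random.default_rng(1)
    return rng.random((3, 227, 227, 3), dtype=np.float32)


class TestForward:

    def test_probability_rows_sum_to_one(self, model, batch):
        p = model.forward(batch)
        assert p.shape == (3, 5)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_fusion_tap_width_tracks_width_scale(self, model, batch):
        f = model.forward(batch, tap="fusion_concat")
        assert f.shape == (3, 64)  # 512 * 0.125

    def test_fusion_tap_is_512_wide_at_full_scale(self):
        model = NetworkModel(ns.build_fused_network(1.0), seed=0)
        rng = np.random.default_rng(2)
        f = model.forward(rng.random((1, 227, 227, 3), dtype=np.float32),
                          tap="fusion_concat")
        assert f.shape == (1, 512)

    def test_zeroed_classifier_head_gives_uniform_probabilities(self, model,
                                                                batch):
        fc = model.params["fusion_fc"]
        saved = (fc["w"].data.copy(), fc["b"].data.copy())
        fc["w"].data[:] = 0.0
        fc["b"].data[:] = 0.0
        try:
            p = model.forward(batch)
            np.testing.assert_allclose(p, 0.2, atol=1e-7)
        finally:
            fc["w"].data, fc["b"].data = saved

    def test_unknown_tap_rejected(self, model, batch):
        with pytest.raises(KeyError):
            model.forward(batch, tap="no_such_layer")

    def test_forward_is_deterministic_for_fixed_weights(self, model, batch):
        np.testing.assert_array_equal(model.forward(batch),
                                      model.forward(batch))
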