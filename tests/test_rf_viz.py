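import numpy as np
import pytest

from facespace import convnet, rf_viz
from facespace.convnet import build_toy_convnet, forward, receptive_field


class TestToyConvNet:
    def test_same_seed_identical_weights(self):
        a = build_toy_convnet(seed=4)
        b = build_toy_convnet(seed=4)
        c = build_toy_convnet(seed=5)
        assert np.array_equal(a.layers[0].weights, b.layers[0].weights)
        assert not np.array_equal(a.layers[0].weights, c.layers[0].weights)

    def test_xavier_variance_close_to_two_over_fan_sum(self):
        """Empirical kernel variance within 20% of 2/(fan_in+fan_out)."""
        ws = [build_toy_convnet(seed=s, channels=16).layers[1].weights for s in range(10)]
        w = np.concatenate([x.ravel() for x in ws])
        fan_in = 16 * 9
        fan_out = 16 * 9
        assert np.var(w) == pytest.approx(2.0 / (fan_in + fan_out), rel=0.2)

    def test_fixed_init_deterministic(self):
        a = build_toy_convnet(seed=0, init="fixed")
        b = build_toy_convnet(seed=99, init="fixed")
        assert np.array_equal(a.layers[0].weights, b.layers[0].weights)
        with pytest.raises(ValueError, match="init"):
            build_toy_convnet(init="uniform")

    def test_receptive_field_of_second_conv_is_5x5(self):
        spec = build_toy_convnet(depth=2, seed=0)
        top, left, h, w = receptive_field(spec, "conv2", 10, 10)
        assert (h, w) == (5, 5) and (top, left) == (8, 8)

    def test_receptive_field_clipped_at_border(self):
        spec = build_toy_convnet(depth=1, seed=0)
        top, left, h, w = receptive_field(spec, "conv1", 0, 0)
        assert (top, left) == (0, 0) and (h, w) == (2, 2)  # 3x3 kernel, padding 1

    def test_forward_shapes(self):
        spec = build_toy_convnet(depth=2, seed=1, input_size=16, channels=4, n_classes=5)
        fp = forward(spec, np.zeros((3, 16, 16)))
        assert fp.outputs[0].shape == (4, 16, 16)
        assert fp.outputs[2].shape == (4, 8, 8)  # after 2x2 pool
        assert fp.outputs[-1].shape == (5,)


def _linear_net(seed=0, size=8):
    return build_toy_convnet(depth=1, seed=seed, relu=False, input_channels=1,
                             channels=2, input_size=size)


class TestDeconvolution:
    def test_single_linear_conv_reconstruction_is_kernel_at_field(self):
        spec = _linear_net()
        img = np.random.default_rng(0).normal(size=(1, 8, 8))
        rf = rf_viz.deconvolve_unit(spec, img, "conv1", (0, 4, 4), seed_value=1.0)
        k = spec.layers[0].weights[0, 0]
        assert np.allclose(rf.reconstruction[0, 3:6, 3:6], k)
        outside = rf.reconstruction.copy()
        outside[0, 3:6, 3:6] = 0
        assert np.allclose(outside, 0)

    def test_linear_network_equals_analytic_adjoint(self):
        """Unit-impulse deconvolution matches the adjoint column built by
        probing the forward map with pixel impulses (max dev < 1e-6)."""
        spec = _linear_net(seed=3, size=6)
        img = np.random.default_rng(1).normal(size=(1, 6, 6))
        unit = (1, 2, 3)
        rf = rf_viz.deconvolve_unit(spec, img, "conv1", unit, seed_value=1.0)
        adjoint = np.zeros((1, 6, 6))
        for i in range(6):
            for j in range(6):
                probe = np.zeros((1, 6, 6))
                probe[0, i, j] = 1.0
                adjoint[0, i, j] = forward(spec, probe).outputs[0][unit]
        assert np.abs(rf.reconstruction - adjoint).max() < 1e-6

    def test_dead_relu_unit_reconstructs_to_zero(self):
        spec = build_toy_convnet(depth=1, seed=2, input_channels=1, channels=2, input_size=8)
        img = np.random.default_rng(2).normal(size=(1, 8, 8))
        fp = forward(spec, img)
        dead = np.argwhere(fp.outputs[0] == 0)
        unit = tuple(dead[0])
        rf = rf_viz.deconvolve_unit(spec, img, "conv1", unit)  # propagated activation = 0
        assert np.allclose(rf.reconstruction, 0)

    def test_reconstruction_confined_to_receptive_field(self):
        spec = build_toy_convnet(depth=2, seed=3, input_size=16)
        img = np.random.default_rng(3).uniform(0, 255, (3, 16, 16))
        unit = (0, 8, 8)
        rf = rf_viz.deconvolve_unit(spec, img, "conv2", unit)
        top, left, h, w = receptive_field(spec, "conv2", 8, 8)
        mask = np.zeros((16, 16), dtype=bool)
        mask[top : top + h, left : left + w] = True
        assert np.allclose(rf.reconstruction[:, ~mask], 0)

    def test_fc_unit_backprojects_to_image_space(self):
        spec = build_toy_convnet(depth=1, seed=4, input_size=8, channels=2, n_classes=3)
        img = np.random.default_rng(4).uniform(0, 255, (3, 8, 8))
        rf = rf_viz.deconvolve_unit(spec, img, "fc1", 1)
        assert rf.reconstruction.shape == (3, 8, 8)


class TestActivationMaximization:
    def test_zero_learning_rate_changes_nothing(self):
        spec = build_toy_convnet(depth=1, seed=5, input_size=8)
        img = np.random.default_rng(5).uniform(0, 255, (3, 8, 8))
        rf, trace = rf_viz.activation_maximization(spec, img, "conv1", (0, 4, 4),
                                                   n_iter=5, lr=0.0)
        assert np.allclose(rf.delta, 0)
        assert np.allclose(trace, trace[0])

    def test_linear_unit_activation_strictly_increases(self):
        spec = _linear_net(seed=6)
        rng = np.random.default_rng(6)
        img = rng.normal(size=(1, 8, 8))
        fp = forward(spec, img)
        # pick a positively activated unit: ascent on the propagated activation
        pos = np.argwhere(fp.outputs[0] > 0)[0]
        _, trace = rf_viz.activation_maximization(spec, img, "conv1", tuple(pos),
                                                  n_iter=15, lr=0.05)
        assert (np.diff(trace) > 0).all()

    def test_relu_net_final_activation_exceeds_initial(self):
        for seed in range(10):
            spec = build_toy_convnet(depth=2, seed=seed, input_size=16)
            rng = np.random.default_rng(seed)
            img = rng.uniform(0, 255, (3, 16, 16))
            fp = forward(spec, img)
            out = fp.outputs[spec.layer_index("conv2")]
            unit = np.unravel_index(np.argmax(out), out.shape)
            _, trace = rf_viz.activation_maximization(spec, img, "conv2", unit,
                                                      n_iter=10, lr=0.05)
            assert trace[-1] > trace[0]

    def test_delta_energy_grows_with_learning_rate(self):
        spec = build_toy_convnet(depth=1, seed=7, input_size=8)
        img = np.random.default_rng(7).uniform(0, 255, (3, 8, 8))
        fp = forward(spec, img)
        out = fp.outputs[0]
        unit = np.unravel_index(np.argmax(out), out.shape)
        energies = []
        for lr in (0.001, 0.01, 0.1):
            rf, _ = rf_viz.activation_maximization(spec, img, "conv1", unit, n_iter=5, lr=lr)
            energies.append(np.abs(rf.delta).sum())
        assert energies[0] < energies[1] < energies[2]

    def test_overflow_reports_iteration(self):
        spec = _linear_net(seed=8)
        img = np.random.default_rng(8).normal(size=(1, 8, 8))
        fp = forward(spec, img)
        pos = tuple(np.argwhere(fp.outputs[0] > 0)[0])
        with pytest.raises(FloatingPointError, match="iteration"):
            rf_viz.activation_maximization(spec, img, "conv1", pos, n_iter=300, lr=1e12)


class TestRendering:
    def test_contrast_stretch_only_at_render_time(self):
        base = np.zeros((1, 4, 4))
        recon = np.array([[[0.0, -2.0], [2.0, 0.0]]])
        rf = rf_viz.RFImage(base[:, :2, :2], recon)
        rendered = rf.render()
        assert rendered.min() == 0 and rendered.max() == 255
        assert np.array_equal(rf.reconstruction, recon)  # stored array untouched

    def test_png_export(self, tmp_path):
        rng = np.random.default_rng(9)
        rf = rf_viz.RFImage(rng.uniform(0, 255, (3, 8, 8)), rng.normal(size=(3, 8, 8)))
        rf.save_png(tmp_path / "rf.png")
        from PIL import Image

        assert Image.open(tmp_path / "rf.png").size == (8, 8)
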