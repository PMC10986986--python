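import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from limbseg.nn.layers import Conv2d, sigmoid, softmax_channels
from limbseg.nn.models import (
    WIDTH_PRESETS,
    AttentionGate,
    NetworkConfig,
    build_attention_unet,
    build_sc_unet,
    build_unet,
    count_parameters,
    predict_labelmap,
    spatial_encoding,
)
from limbseg.training import _cross_entropy_from_logits, _gated_cross_entropy
from limbseg.volumes import ImageVolume

TINY = (2, 4, 8, 16, 32)


def _unet_cfg(**kw):
    kw.setdefault("encoder_widths", TINY)
    kw.setdefault("n_muscle_classes", 3)
    return NetworkConfig(**kw)


class TestConfig:
    def test_widths_must_double(self):
        with pytest.raises(ValueError):
            NetworkConfig(encoder_widths=(8, 16, 32, 64, 100))
        with pytest.raises(ValueError):
            NetworkConfig(encoder_widths=(8, 16, 32, 64))

    def test_output_channels_include_background(self):
        assert NetworkConfig(n_muscle_classes=37).n_out_channels == 38
        assert (
            NetworkConfig(n_muscle_classes=37, include_background_channel=False).n_out_channels
            == 37
        )


class TestSpatialEncoding:
    def test_endpoints(self):
        assert spatial_encoding(0, 200).p == 1
        assert spatial_encoding(199, 200).p == 100
        assert spatial_encoding(99, 200).p == 50

    def test_onehot_structure(self):
        enc = spatial_encoding(42, 100)
        assert enc.vector.sum() == 1 and enc.vector[enc.p - 1] == 1

    @settings(max_examples=200, derandomize=True)
    @given(total=st.integers(1, 500), frac=st.floats(0, 1, exclude_max=True))
    def test_p_valid_and_monotone(self, total, frac):
        i = int(frac * total)
        enc = spatial_encoding(i, total)
        assert 1 <= enc.p <= 100
        if i + 1 < total:
            assert spatial_encoding(i + 1, total).p >= enc.p

    def test_all_nodes_covered_for_long_axes(self):
        ps = {spatial_encoding(i, 1000).p for i in range(1000)}
        assert ps == set(range(1, 101))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            spatial_encoding(0, 0)
        with pytest.raises(ValueError):
            spatial_encoding(5, 5)


class TestUNet:
    def test_output_shape_and_softmax_normalisation(self, rng):
        net = build_unet(_unet_cfg(n_muscle_classes=37), seed=0)
        x = rng.normal(size=(2, 1, 64, 64)).astype(np.float32)
        probs = net.predict_proba(x)
        assert probs.shape == (2, 38, 64, 64)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert (probs >= 0).all()

    def test_non_multiple_of_16_padded_and_cropped(self, rng):
        net = build_unet(_unet_cfg(), seed=0)
        x = rng.normal(size=(1, 1, 40, 56)).astype(np.float32)
        assert net.predict_proba(x).shape == (1, 4, 40, 56)

    def test_head_conv_parameter_arithmetic(self, rng):
        conv = Conv2d(16, 38, 1, bias=True, rng=np.random.default_rng(0))
        assert sum(p.v.size for p in conv.params()) == 16 * 38 + 38

    def test_doubling_widths_quadruples_parameters(self):
        c1 = count_parameters(build_unet(NetworkConfig(encoder_widths=WIDTH_PRESETS["tiny"])))
        c2 = count_parameters(build_unet(NetworkConfig(encoder_widths=WIDTH_PRESETS["small"])))
        assert c2 / c1 == pytest.approx(4.0, rel=0.10)

    def test_count_parameters_against_closed_form(self):
        cfg = _unet_cfg(n_muscle_classes=5)
        w = cfg.encoder_widths
        expected = 0
        cin = 1
        for wi in list(w[:4]) + [w[4]]:  # four encoder stages + bottleneck
            expected += cin * wi * 9 + 2 * wi + wi * wi * 9 + 2 * wi
            cin = wi
        for i in range(4):  # up blocks: 3x3 conv with bias after upsampling
            expected += w[i + 1] * w[i] * 9 + w[i]
        for i in range(4):  # decoder blocks on concatenated features
            expected += 2 * w[i] * w[i] * 9 + 2 * w[i] + w[i] * w[i] * 9 + 2 * w[i]
        expected += w[0] * cfg.n_out_channels + cfg.n_out_channels  # 1x1 head
        assert count_parameters(build_unet(cfg)) == expected

    def test_full_gradient_against_numeric(self):
        # batch-norm off: batch statistics make the float32 numeric
        # difference ill-conditioned; the BN layer has its own check
        rng = np.random.default_rng(17)
        net = build_unet(_unet_cfg(batch_norm=False), seed=1)
        x = rng.normal(size=(2, 1, 16, 16)).astype(np.float32)
        y = rng.integers(0, 4, size=(2, 16, 16))

        def loss():
            return _cross_entropy_from_logits(net.forward(x, train=True), y)

        _, dl = loss()
        params = net.parameters()
        for p in params:
            p.g[...] = 0
        net.backward(dl)
        # directional derivative along the analytic gradient:
        # d/dt L(theta + t g) at 0 must equal ||g||^2
        g_sq = float(sum((p.g.astype(np.float64) ** 2).sum() for p in params))
        assert g_sq > 0
        t = 1e-2 / np.sqrt(g_sq)
        saved = [p.v.copy() for p in params]
        for p in params:
            p.v += t * p.g
        lp, _ = loss()
        for p, s in zip(params, saved):
            p.v[...] = s - t * p.g
        lm, _ = loss()
        for p, s in zip(params, saved):
            p.v[...] = s
        assert (lp - lm) / (2 * t) == pytest.approx(g_sq, rel=0.02)


class TestAttentionGate:
    def test_zero_skip_gives_zero_output(self, rng):
        gate = AttentionGate(4, np.random.default_rng(0))
        x = np.zeros((1, 4, 8, 8), dtype=np.float32)
        g = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        assert np.all(gate.forward(x, g) == 0)

    def test_attention_coefficients_strictly_in_unit_interval(self, rng):
        gate = AttentionGate(4, np.random.default_rng(0))
        x = rng.normal(size=(2, 4, 8, 8)).astype(np.float32)
        g = rng.normal(size=(2, 4, 8, 8)).astype(np.float32)
        gate.forward(x, g)
        a = gate.last_attention
        assert (a > 0).all() and (a < 1).all()

    def test_hand_computed_toy(self):
        gate = AttentionGate(1, np.random.default_rng(0))
        gate.theta.W.v[...] = 2.0
        gate.phi.W.v[...] = 1.0
        gate.phi.b.v[...] = 0.5
        gate.psi.W.v[...] = 1.0
        gate.psi.b.v[...] = -1.0
        x = np.array([[[[1.0, -1.0], [0.0, 2.0]]]], dtype=np.float32)
        g = np.array([[[[0.5, 0.0], [1.0, -2.0]]]], dtype=np.float32)
        out = gate.forward(x, g)
        s = np.maximum(2 * x + g + 0.5, 0)
        expected = x * (1 / (1 + np.exp(-(s - 1))))
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_mismatched_spatial_sizes_rejected(self, rng):
        gate = AttentionGate(2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            gate.forward(np.zeros((1, 2, 8, 8), np.float32), np.zeros((1, 2, 4, 4), np.float32))


class TestAttentionUNet:
    def test_parameter_count_exceeds_unet(self):
        for preset in WIDTH_PRESETS.values():
            cu = count_parameters(build_unet(NetworkConfig(encoder_widths=preset)))
            ca = count_parameters(
                build_attention_unet(
                    NetworkConfig(variant="attention_unet", encoder_widths=preset)
                )
            )
            assert ca > cu

    def test_shape_preserved(self, rng):
        net = build_attention_unet(_unet_cfg(variant="attention_unet"), seed=0)
        x = rng.normal(size=(1, 1, 64, 64)).astype(np.float32)
        assert net.predict_proba(x).shape == (1, 4, 64, 64)

    def test_bypassed_gates_equal_plain_unet_with_shared_weights(self, rng):
        cfg = _unet_cfg(variant="attention_unet")
        anet = build_attention_unet(cfg, seed=5)
        unet = build_unet(_unet_cfg(variant="unet"), seed=0)
        # share every trunk weight; the attention gates are then the only difference
        for pa, pu in zip(
            [p for m in [*anet.enc, anet.bottleneck, *anet.ups, *anet.dec, anet.head] for p in m.params()],
            unet.parameters(),
        ):
            pu.v[...] = pa.v
        x = rng.normal(size=(2, 1, 32, 32)).astype(np.float32)
        anet.bypass_gates = True
        np.testing.assert_allclose(anet.predict_proba(x), unet.predict_proba(x), atol=1e-6)
        anet.bypass_gates = False
        assert not np.allclose(anet.predict_proba(x), unet.predict_proba(x))


class TestSCUNet:
    def test_parameter_delta_is_nodes_times_classes(self):
        for preset in WIDTH_PRESETS.values():
            cu = count_parameters(build_unet(NetworkConfig(encoder_widths=preset)))
            cs = count_parameters(
                build_sc_unet(NetworkConfig(variant="sc_unet", encoder_widths=preset))
            )
            assert cs - cu == 100 * 37

    def test_spatial_layer_dimensions(self):
        net = build_sc_unet(NetworkConfig(variant="sc_unet", encoder_widths=TINY))
        assert net.spatial.W.v.shape == (37, 100)
        assert net.spatial.b is None

    def test_all_ones_gates_reduce_to_unet_branch(self, rng):
        net = build_sc_unet(_unet_cfg(variant="sc_unet"), seed=2)
        x = rng.normal(size=(2, 1, 32, 32)).astype(np.float32)
        pos = np.stack([spatial_encoding(z, 10).vector for z in (2, 7)])
        gated = net.predict_proba(x, pos, gate_override=1.0)
        plain = softmax_channels(net.unet.forward(x, train=False))
        np.testing.assert_allclose(gated, plain, atol=1e-6)

    def test_zero_gate_excludes_class(self, rng):
        cfg = _unet_cfg(variant="sc_unet")
        net = build_sc_unet(cfg, seed=2)
        x = rng.normal(size=(2, 1, 32, 32)).astype(np.float32)
        pos = np.stack([spatial_encoding(z, 10).vector for z in (2, 7)])
        override = np.ones((2, cfg.n_muscle_classes), dtype=np.float32)
        override[:, 1] = 0.0  # class 2
        probs = net.predict_proba(x, pos, gate_override=override)
        assert not (probs.argmax(axis=1) == 2).any()

    def test_gated_loss_gradients_against_numeric(self):
        rng = np.random.default_rng(23)
        cfg = _unet_cfg(variant="sc_unet", batch_norm=False)
        net = build_sc_unet(cfg, seed=4)
        x = rng.normal(size=(2, 1, 16, 16)).astype(np.float32)
        y = rng.integers(0, 4, size=(2, 16, 16))
        pos = np.stack([spatial_encoding(z, 8).vector for z in (1, 6)])

        def loss():
            logits, gates = net.forward(x, pos, train=True)
            return _gated_cross_entropy(logits, gates, y, net)

        _, dlog, dg = loss()
        params = net.parameters()
        for p in params:
            p.g[...] = 0
        net.backward(dlog, dg)
        # the spatial layer must receive gradient at all
        assert float(np.abs(net.spatial.W.g).sum()) > 0
        g_sq = float(sum((p.g.astype(np.float64) ** 2).sum() for p in params))
        t = 1e-2 / np.sqrt(g_sq)
        saved = [p.v.copy() for p in params]
        for p in params:
            p.v += t * p.g
        lp = loss()[0]
        for p, s in zip(params, saved):
            p.v[...] = s - t * p.g
        lm = loss()[0]
        for p, s in zip(params, saved):
            p.v[...] = s
        assert (lp - lm) / (2 * t) == pytest.approx(g_sq, rel=0.02)


class TestPredictLabelmap:
    def test_uniform_probabilities_give_all_background(self, small_subject):
        net = build_unet(_unet_cfg(n_muscle_classes=3), seed=0)
        net.head.W.v[...] = 0.0
        net.head.b.v[...] = 0.0
        lm = predict_labelmap(net, small_subject.image)
        assert (lm.labels == 0).all()

    def test_agrees_with_per_pixel_argmax_oracle(self, rng):
        net = build_unet(_unet_cfg(n_muscle_classes=3), seed=3)
        vol = ImageVolume(rng.normal(size=(4, 16, 16)).astype(np.float32), (1, 1, 1))
        lm = predict_labelmap(net, vol)
        for z in range(4):
            probs = net.predict_proba(vol.voxels[z][None, None])[0]
            for i in range(16):
                for j in range(16):
                    assert lm.labels[z, i, j] == int(np.argmax(probs[:, i, j]))

    def test_requires_volume_container(self, rng):
        net = build_unet(_unet_cfg(), seed=0)
        with pytest.raises(TypeError):
            predict_labelmap(net, rng.normal(size=(4, 16, 16)))

    def test_geometry_preserved(self, small_subject):
        net = build_unet(_unet_cfg(n_muscle_classes=3), seed=0)
        lm = predict_labelmap(net, small_subject.image)
        assert lm.shape == small_subject.image.shape
        assert lm.spacing == small_subject.image.spacing


class TestCheckpoints:
    def test_roundtrip_preserves_predictions(self, tmp_path, rng):
        from limbseg.nn.models import load_checkpoint, save_checkpoint, build_attention_unet

        for variant, builder in (
            ("attention_unet", build_attention_unet),
            ("sc_unet", build_sc_unet),
        ):
            cfg = _unet_cfg(variant=variant)
            net = builder(cfg, seed=6)
            path = str(tmp_path / f"{variant}.npz")
            save_checkpoint(net, path)
            restored = load_checkpoint(path, seed=99)
            x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
            if variant == "sc_unet":
                pos = spatial_encoding(3, 10).vector[None]
                np.testing.assert_array_equal(
                    net.predict_proba(x, pos), restored.predict_proba(x, pos)
                )
            else:
                np.testing.assert_array_equal(net.predict_proba(x), restored.predict_proba(x))
            assert restored.config == cfg

    def test_shape_mismatch_rejected(self, tmp_path):
        from limbseg.nn.models import load_checkpoint, save_checkpoint

        net = build_unet(_unet_cfg(), seed=0)
        path = str(tmp_path / "ck.npz")
        save_checkpoint(net, path)
        import numpy as _np
        import json as _json

        with _np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
        arrays["arr_0000"] = _np.zeros((1, 1))
        _np.savez(path, **arrays)
        with pytest.raises(ValueError):
            load_checkpoint(path)
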