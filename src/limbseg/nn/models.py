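"""The three 2D segmentation architectures: UNet, Attention UNet, SC-UNet.

All three share the same encoder-decoder trunk: four down-sampling stages
(two 3x3 convolutions + batch-norm + ReLU, then 2x2 stride-2 max pooling),
a bottleneck block, and four up-sampling stages whose inputs are
concatenated with the same-size encoder feature maps (skip connections),
closed by a 1x1 convolution onto the class channels.  The Attention UNet
multiplies each skip by a learned attention map (add -> ReLU -> 1x1
projection -> sigmoid) driven by the decoder.  The SC-UNet runs a parallel
fully connected layer from a 100-node one-hot encoding of the slice's
axial position to one sigmoid gate per muscle class; the gates multiply
the per-pixel class probabilities, so a gate of 0 makes a muscle
impossible on that slice.

Output channels are background (channel 0) plus one channel per muscle
class by default; per-pixel class probabilities come from a softmax over
channels and predictions are the per-pixel arg-max, ties broken toward the
lowest class id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from ..volumes import ImageVolume, LabelVolume
from .layers import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2x2,
    Linear,
    MaxPool2x2,
    NearestUpsample2,
    Param,
    ReLU,
    sigmoid,
    softmax_channels,
)

WIDTH_PRESETS: dict[str, tuple[int, ...]] = {
    "tiny": (8, 16, 32, 64, 128),
    "small": (16, 32, 64, 128, 256),
    "full": (64, 128, 256, 512, 1024),
}

VARIANTS = ("unet", "attention_unet", "sc_unet")


@dataclass(frozen=True)
class NetworkConfig:
    variant: str = "unet"
    encoder_widths: tuple[int, ...] = WIDTH_PRESETS["tiny"]
    n_muscle_classes: int = 37
    include_background_channel: bool = True
    upsampling: str = "interpolation"  # or "transposed"
    batch_norm: bool = True
    spatial_nodes: int = 100
    spatial_bias: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        w = tuple(self.encoder_widths)
        if len(w) != 5 or any(w[i + 1] != 2 * w[i] for i in range(4)):
            raise ValueError("encoder_widths must be 5 values, each double the last")
        object.__setattr__(self, "encoder_widths", w)
        if self.n_muscle_classes < 1:
            raise ValueError("n_muscle_classes must be >= 1")
        if self.upsampling not in ("interpolation", "transposed"):
            raise ValueError("upsampling must be 'interpolation' or 'transposed'")
        if self.spatial_nodes < 1:
            raise ValueError("spatial_nodes must be >= 1")

    @property
    def n_out_channels(self) -> int:
        return self.n_muscle_classes + (1 if self.include_background_channel else 0)


@dataclass(frozen=True)
class SpatialEncoding:
    """One-hot axial position: element p (1-based) of a length-``nodes`` vector."""

    vector: np.ndarray
    p: int


def spatial_encoding(slice_index: int, total_slices: int, nodes: int = 100) -> SpatialEncoding:
    """Encode the axial position of a slice as a one-hot percentage vector.

    The position percentage is ``p = ceil(nodes * (slice_index+1) /
    total_slices)`` clamped into [1, nodes]; element p (1-based) is set.
    """
    if total_slices <= 0:
        raise ValueError("total_slices must be positive")
    if not 0 <= slice_index < total_slices:
        raise ValueError("slice_index must be in [0, total_slices)")
    p = math.ceil(nodes * (slice_index + 1) / total_slices)
    p = min(max(p, 1), nodes)
    vec = np.zeros(nodes, dtype=np.float32)
    vec[p - 1] = 1.0
    return SpatialEncoding(vector=vec, p=p)


# ---------------------------------------------------------------------------
# Building blocks


class _Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train: bool = True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def _conv_block(c_in: int, c_out: int, bn: bool, rng) -> _Sequential:
    layers = []
    for cin in (c_in, c_out):
        layers.append(Conv2d(cin, c_out, 3, bias=not bn, rng=rng))
        if bn:
            layers.append(BatchNorm2d(c_out))
        layers.append(ReLU())
    return _Sequential(*layers)


def _up_block(c_in: int, c_out: int, mode: str, rng) -> _Sequential:
    if mode == "transposed":
        return _Sequential(ConvTranspose2x2(c_in, c_out, rng))
    return _Sequential(NearestUpsample2(), Conv2d(c_in, c_out, 3, bias=True, rng=rng), ReLU())


class AttentionGate:
    """Multiplicative skip-connection gate: add -> ReLU -> 1x1 -> sigmoid -> multiply.

    The skip (``x``) and gating (``g``) features arrive at the same spatial
    size here (the gate sits after up-sampling), so the resampling step of
    the general formulation is the identity.  The internal projection width
    is half the skip channels.
    """

    def __init__(self, channels: int, rng):
        f_int = max(channels // 2, 1)
        self.theta = Conv2d(channels, f_int, 1, bias=False, rng=rng)
        self.phi = Conv2d(channels, f_int, 1, bias=True, rng=rng)
        self.psi = Conv2d(f_int, 1, 1, bias=True, rng=rng)
        self.relu = ReLU()

    def params(self) -> list[Param]:
        return self.theta.params() + self.phi.params() + self.psi.params()

    def forward(self, x: np.ndarray, g: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[2:] != g.shape[2:]:
            raise ValueError(f"skip {x.shape} and gating {g.shape} spatial sizes differ")
        s = self.relu.forward(self.theta.forward(x, train) + self.phi.forward(g, train), train)
        a = sigmoid(self.psi.forward(s, train))  # (B,1,H,W) in (0,1)
        if train:
            self._x, self._a = x, a
        self.last_attention = a
        return x * a

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x, a = self._x, self._a
        da = (dout * x).sum(axis=1, keepdims=True)
        dx = dout * a
        ds = self.relu.backward(self.psi.backward(da * a * (1.0 - a)))
        dx = dx + self.theta.backward(ds)
        dg = self.phi.backward(ds)
        return dx, dg


# ---------------------------------------------------------------------------
# UNet trunk


class UNet:
    """Plain 2D UNet.  Input (B, 1, H, W); output logits (B, C, H, W)."""

    variant = "unet"

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        w = config.encoder_widths
        bn = config.batch_norm
        self.enc = [_conv_block(1 if i == 0 else w[i - 1], w[i], bn, rng) for i in range(4)]
        self.pools = [MaxPool2x2() for _ in range(4)]
        self.bottleneck = _conv_block(w[3], w[4], bn, rng)
        self.ups = [_up_block(w[i + 1], w[i], config.upsampling, rng) for i in range(4)]
        self.dec = [_conv_block(2 * w[i], w[i], bn, rng) for i in range(4)]
        self.head = Conv2d(w[0], config.n_out_channels, 1, bias=True, rng=rng)

    # -- structure traversal ------------------------------------------------
    def modules(self):
        yield from self.enc
        yield from self.pools
        yield self.bottleneck
        yield from self.ups
        yield from self.dec
        yield self.head

    def parameters(self) -> list[Param]:
        return [p for m in self.modules() for p in m.params()]

    # -- skip gating hook (overridden by AttentionUNet) ---------------------
    def _gate_skip(self, i: int, skip: np.ndarray, up: np.ndarray, train: bool) -> np.ndarray:
        return skip

    def _gate_skip_backward(self, i: int, dskip: np.ndarray):
        return dskip, None

    # -- forward / backward -------------------------------------------------
    def _pad(self, x: np.ndarray) -> np.ndarray:
        h, w = x.shape[2:]
        self._orig_hw = (h, w)
        ph, pw = (-h) % 16, (-w) % 16
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        return x

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = self._pad(np.ascontiguousarray(x, dtype=np.float32))
        feats = []
        h = x
        for enc, pool in zip(self.enc, self.pools):
            f = enc.forward(h, train)
            feats.append(f)
            h = pool.forward(f, train)
        h = self.bottleneck.forward(h, train)
        self._widths_cache = [f.shape[1] for f in feats]
        for i in (3, 2, 1, 0):
            u = self.ups[i].forward(h, train)
            s = self._gate_skip(i, feats[i], u, train)
            h = self.dec[i].forward(np.concatenate([s, u], axis=1), train)
        logits = self.head.forward(h, train)
        oh, ow = self._orig_hw
        return logits[:, :, :oh, :ow]

    def backward(self, dlogits: np.ndarray) -> None:
        oh, ow = self._orig_hw
        ph, pw = (-oh) % 16, (-ow) % 16
        if ph or pw:
            dlogits = np.pad(dlogits, ((0, 0), (0, 0), (0, ph), (0, pw)))
        dh = self.head.backward(dlogits)
        dskips = [None] * 4
        for i in (0, 1, 2, 3):
            w_i = self._widths_cache[i]
            dcat = self.dec[i].backward(dh)
            ds, du = dcat[:, :w_i], dcat[:, w_i:]
            ds, dg = self._gate_skip_backward(i, ds)
            if dg is not None:
                du = du + dg
            dskips[i] = ds
            dh = self.ups[i].backward(du)
        dh = self.bottleneck.backward(dh)
        for i in (3, 2, 1, 0):
            df = self.pools[i].backward(dh) + dskips[i]
            dh = self.enc[i].backward(df)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (softmax over channels)."""
        return softmax_channels(self.forward(x, train=False))


class AttentionUNet(UNet):
    """UNet with an attention gate on every skip connection."""

    variant = "attention_unet"

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        super().__init__(config, rng)
        self.gates = [AttentionGate(config.encoder_widths[i], rng) for i in range(4)]
        self.bypass_gates = False  # True forces attention coefficients to 1

    def modules(self):
        yield from super().modules()
        yield from self.gates

    def _gate_skip(self, i: int, skip: np.ndarray, up: np.ndarray, train: bool) -> np.ndarray:
        if self.bypass_gates:
            return skip
        return self.gates[i].forward(skip, up, train)

    def _gate_skip_backward(self, i: int, dskip: np.ndarray):
        if self.bypass_gates:
            return dskip, None
        return self.gates[i].backward(dskip)


class SCUNet:
    """Spatial-channel UNet: a UNet trunk plus a parallel position gate.

    The one-hot axial-position vector passes through one fully connected
    layer (``spatial_nodes`` inputs, one output per muscle class, bias-free
    by default) and a sigmoid, yielding per-muscle gates in (0,1).  Each
    muscle channel of the per-pixel class probabilities is multiplied by
    its gate; the background channel is multiplied by 1.
    """

    variant = "sc_unet"

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        self.unet = UNet(config, rng)
        self.spatial = Linear(
            config.spatial_nodes, config.n_muscle_classes, bias=config.spatial_bias, rng=rng
        )

    def modules(self):
        yield from self.unet.modules()
        yield self.spatial

    def parameters(self) -> list[Param]:
        return [p for m in self.modules() for p in m.params()]

    def forward(
        self, x: np.ndarray, pos: np.ndarray, train: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (logits, gates); ``pos`` is (B, spatial_nodes) one-hot rows."""
        pos = np.ascontiguousarray(pos, dtype=np.float32)
        if pos.ndim != 2 or pos.shape[1] != self.config.spatial_nodes:
            raise ValueError(
                f"position encoding must be (batch, {self.config.spatial_nodes}), got {pos.shape}"
            )
        logits = self.unet.forward(x, train)
        gates = sigmoid(self.spatial.forward(pos, train))
        if train:
            self._gates = gates
        return logits, gates

    def backward(self, dlogits: np.ndarray, dgates: np.ndarray) -> None:
        self.unet.backward(dlogits)
        g = self._gates
        self.spatial.backward(dgates * g * (1.0 - g))

    def gate_probabilities(
        self, probs: np.ndarray, gates: np.ndarray, gate_override: np.ndarray | float | None = None
    ) -> np.ndarray:
        """Multiply muscle channels of per-pixel probabilities by their gates."""
        if gate_override is not None:
            gates = np.broadcast_to(
                np.asarray(gate_override, dtype=np.float32),
                (probs.shape[0], self.config.n_muscle_classes),
            )
        if self.config.include_background_channel:
            full = np.concatenate([np.ones((gates.shape[0], 1), dtype=np.float32), gates], axis=1)
        else:
            full = gates
        return probs * full[:, :, None, None]

    def predict_proba(
        self, x: np.ndarray, pos: np.ndarray, gate_override: np.ndarray | float | None = None
    ) -> np.ndarray:
        logits, gates = self.forward(x, pos, train=False)
        return self.gate_probabilities(softmax_channels(logits), gates, gate_override)


Network = UNet | AttentionUNet | SCUNet


# ---------------------------------------------------------------------------
# Builders


def build_unet(config: NetworkConfig | None = None, seed: int = 0) -> UNet:
    config = config or NetworkConfig(variant="unet")
    return UNet(config, np.random.default_rng(seed))


def build_attention_unet(config: NetworkConfig | None = None, seed: int = 0) -> AttentionUNet:
    config = config or NetworkConfig(variant="attention_unet")
    return AttentionUNet(config, np.random.default_rng(seed))


def build_sc_unet(config: NetworkConfig | None = None, seed: int = 0) -> SCUNet:
    config = config or NetworkConfig(variant="sc_unet")
    return SCUNet(config, np.random.default_rng(seed))


def build_network(config: NetworkConfig, seed: int = 0) -> Network:
    builder = {
        "unet": build_unet,
        "attention_unet": build_attention_unet,
        "sc_unet": build_sc_unet,
    }[config.variant]
    return builder(config, seed)


def count_parameters(network: Network) -> int:
    """Total number of trainable scalar weights."""
    return int(sum(p.v.size for p in network.parameters()))


# ---------------------------------------------------------------------------
# Checkpoints


def _leaf_layers(network: Network):
    for m in network.modules():
        if isinstance(m, _Sequential):
            yield from m.layers
        elif isinstance(m, AttentionGate):
            yield m.theta
            yield m.phi
            yield m.psi
        else:
            yield m


def _state_arrays(network: Network) -> list[np.ndarray]:
    arrays = []
    for layer in _leaf_layers(network):
        arrays.extend(p.v for p in layer.params())
        if isinstance(layer, BatchNorm2d):
            arrays.extend([layer.running_mean, layer.running_var])
    return arrays


def save_checkpoint(network: Network, path: str) -> None:
    """Save weights, batch-norm statistics and the config to an .npz file."""
    import dataclasses
    import json

    config = dataclasses.asdict(network.config)
    arrays = {f"arr_{i:04d}": a for i, a in enumerate(_state_arrays(network))}
    np.savez(path, __config__=np.frombuffer(json.dumps(config).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str, seed: int = 0) -> Network:
    """Rebuild the network recorded in a checkpoint and restore its state."""
    import json

    with np.load(path) as data:
        config_kw = json.loads(bytes(data["__config__"]).decode())
        config_kw["encoder_widths"] = tuple(config_kw["encoder_widths"])
        network = build_network(NetworkConfig(**config_kw), seed=seed)
        targets = _state_arrays(network)
        keys = sorted(k for k in data.files if k.startswith("arr_"))
        if len(keys) != len(targets):
            raise ValueError(f"checkpoint has {len(keys)} tensors, network needs {len(targets)}")
        for key, target in zip(keys, targets):
            saved = data[key]
            if saved.shape != target.shape:
                raise ValueError(f"shape mismatch for {key}: {saved.shape} vs {target.shape}")
            target[...] = saved
    return network


# ---------------------------------------------------------------------------
# Volume prediction


def _argmax_to_class(probs: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """Per-pixel arg-max channel -> class id; first (lowest) index wins ties."""
    idx = probs.argmax(axis=1)
    if config.include_background_channel:
        return idx.astype(np.uint8)  # channel 0 = background = class 0
    return (idx + 1).astype(np.uint8)


def predict_labelmap(network: Network, volume: ImageVolume, batch_size: int = 16) -> LabelVolume:
    """Slice-wise segmentation of a whole volume into a label map."""
    if not isinstance(volume, ImageVolume):
        raise TypeError("predict_labelmap needs an ImageVolume (spacing metadata required)")
    nz = volume.shape[0]
    config = network.config
    out = np.empty(volume.shape, dtype=np.uint8)
    for start in range(0, nz, batch_size):
        stop = min(start + batch_size, nz)
        x = volume.voxels[start:stop, None, :, :]
        if isinstance(network, SCUNet):
            pos = np.stack(
                [
                    spatial_encoding(z, nz, config.spatial_nodes).vector
                    for z in range(start, stop)
                ]
            )
            probs = network.predict_proba(x, pos)
        else:
            probs = network.predict_proba(x)
        out[start:stop] = _argmax_to_class(probs, config)
    return LabelVolume(out, volume.spacing, origin_offset=volume.origin_offset)
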