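"""A small, fully inspectable convolutional network in numpy.

The network is a declarative stack of convolution / ReLU / max-pool / dense
layers with reproducible Xavier-normal weights. It exists as a test surface:
receptive-field arithmetic is derivable from the layer spec, the forward
pass records everything the deconvolution pass needs (pooling switches,
ReLU masks), and a purely linear instance has an analytic adjoint to check
the backward reconstruction against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._rng import rng_for


@dataclass
class ConvLayer:
    weights: np.ndarray  # (out_c, in_c, k, k)
    bias: np.ndarray  # (out_c,)
    stride: int = 1
    padding: int = 0
    relu: bool = True
    name: str = "conv"

    @property
    def kernel_size(self) -> int:
        return self.weights.shape[2]


@dataclass
class MaxPoolLayer:
    size: int = 2
    stride: int = 2
    relu: bool = False
    name: str = "pool"


@dataclass
class FlattenLayer:
    relu: bool = False
    name: str = "flatten"


@dataclass
class DenseLayer:
    weights: np.ndarray  # (out, in)
    bias: np.ndarray
    relu: bool = True
    name: str = "fc"


@dataclass
class ToyConvNetSpec:
    """Layer stack + input geometry; weights reproducible from ``seed``."""

    layers: list
    input_size: int
    input_channels: int = 3
    seed: int = 0

    @property
    def layer_names(self) -> list:
        return [lyr.name for lyr in self.layers]

    def layer_index(self, name: str) -> int:
        return self.layer_names.index(name)


def xavier_normal(shape, fan_in: int, fan_out: int, rng) -> np.ndarray:
    """Glorot-normal weights: std = sqrt(2 / (fan_in + fan_out))."""
    return rng.standard_normal(shape) * np.sqrt(2.0 / (fan_in + fan_out))


def build_toy_convnet(
    depth: int = 3,
    seed: int = 0,
    init: str = "xavier_normal",
    input_size: int = 32,
    input_channels: int = 3,
    channels: int = 8,
    n_classes: int = 10,
    relu: bool = True,
) -> ToyConvNetSpec:
    """Small convnet: ``depth`` 3x3 stride-1 convolutions, one 2x2 max-pool,
    one fully connected readout.

    ``init='fixed'`` fills kernels with a deterministic ramp (handy for
    closed-form checks); ``relu=False`` yields a purely linear network whose
    deconvolution equals the analytic adjoint.
    """
    if init not in ("xavier_normal", "fixed"):
        raise ValueError(f"unknown init {init!r}")
    rng = rng_for(seed, "toy_convnet")
    layers = []
    in_c, side = input_channels, input_size
    for d in range(depth):
        k = 3
        shape = (channels, in_c, k, k)
        fan_in, fan_out = in_c * k * k, channels * k * k
        if init == "xavier_normal":
            w = xavier_normal(shape, fan_in, fan_out, rng)
        else:
            w = (np.arange(np.prod(shape), dtype=float).reshape(shape) % 7 - 3) / 10.0
        layers.append(ConvLayer(w, np.zeros(channels), stride=1, padding=1, relu=relu,
                                name=f"conv{d + 1}"))
        in_c = channels
    layers.append(MaxPoolLayer(2, 2, name="pool1"))
    side = input_size // 2
    layers.append(FlattenLayer(name="flatten"))
    n_feat = in_c * side * side
    if init == "xavier_normal":
        wfc = xavier_normal((n_classes, n_feat), n_feat, n_classes, rng)
    else:
        wfc = (np.arange(n_classes * n_feat, dtype=float).reshape(n_classes, n_feat) % 5 - 2) / 50.0
    layers.append(DenseLayer(wfc, np.zeros(n_classes), relu=False, name="fc1"))
    return ToyConvNetSpec(layers, input_size, input_channels, seed)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

@dataclass
class ForwardPass:
    """Per-layer outputs plus the caches the backward pass needs."""

    spec: ToyConvNetSpec
    input: np.ndarray
    outputs: list  # post-ReLU output per layer
    relu_masks: list  # pre-ReLU > 0 mask (None where no ReLU)
    pool_switches: list  # argmax index per pooling window (None elsewhere)

    def activation(self, layer: int | str, unit) -> float:
        """Activation of one unit; ``unit`` is (channel, i, j) or a flat index."""
        li = self.spec.layer_index(layer) if isinstance(layer, str) else layer
        out = self.outputs[li]
        if np.isscalar(unit) or isinstance(unit, (int, np.integer)):
            return float(out.reshape(-1)[int(unit)])
        return float(out[tuple(unit)])


def _conv_forward(x: np.ndarray, lyr: ConvLayer) -> np.ndarray:
    p, s = lyr.padding, lyr.stride
    xp = np.pad(x, ((0, 0), (p, p), (p, p))) if p else x
    win = sliding_window_view(xp, (lyr.kernel_size, lyr.kernel_size), axis=(1, 2))
    win = win[:, ::s, ::s]
    return np.einsum("cijuv,ocuv->oij", win, lyr.weights) + lyr.bias[:, None, None]


def _pool_forward(x: np.ndarray, lyr: MaxPoolLayer):
    win = sliding_window_view(x, (lyr.size, lyr.size), axis=(1, 2))[:, :: lyr.stride, :: lyr.stride]
    flat = win.reshape(*win.shape[:3], -1)
    switches = flat.argmax(axis=3)
    return flat.max(axis=3), switches


def forward(spec: ToyConvNetSpec, image: np.ndarray) -> ForwardPass:
    """Run the network on one image (channels x H x W or H x W x channels)."""
    x = np.asarray(image, dtype=float)
    if x.ndim == 2:
        x = x[None]
    elif x.ndim == 3 and x.shape[2] == spec.input_channels and x.shape[0] != spec.input_channels:
        x = x.transpose(2, 0, 1)
    if x.shape != (spec.input_channels, spec.input_size, spec.input_size):
        raise ValueError(f"expected input {spec.input_channels}x{spec.input_size}^2, got {x.shape}")
    outputs, masks, switches = [], [], []
    cur = x
    for lyr in spec.layers:
        sw = None
        if isinstance(lyr, ConvLayer):
            cur = _conv_forward(cur, lyr)
        elif isinstance(lyr, MaxPoolLayer):
            cur, sw = _pool_forward(cur, lyr)
        elif isinstance(lyr, FlattenLayer):
            cur = cur.reshape(-1)
        elif isinstance(lyr, DenseLayer):
            cur = lyr.weights @ cur + lyr.bias
        else:
            raise TypeError(f"unknown layer {lyr!r}")
        mask = None
        if lyr.relu:
            mask = cur > 0
            cur = np.where(mask, cur, 0.0)
        outputs.append(cur)
        masks.append(mask)
        switches.append(sw)
    return ForwardPass(spec, x, outputs, masks, switches)


# ---------------------------------------------------------------------------
# receptive-field arithmetic
# ---------------------------------------------------------------------------

def receptive_field(spec: ToyConvNetSpec, layer: int | str, i: int, j: int) -> tuple:
    """Input-pixel bounding box (top, left, height, width) seen by unit (i, j).

    Propagates the index range backward through the stack; convolution with
    kernel k, stride s, padding p maps range [a, b] to
    [a·s − p, b·s − p + k − 1], clipped to the input raster.
    """
    li = spec.layer_index(layer) if isinstance(layer, str) else layer
    a_i = b_i = i
    a_j = b_j = j
    for lyr in reversed(spec.layers[: li + 1]):
        if isinstance(lyr, (ConvLayer, MaxPoolLayer)):
            k = lyr.kernel_size if isinstance(lyr, ConvLayer) else lyr.size
            p = lyr.padding if isinstance(lyr, ConvLayer) else 0
            s = lyr.stride
            a_i, b_i = a_i * s - p, b_i * s - p + k - 1
            a_j, b_j = a_j * s - p, b_j * s - p + k - 1
        elif isinstance(lyr, (FlattenLayer, DenseLayer)):
            raise ValueError("receptive_field applies to spatial layers only")
    n = spec.input_size
    a_i, b_i = max(a_i, 0), min(b_i, n - 1)
    a_j, b_j = max(a_j, 0), min(b_j, n - 1)
    return a_i, a_j, b_i - a_i + 1, b_j - a_j + 1
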