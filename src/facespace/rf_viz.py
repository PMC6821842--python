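"""Receptive-field visualization: deconvolution and activation maximization.

Deconvolution propagates a single unit's activation backward to image space
— every other unit in the layer zeroed — through transposed convolutions,
unpooling with the switches recorded on the forward pass, and the deconvnet
ReLU rule (backward signal masked by the forward activation pattern). For a
purely linear network this is exactly the adjoint operator applied to the
unit's indicator, so the reconstruction has a closed form to test against.

Activation maximization applies deconvolution iteratively: each iteration
adds the reconstruction, scaled by a learning rate, to the current image and
re-runs the forward pass. The stored delta (altered − original image) shows
what was added to drive the unit; contrast stretching is applied only when
rendering, never to stored arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .convnet import (
    ConvLayer,
    DenseLayer,
    FlattenLayer,
    ForwardPass,
    MaxPoolLayer,
    ToyConvNetSpec,
    forward,
)


@dataclass
class RFImage:
    """A unit's receptive-field visualization on one base image."""

    base: np.ndarray  # input image, channels x H x W
    reconstruction: np.ndarray  # back-projected unit activation, same raster
    delta: np.ndarray | None = None  # altered − original (activation maximization)
    contrast_stretch: bool = True  # display-time only

    def render(self, array: np.ndarray | None = None) -> np.ndarray:
        """8-bit render (H x W x C); stretches the active range if enabled."""
        arr = self.reconstruction if array is None else array
        img = np.asarray(arr, dtype=float)
        if self.contrast_stretch:
            lo, hi = img.min(), img.max()
            img = (img - lo) / (hi - lo) * 255.0 if hi > lo else np.zeros_like(img)
        out = np.clip(np.round(img), 0, 255).astype(np.uint8)
        return out.transpose(1, 2, 0) if out.ndim == 3 else out

    def save_png(self, path, which: str = "reconstruction") -> None:
        from PIL import Image

        arr = {"base": self.base, "reconstruction": self.reconstruction, "delta": self.delta}[which]
        Image.fromarray(self.render(arr)).save(path)


def _conv_backward(g: np.ndarray, lyr: ConvLayer, in_shape) -> np.ndarray:
    c, h, w = in_shape
    p, s, k = lyr.padding, lyr.stride, lyr.kernel_size
    xg = np.zeros((c, h + 2 * p, w + 2 * p))
    ho, wo = g.shape[1:]
    for di in range(k):
        for dj in range(k):
            contrib = np.einsum("oc,oij->cij", lyr.weights[:, :, di, dj], g)
            xg[:, di : di + s * ho : s, dj : dj + s * wo : s] += contrib
    return xg[:, p : p + h, p : p + w] if p else xg


def _pool_backward(g: np.ndarray, lyr: MaxPoolLayer, switches: np.ndarray, in_shape) -> np.ndarray:
    xg = np.zeros(in_shape)
    c, ho, wo = g.shape
    ci, io, jo = np.meshgrid(np.arange(c), np.arange(ho), np.arange(wo), indexing="ij")
    ii = io * lyr.stride + switches // lyr.size
    jj = jo * lyr.stride + switches % lyr.size
    np.add.at(xg, (ci, ii, jj), g)
    return xg


def backproject(fp: ForwardPass, layer: int | str, seed_tensor: np.ndarray) -> np.ndarray:
    """Propagate a layer-space tensor back to image space (deconvnet rules)."""
    spec = fp.spec
    li = spec.layer_index(layer) if isinstance(layer, str) else layer
    g = np.asarray(seed_tensor, dtype=float)
    for l in range(li, -1, -1):
        lyr = spec.layers[l]
        if lyr.relu:
            g = g * fp.relu_masks[l]
        in_shape = fp.outputs[l - 1].shape if l > 0 else fp.input.shape
        if isinstance(lyr, ConvLayer):
            g = _conv_backward(g, lyr, in_shape)
        elif isinstance(lyr, MaxPoolLayer):
            g = _pool_backward(g, lyr, fp.pool_switches[l], in_shape)
        elif isinstance(lyr, FlattenLayer):
            g = g.reshape(in_shape)
        elif isinstance(lyr, DenseLayer):
            g = lyr.weights.T @ g
    return g


def _seed_tensor(fp: ForwardPass, li: int, unit, seed_value) -> np.ndarray:
    out = np.zeros_like(fp.outputs[li])
    value = fp.activation(li, unit) if seed_value is None else float(seed_value)
    if np.isscalar(unit) or isinstance(unit, (int, np.integer)):
        out.reshape(-1)[int(unit)] = value
    else:
        out[tuple(unit)] = value
    return out


def deconvolve_unit(
    spec: ToyConvNetSpec,
    image: np.ndarray,
    layer: int | str,
    unit,
    seed_value: float | None = None,
) -> RFImage:
    """Back-project one unit's activation to image space.

    ``unit`` is (channel, i, j) for spatial layers or a flat index; fully
    connected units back-project through the dense weights (their 1x1 spatial
    interpretation). ``seed_value`` overrides the propagated activation
    (use 1.0 for a unit-impulse reconstruction).
    """
    fp = forward(spec, image)
    li = spec.layer_index(layer) if isinstance(layer, str) else layer
    recon = backproject(fp, li, _seed_tensor(fp, li, unit, seed_value))
    return RFImage(fp.input, recon)


def activation_maximization(
    spec: ToyConvNetSpec,
    image: np.ndarray,
    layer: int | str,
    unit,
    n_iter: int = 300,
    lr: float = 200.0,
) -> tuple[RFImage, np.ndarray]:
    """Iteratively amplify one unit's response by adding its deconvolution.

    Each iteration deconvolves the unit's current activation and adds
    ``lr`` times the reconstruction to the image; the image is *not*
    re-clipped to [0, 255] during the ascent (the stored delta needs the
    unbounded values). Returns the RF image (with delta = altered − original)
    and the per-iteration activation trace (length ``n_iter + 1``, final
    activation last).
    """
    fp = forward(spec, image)
    li = spec.layer_index(layer) if isinstance(layer, str) else layer
    base = fp.input.copy()
    img = base.copy()
    trace = np.empty(n_iter + 1)
    recon = np.zeros_like(img)
    for it in range(n_iter):
        trace[it] = fp.activation(li, unit)
        recon = backproject(fp, li, _seed_tensor(fp, li, unit, None))
        with np.errstate(over="ignore", invalid="ignore"):
            img = img + lr * recon
        if not np.isfinite(img).all():
            raise FloatingPointError(f"activation maximization overflowed at iteration {it}")
        fp = forward(spec, img)
    trace[n_iter] = fp.activation(li, unit)
    return RFImage(base, recon, delta=img - base), trace
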