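"""3D U-net for hypothalamus subunit segmentation.

The default architecture follows the configuration that performed best for
this task: three resolution levels, two 3x3x3 convolutions per level with 24
kernels at the top (doubled after each max-pooling, halved after each
up-convolution), batch normalisation after each convolution, ELU activations
everywhere, transposed-convolution upsampling, skip concatenations between
paths, and a final 1x1x1 convolution with softmax over the 11 labels.

The network runs on the engine in :mod:`hypothseg._nn`; ``predict_soft``
pads any input symmetrically to the pooling divisibility constraint and
crops the probabilities back, so the output grid always matches the input.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _nn
from .io import HYPOTHALAMUS_TAXONOMY, LabelTaxonomy, SoftLabelMap, Volume

__all__ = ["UNetSpec", "UNet3D", "build_unet", "predict_soft", "save_checkpoint", "load_checkpoint"]


@dataclass
class UNetSpec:
    """Architecture hyperparameters of the 3D U-net."""

    levels: int = 3
    base_features: int = 24
    convs_per_level: int = 2
    kernel_size: tuple[int, int, int] = (3, 3, 3)
    activation: str = "elu"
    batch_norm: bool = True
    n_labels: int = 11

    def __post_init__(self) -> None:
        if isinstance(self.kernel_size, int):
            self.kernel_size = (self.kernel_size,) * 3
        self.kernel_size = tuple(int(k) for k in self.kernel_size)
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_features < 1:
            raise ValueError("base_features must be >= 1")
        if self.n_labels < 2:
            raise ValueError("n_labels must be >= 2")
        if self.activation.lower() != "elu":
            raise ValueError("only the ELU activation is supported")

    def features_at(self, level: int) -> int:
        """Feature maps at contracting-path level k: base * 2**k."""
        return self.base_features * (2 ** level)

    @property
    def divisor(self) -> int:
        """Input spatial sizes must be divisible by this (padding enforces it)."""
        return 2 ** (self.levels - 1)


class _ConvBlock:
    """conv -> [batch norm] -> ELU, repeated convs_per_level times."""

    def __init__(self, in_ch: int, out_ch: int, spec: UNetSpec, rng):
        self.layers: list = []
        ch = in_ch
        for _ in range(spec.convs_per_level):
            self.layers.append(_nn.Conv3d(ch, out_ch, spec.kernel_size, rng))
            if spec.batch_norm:
                self.layers.append(_nn.BatchNorm3d(out_ch))
            self.layers.append(_nn.ELU())
            ch = out_ch

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class UNet3D:
    """Trainable 3D U-net exposing pre-softmax and softmax forward passes."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        s = spec
        self.enc = []
        self.pools = []
        ch = 1
        for level in range(s.levels - 1):
            out = s.features_at(level)
            self.enc.append(_ConvBlock(ch, out, s, rng))
            self.pools.append(_nn.MaxPool3d())
            ch = out
        self.bottleneck = _ConvBlock(ch, s.features_at(s.levels - 1), s, rng)
        self.ups = []
        self.dec = []
        ch = s.features_at(s.levels - 1)
        for level in range(s.levels - 2, -1, -1):
            out = s.features_at(level)
            self.ups.append(_nn.ConvTranspose3d(ch, out, rng))
            self.dec.append(_ConvBlock(2 * out, out, s, rng))
            ch = out
        self.head = _nn.Conv3d(ch, s.n_labels, (1, 1, 1), rng)
        self._skip_channels: list[int] = [s.features_at(l) for l in range(s.levels - 1)]

    # -- graph traversal ---------------------------------------------------

    def _all_layers(self):
        for block in self.enc:
            yield from block.layers
        yield from self.pools
        yield from self.bottleneck.layers
        yield from self.ups
        for block in self.dec:
            yield from block.layers
        yield self.head

    def parameters(self):
        """Flat (value, gradient) pairs across all layers, in graph order."""
        return [(v, g) for layer in self._all_layers() for _, v, g in layer.parameters()]

    def zero_grad(self):
        for layer in self._all_layers():
            layer.zero_grad()

    def forward_logits(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """Pre-softmax activations, shape (n_labels, D, H, W).

        ``x`` is a (D, H, W) or (1, D, H, W) float array whose spatial sizes
        must be divisible by ``spec.divisor``.
        """
        if x.ndim == 3:
            x = x[None]
        if any(d % self.spec.divisor for d in x.shape[1:]):
            raise ValueError(
                f"spatial sizes {x.shape[1:]} not divisible by {self.spec.divisor}; "
                "use predict_soft for automatic padding"
            )
        x = x.astype(np.float32)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, training)
            x = np.concatenate([skip, x], axis=0)
            x = block.forward(x, training)
        return self.head.forward(x, training)

    def forward_proba(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Softmax probabilities, shape (n_labels, D, H, W)."""
        return softmax_channels(self.forward_logits(x, training))

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from the loss gradient at the head."""
        g = self.head.backward(dlogits)
        skip_grads = []
        for up, block in zip(reversed(self.ups), reversed(self.dec)):
            g = block.backward(g)
            n_skip = g.shape[0] // 2
            skip_grads.append(g[:n_skip])
            g = up.backward(g[n_skip:])
        g = self.bottleneck.backward(g)
        # skip_grads were collected shallow-to-deep; the encoder unwinds deep-to-shallow
        for block, pool, gs in zip(
            reversed(self.enc), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g)
            g = g + gs
            g = block.backward(g)


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the leading (channel) axis."""
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def build_unet(spec: UNetSpec | None = None, seed: int = 0) -> UNet3D:
    """Construct a randomly initialised U-net from an architecture spec."""
    return UNet3D(spec or UNetSpec(), seed=seed)


def predict_soft(
    net: UNet3D,
    v: Volume,
    taxonomy: LabelTaxonomy = HYPOTHALAMUS_TAXONOMY,
    normalize: bool = True,
) -> SoftLabelMap:
    """Segment a volume into a per-voxel probability map.

    The image is min-max normalised (unless already in [0, 1] and
    ``normalize`` is False), padded symmetrically to the pooling divisor,
    run through the network in evaluation mode, and the softmax output is
    cropped back to the input grid.
    """
    if v.data.ndim != 3:
        raise ValueError("predict_soft expects a 3D volume")
    if len(taxonomy) != net.spec.n_labels:
        raise ValueError("taxonomy size does not match the network output channels")
    data = v.data.astype(np.float32)
    if normalize or data.min() < 0 or data.max() > 1:
        lo, hi = float(data.min()), float(data.max())
        data = np.zeros_like(data) if hi == lo else (data - lo) / (hi - lo)
    div = net.spec.divisor
    pads = []
    for s in data.shape:
        extra = (-s) % div
        pads.append((extra // 2, extra - extra // 2))
    padded = np.pad(data, pads, mode="edge")
    proba = net.forward_proba(padded, training=False)
    sl = tuple(slice(p0, p0 + s) for (p0, _), s in zip(pads, data.shape))
    proba = np.moveaxis(proba, 0, -1)[sl]
    return SoftLabelMap(np.ascontiguousarray(proba), taxonomy, v.voxel_size, v.affine)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(net: UNet3D, path) -> None:
    """Persist architecture spec, weights and normalisation buffers (.npz)."""
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(net._all_layers()):
        for name, val, _ in layer.parameters():
            arrays[f"param_{i}_{name}"] = val
        for name, val in layer.state().items():
            arrays[f"state_{i}_{name}"] = val
    meta = asdict(net.spec)
    meta["kernel_size"] = list(meta["kernel_size"])
    np.savez(Path(path), __spec__=np.array([json.dumps(meta)]), **arrays)


def load_checkpoint(path) -> UNet3D:
    """Rebuild a network from :func:`save_checkpoint` output."""
    with np.load(Path(path), allow_pickle=False) as f:
        meta = json.loads(str(f["__spec__"][0]))
        spec = UNetSpec(**{**meta, "kernel_size": tuple(meta["kernel_size"])})
        net = UNet3D(spec)
        for i, layer in enumerate(net._all_layers()):
            for name, val, _ in layer.parameters():
                val[...] = f[f"param_{i}_{name}"]
            for name, val in layer.state().items():
                val[...] = f[f"state_{i}_{name}"]
    return net
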