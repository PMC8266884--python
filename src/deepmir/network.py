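"""The segmentation network: a 2D U-Net with padded convolutions.

The default architecture operates on six spatial resolutions — five
analysis (down-sampling) stages of two 3x3 conv + BatchNorm + ReLU layers
followed by 2x2 max pooling, a central block, and five synthesis stages of
a 2x2 stride-2 transpose convolution, concatenation with the matching
analysis feature map, and two further conv-BN-ReLU layers.  With padded
convolutions a 256x256 input stays 256x256 throughout each resolution and
the central block sees an 8x8 map; the extra (sixth) resolution relative to
the classic U-Net is what lets the model resolve very small lesions.

Two baseline variants are provided: a 5-resolution version (16x16 central
map at 256x256 input) and the original unpadded U-Net, whose valid
convolutions shrink the output (572 -> 388 in the classic configuration);
for the unpadded variant skip feature maps are center-cropped before
concatenation and labels must be center-cropped to the output size.

Heads: single-class = 1x1 conv + sigmoid; multiclass = 1x1 conv + ReLU +
softmax.  The ReLU before the softmax is unconventional (it zeroes negative
logits) but is the multiclass head this architecture specifies; a flag
allows a plain softmax head for ablation.  Training uses cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_types import ValidationError
from . import nn


@dataclass
class NetworkSpec:
    n_resolutions: int = 6
    in_channels: int = 1
    head: str = "sigmoid_single"  # "sigmoid_single" | "softmax_multi"
    n_classes: int = 3
    base_width: int = 64
    max_width: int = 1024
    padded: bool = True
    relu_before_softmax: bool = True
    #: initial bias of the head convolution, favouring the (rare) lesion
    #: classes.  Lesion pixels are a tiny fraction of each slice; starting
    #: the head away from the all-background solution forces the network to
    #: learn discriminative features before it can suppress lesion pixels,
    #: which prevents collapse to "predict nothing" on short training runs.
    head_bias_init: float = 2.0

    def __post_init__(self) -> None:
        if self.n_resolutions < 2:
            raise ValidationError("n_resolutions must be >= 2")
        if self.in_channels < 1:
            raise ValidationError("in_channels must be >= 1")
        if self.head not in ("sigmoid_single", "softmax_multi"):
            raise ValidationError(f"unknown head {self.head!r}")
        if self.head == "softmax_multi" and self.n_classes < 2:
            raise ValidationError("softmax_multi requires n_classes >= 2")

    @property
    def out_channels(self) -> int:
        return 1 if self.head == "sigmoid_single" else self.n_classes

    def widths(self) -> list:
        return [min(self.base_width * 2**i, self.max_width)
                for i in range(self.n_resolutions)]


def output_size(spec: NetworkSpec, input_size: int) -> int:
    """Spatial output size for a square input (closed-form size arithmetic).

    Padded network: identity (input must be divisible by 2^(n_res - 1)).
    Unpadded: each conv pair shrinks by 4, pooling halves, transpose conv
    doubles — the classic 572 -> 388 shrinkage.
    """
    r = spec.n_resolutions
    if spec.padded:
        if input_size % 2 ** (r - 1) != 0:
            raise ValidationError(
                f"input size {input_size} not divisible by {2**(r-1)}"
            )
        return input_size
    s = input_size
    for _ in range(r - 1):
        s -= 4
        if s <= 0 or s % 2 != 0:
            raise ValidationError(f"input size {input_size} invalid for unpadded net")
        s //= 2
    s -= 4  # central block
    if s <= 0:
        raise ValidationError(f"input size {input_size} invalid for unpadded net")
    for _ in range(r - 1):
        s = 2 * s - 4
        if s <= 0:
            raise ValidationError(f"input size {input_size} invalid for unpadded net")
    return s


def central_size(spec: NetworkSpec, input_size: int) -> int:
    """Spatial size of the feature map entering the central block."""
    s = input_size
    for _ in range(spec.n_resolutions - 1):
        if not spec.padded:
            s -= 4
        s //= 2
    return s


class _ConvBlock:
    """Two (conv 3x3 -> BN -> ReLU) layers."""

    def __init__(self, in_c, out_c, padded, rng, dtype):
        pad = 1 if padded else 0
        self.layers = [
            nn.Conv2d(in_c, out_c, k=3, pad=pad, rng=rng, dtype=dtype),
            nn.BatchNorm2d(out_c, dtype=dtype),
            nn.ReLU(),
            nn.Conv2d(out_c, out_c, k=3, pad=pad, rng=rng, dtype=dtype),
            nn.BatchNorm2d(out_c, dtype=dtype),
            nn.ReLU(),
        ]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


class UNet:
    """U-Net assembled from :mod:`deepmir.nn` layers.

    ``forward`` returns raw logits; ``predict_proba`` applies the head
    nonlinearity in eval mode.  After any forward pass
    ``central_spatial_shape`` holds the spatial size that entered the
    central block.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        w = spec.widths()
        r = spec.n_resolutions
        self.down_blocks = []
        in_c = spec.in_channels
        for i in range(r - 1):
            self.down_blocks.append(_ConvBlock(in_c, w[i], spec.padded, rng, dtype))
            in_c = w[i]
        self.pools = [nn.MaxPool2x2() for _ in range(r - 1)]
        self.center = _ConvBlock(w[r - 2], w[r - 1], spec.padded, rng, dtype)
        self.up_tconvs = []
        self.up_blocks = []
        for i in reversed(range(r - 1)):
            self.up_tconvs.append(nn.ConvTranspose2x2(
                w[i + 1], w[i], rng=rng, dtype=dtype))
            self.up_blocks.append(_ConvBlock(2 * w[i], w[i], spec.padded, rng, dtype))
        self.head_conv = nn.Conv2d(w[0], spec.out_channels, k=1, pad=0,
                                   rng=rng, dtype=dtype)
        if spec.head_bias_init:
            b = self.head_conv.params["b"]
            if spec.head == "sigmoid_single":
                b[:] = spec.head_bias_init
            else:
                b[0] = -spec.head_bias_init  # depress the background class
        self.central_spatial_shape = None

    # -- plumbing -----------------------------------------------------------

    def layers(self) -> list:
        out = []
        for blk in self.down_blocks + [self.center] + self.up_blocks:
            out.extend(blk.layers)
        out.extend(self.up_tconvs)
        out.append(self.head_conv)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers() for p in l.params.values())

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x):
        if x.ndim != 4:
            raise ValidationError("expected a (B, C, H, W) batch")
        if x.shape[1] != self.spec.in_channels:
            raise ValidationError(
                f"batch has {x.shape[1]} channels, spec expects {self.spec.in_channels}"
            )
        if x.shape[2] != x.shape[3]:
            raise ValidationError("only square inputs are supported")
        output_size(self.spec, x.shape[2])  # raises if invalid

    def forward(self, x, training=False):
        """Raw logits (B, K, H', W')."""
        x = np.asarray(x, dtype=self.dtype)
        self._check_input(x)
        skips = []
        self._crop_offsets = []
        for blk, pool in zip(self.down_blocks, self.pools):
            x = blk.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        self.central_spatial_shape = x.shape[2:]
        x = self.center.forward(x, training)
        self._skip_shapes = []
        for tconv, blk in zip(self.up_tconvs, self.up_blocks):
            x = tconv.forward(x, training)
            s = skips.pop()
            self._skip_shapes.append(s.shape)
            if s.shape[2:] != x.shape[2:]:  # unpadded: center-crop the skip
                oh = (s.shape[2] - x.shape[2]) // 2
                ow = (s.shape[3] - x.shape[3]) // 2
                self._crop_offsets.append((oh, ow))
                s = s[:, :, oh:oh + x.shape[2], ow:ow + x.shape[3]]
            else:
                self._crop_offsets.append((0, 0))
            x = np.concatenate([s, x], axis=1)
            x = blk.forward(x, training)
        return self.head_conv.forward(x, training)

    def backward(self, glogits):
        g = self.head_conv.backward(glogits)
        gskips = []
        for i in reversed(range(len(self.up_blocks))):
            g = self.up_blocks[i].backward(g)
            shape = self._skip_shapes[i]
            nskip = shape[1]
            gs, g = g[:, :nskip], g[:, nskip:]
            oh, ow = self._crop_offsets[i]
            if (oh, ow) != (0, 0) or gs.shape[2:] != shape[2:]:
                full = np.zeros(shape, dtype=gs.dtype)
                full[:, :, oh:oh + gs.shape[2], ow:ow + gs.shape[3]] = gs
                gs = full
            gskips.append(gs)
            g = self.up_tconvs[i].backward(g)
        g = self.center.backward(g)
        for i in reversed(range(len(self.down_blocks))):
            g = self.pools[i].backward(g)
            g = g + gskips[i]
            g = self.down_blocks[i].backward(g)
        return g

    # -- inference ----------------------------------------------------------

    def predict_proba(self, x):
        """Head probabilities in eval mode.

        Single-class: (B, 1, H, W) sigmoid map in [0, 1].  Multiclass:
        (B, K, H, W) class probabilities summing to 1 per pixel.
        """
        logits = self.forward(x, training=False)
        if self.spec.head == "sigmoid_single":
            return nn.sigmoid(logits)
        z = np.maximum(logits, 0) if self.spec.relu_before_softmax else logits
        return nn.softmax(z, axis=1)

    def train_loss(self, x, target):
        """Forward in training mode, compute loss, backprop. Returns loss."""
        logits = self.forward(x, training=True)
        if self.spec.head == "sigmoid_single":
            loss, grad = nn.bce_with_logits(logits[:, 0], target)
            self.backward(grad[:, None])
        else:
            if target.max() >= self.spec.n_classes or target.min() < 0:
                raise ValidationError("target class outside [0, n_classes)")
            loss, grad = nn.softmax_ce_with_logits(
                logits, target, relu_first=self.spec.relu_before_softmax)
            self.backward(grad)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss: {loss}")
        return loss


def build_network(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> UNet:
    return UNet(spec, seed=seed, dtype=dtype)


def prediction_loss(pred, target, head: str) -> float:
    """Cross-entropy of predicted *probabilities* against a target map.

    Single-class: mean binary cross-entropy of ``pred`` in [0, 1] against a
    binary target.  Multiclass: mean categorical cross-entropy of a
    (K, ...) or (B, K, ...) probability stack against an integer class map.
    Probabilities are clamped away from {0, 1} for finiteness.
    """
    eps = 1e-12
    if head == "sigmoid_single":
        p = np.clip(np.asarray(pred, dtype=np.float64), eps, 1 - eps)
        t = np.asarray(target, dtype=np.float64)
        return float(-np.mean(t * np.log(p) + (1 - t) * np.log(1 - p)))
    if head == "softmax_multi":
        p = np.asarray(pred, dtype=np.float64)
        axis = 0 if p.ndim == target.ndim + 1 and p.shape[1:] == target.shape else 1
        idx = np.asarray(target, dtype=np.int64)
        if idx.max() >= p.shape[axis] or idx.min() < 0:
            raise ValidationError("target class outside [0, n_classes)")
        picked = np.take_along_axis(p, np.expand_dims(idx, axis), axis=axis)
        return float(-np.mean(np.log(np.clip(picked, eps, None))))
    raise ValidationError(f"unknown head {head!r}")


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(net: UNet, path, meta: dict | None = None) -> Path:
    """Save spec + weights + BN running stats (+ optional metadata)."""
    import dataclasses as _dc
    import json as _json

    arrays = {}
    for i, layer in enumerate(net.layers()):
        for k, v in layer.params.items():
            arrays[f"p_{i}_{k}"] = v
        if isinstance(layer, nn.BatchNorm2d):
            arrays[f"s_{i}_rm"] = layer.running_mean
            arrays[f"s_{i}_rv"] = layer.running_var
    spec_json = _json.dumps(_dc.asdict(net.spec))
    meta_json = _json.dumps(meta or {})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __spec__=spec_json, __meta__=meta_json, **arrays)
    return path


def load_checkpoint(path):
    """Rebuild a network from :func:`save_checkpoint` output."""
    import json as _json

    data = np.load(path, allow_pickle=False)
    spec = NetworkSpec(**_json.loads(str(data["__spec__"])))
    meta = _json.loads(str(data["__meta__"]))
    net = UNet(spec)
    for i, layer in enumerate(net.layers()):
        for k in layer.params:
            layer.params[k] = data[f"p_{i}_{k}"].copy()
        if isinstance(layer, nn.BatchNorm2d):
            layer.running_mean = data[f"s_{i}_rm"].copy()
            layer.running_var = data[f"s_{i}_rv"].copy()
    return net, meta
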