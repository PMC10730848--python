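"""The three encoder-decoder backbone paths of the fusion network.

Each path maps a 1-channel image (N,1,H,W), H and W multiples of 8, through
four feature levels (level i at spatial size H/2^(i-1); three downsamplings
in total) and back to full resolution:

* **U-Net path** (spatial features): max-pool downsampling, transposed-conv
  upsampling, skip concatenation of the same-level encoder feature.
* **SegNet path** (boundary features): max-pool downsampling that records
  the argmax position of every 2x2 window; the decoder upsamples by placing
  values back at those recorded positions (max-unpooling), which preserves
  edge localisation.  No skip concatenation.
* **Haar path** (frequency features): downsampling by the orthonormal Haar
  analysis (channel count x4, resolution /2) and upsampling by the exact
  synthesis transform, with skip concatenation of the pre-analysis feature.

All paths are built from the shared CBR2 block: two rounds of 3x3
convolution + batch normalisation + ReLU, size-preserving.

Channel bookkeeping: decoder features d_i carry width_i channels in every
path.  Where an upsampling operator constrains its input channel count
(unpooling needs the recorded indices' channel count; Haar synthesis needs
a multiple of 4 that lands on width_i), a 1x1 convolution adjusts channels
immediately before it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

DEFAULT_WIDTHS = (64, 128, 256, 512)
TINY_WIDTHS = (8, 16, 32, 64)


@dataclass
class PathState:
    """Per-level encoder/decoder features of one backbone path.

    ``encoder[i]``/``decoder[i]`` hold level i+1 (0-indexed list; level i at
    spatial size (H/2^i, W/2^i)).  ``pool_indices`` is populated by the
    SegNet path only.
    """

    path_id: int
    encoder: list[nn.Tensor]
    decoder: list[nn.Tensor]
    pool_indices: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, (e, d) in enumerate(zip(self.encoder, self.decoder)):
            if e.shape[-2:] != d.shape[-2:]:
                raise ValueError(
                    f"level {i + 1}: encoder {e.shape[-2:]} and decoder "
                    f"{d.shape[-2:]} spatial sizes differ"
                )


class CBR2(nn.Module):
    """Two rounds of (3x3 conv, batch norm, ReLU); spatial size preserved."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_channels, out_channels, 3, rng)
        self.bn1 = nn.BatchNorm2d(out_channels)
        self.conv2 = nn.Conv2d(out_channels, out_channels, 3, rng)
        self.bn2 = nn.BatchNorm2d(out_channels)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        x = nn.relu(self.bn1(self.conv1(x)))
        return nn.relu(self.bn2(self.conv2(x)))


def _check_input(x: nn.Tensor) -> nn.Tensor:
    x = nn.as_tensor(x)
    if x.ndim == 3:
        x = x.reshape(1, *x.shape)
    if x.ndim != 4:
        raise ValueError(f"expected (N,C,H,W) input, got shape {x.shape}")
    h, w = x.shape[-2:]
    if h % 8 or w % 8:
        raise ValueError(f"spatial size ({h},{w}) must be a multiple of 8")
    return x


class UnetPath(nn.Module):
    """Skip-connection encoder-decoder (spatial-feature path, id 1)."""

    path_id = 1

    def __init__(self, widths=DEFAULT_WIDTHS, in_channels: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        w = list(widths)
        self.widths = tuple(w)
        self.enc = [CBR2(c_in, c_out, rng) for c_in, c_out in zip([in_channels] + w[:-1], w)]
        self.bottleneck = CBR2(w[3], w[3], rng)
        self.up = [nn.ConvTranspose2x2(w[i + 1], w[i], rng) for i in range(3)]
        self.dec = [CBR2(2 * w[i], w[i], rng) for i in range(3)]

    def __call__(self, x: nn.Tensor) -> PathState:
        x = _check_input(x)
        e: list[nn.Tensor] = []
        h = x
        for i, block in enumerate(self.enc):
            if i > 0:
                h, _ = nn.max_pool2x2(h)
            h = block(h)
            e.append(h)
        d = [None] * 4
        d[3] = self.bottleneck(e[3])
        for i in (2, 1, 0):
            upped = self.up[i](d[i + 1])
            d[i] = self.dec[i](nn.concat([upped, e[i]], axis=1))
        return PathState(self.path_id, e, d)


class SegNetPath(nn.Module):
    """Pooling-index encoder-decoder (boundary-feature path, id 2)."""

    path_id = 2

    def __init__(self, widths=DEFAULT_WIDTHS, in_channels: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        w = list(widths)
        self.widths = tuple(w)
        self.enc = [CBR2(c_in, c_out, rng) for c_in, c_out in zip([in_channels] + w[:-1], w)]
        self.bottleneck = CBR2(w[3], w[3], rng)
        # 1x1 channel adjust so d_{i+1} matches the recorded indices' channels
        self.adjust = [nn.Conv2d(w[i + 1], w[i], 1, rng) for i in range(3)]
        self.dec = [CBR2(w[i], w[i], rng) for i in range(3)]

    def __call__(self, x: nn.Tensor) -> PathState:
        x = _check_input(x)
        e: list[nn.Tensor] = []
        indices: list[np.ndarray] = []
        h = x
        for i, block in enumerate(self.enc):
            if i > 0:
                h, idx = nn.max_pool2x2(h)
                indices.append(idx)
            h = block(h)
            e.append(h)
        d = [None] * 4
        d[3] = self.bottleneck(e[3])
        for i in (2, 1, 0):
            t = self.adjust[i](d[i + 1])
            up = nn.max_unpool2x2(t, indices[i])
            d[i] = self.dec[i](up)
        return PathState(self.path_id, e, d, pool_indices=indices)


class HaarPath(nn.Module):
    """Wavelet encoder-decoder (frequency-feature path, id 3).

    Encoder: g_i = CBR2(e_i); e_{i+1} = Concat[DWT(g_i)] for levels 1..3.
    Bottleneck: d_4 = CBR2(e_4).  Decoder: g_i' = IDWT[Split(d_{i+1})] after
    a 1x1 channel adjust to 4*width_i; d_i = CBR2(Concat(g_i', g_i)).
    """

    path_id = 3

    def __init__(self, widths=DEFAULT_WIDTHS, in_channels: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        w = list(widths)
        self.widths = tuple(w)
        # g_i blocks: e_i channel counts are [in, 4*w1, 4*w2]; g_i has w_i
        self.g = [CBR2(c_in, c_out, rng)
                  for c_in, c_out in zip([in_channels, 4 * w[0], 4 * w[1]], w[:3])]
        self.bottleneck = CBR2(4 * w[2], w[3], rng)
        self.adjust = [nn.Conv2d(w[i + 1], 4 * w[i], 1, rng) for i in range(3)]
        self.dec = [CBR2(2 * w[i], w[i], rng) for i in range(3)]

    def __call__(self, x: nn.Tensor) -> PathState:
        x = _check_input(x)
        e: list[nn.Tensor] = [x]
        g: list[nn.Tensor] = []
        h = x
        for i in range(3):
            gi = self.g[i](h)
            g.append(gi)
            h = nn.haar_down(gi)
            e.append(h)
        d = [None] * 4
        d[3] = self.bottleneck(e[3])
        for i in (2, 1, 0):
            gp = nn.haar_up(self.adjust[i](d[i + 1]))
            d[i] = self.dec[i](nn.concat([gp, g[i]], axis=1))
        return PathState(self.path_id, e, d)


PATH_CLASSES = {"unet": UnetPath, "segnet": SegNetPath, "haar": HaarPath}
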