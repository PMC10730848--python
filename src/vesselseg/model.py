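"""Three-path fusion segmentation model with deep supervision and an
auto-encoder reconstruction head.

The model runs up to three parallel backbone paths (spatial / boundary /
frequency; see :mod:`vesselseg.paths`) over a 1-channel image and couples
them only at the output heads:

* **Deep-supervision heads** (one per decoder level i=1..4): the enabled
  paths' decoder features D_i = [d_i^1, d_i^2, d_i^3] are concatenated,
  reduced to 2 channels by a 1x1 convolution and passed through a channel
  softmax, giving a per-level class-probability map
  u_i in R^{2 x H/2^(i-1) x W/2^(i-1)} (channel 0 = background,
  channel 1 = vessel).
* **Auto-encoder head**: the bottleneck features E_4 = [e_4^1, e_4^2,
  e_4^3] are concatenated, compressed by a 1x1 convolution and decoded by
  three 2x2 stride-2 transposed convolutions back to input resolution,
  ending in a 1x1 convolution that yields the reconstruction X^R (1, H, W).

A full forward pass returns the tuple [u_1, u_2, u_3, u_4, X^R];
``predict`` returns the vessel channel of u_1.  Heads can be switched off
(ablation presets), in which case only u_1 (and no X^R) is produced.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .paths import DEFAULT_WIDTHS, PATH_CLASSES, TINY_WIDTHS, PathState

#: ablation presets: enabled paths, deep supervision on/off, AE head on/off
PRESETS: dict[str, dict] = {
    "unet": {"paths": ("unet",), "dsl": False, "ae": False},
    "segnet": {"paths": ("segnet",), "dsl": False, "ae": False},
    "haarnet": {"paths": ("haar",), "dsl": False, "ae": False},
    "unet+segnet": {"paths": ("unet", "segnet"), "dsl": False, "ae": False},
    "unet+haarnet": {"paths": ("unet", "haar"), "dsl": False, "ae": False},
    "segnet+haarnet": {"paths": ("segnet", "haar"), "dsl": False, "ae": False},
    "tp-unet": {"paths": ("unet", "segnet", "haar"), "dsl": False, "ae": False},
    "tp-unet+ae": {"paths": ("unet", "segnet", "haar"), "dsl": False, "ae": True},
    "tp-unet+dsl": {"paths": ("unet", "segnet", "haar"), "dsl": True, "ae": False},
    "tp-unet+ae+dsl": {"paths": ("unet", "segnet", "haar"), "dsl": True, "ae": True},
}


@dataclass
class ModelOutput:
    """Per-level probability maps u_1..u_4 plus the reconstruction X^R.

    Levels beyond u_1 and the reconstruction are ``None`` when the
    corresponding head is disabled.  ``states`` holds the raw per-path
    encoder/decoder features.
    """

    u: list  # list of Tensors (N,2,H/2^(i-1),W/2^(i-1)) or None
    x_r: nn.Tensor | None
    states: list[PathState] = field(default_factory=list)


class DSLHead(nn.Module):
    """1x1 conv to 2 channels + channel softmax over concatenated decoders."""

    def __init__(self, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, 2, 1, rng)

    def __call__(self, decoders: list[nn.Tensor]) -> nn.Tensor:
        sizes = {d.shape[-2:] for d in decoders}
        if len(sizes) != 1:
            raise ValueError(f"decoder features disagree on spatial size: {sizes}")
        return nn.softmax_channels(self.conv(nn.concat(decoders, axis=1)))


class AEHead(nn.Module):
    """Reconstruction decoder: 1x1 compress, three 2x deconvs, 1x1 to 1 ch."""

    def __init__(self, in_channels: int, width4: int, rng: np.random.Generator):
        super().__init__()
        w = [width4, width4 // 2, width4 // 4, width4 // 8]
        if w[3] < 1:
            raise ValueError(f"width_4={width4} too small for three halvings")
        self.compress = nn.Conv2d(in_channels, w[0], 1, rng)
        self.up = [nn.ConvTranspose2x2(w[i], w[i + 1], rng) for i in range(3)]
        self.out = nn.Conv2d(w[3], 1, 1, rng)

    def __call__(self, encoders: list[nn.Tensor]) -> nn.Tensor:
        a = self.compress(nn.concat(encoders, axis=1))
        for up in self.up:
            a = nn.relu(up(a))
        return self.out(a)


class TriplePathNet(nn.Module):
    """The assembled fusion model (configurable paths and heads)."""

    def __init__(self, widths=DEFAULT_WIDTHS, enabled_paths=("unet", "segnet", "haar"),
                 use_dsl: bool = True, use_ae: bool = True, seed: int = 0):
        super().__init__()
        if not enabled_paths:
            raise ValueError("at least one backbone path must be enabled")
        for name in enabled_paths:
            if name not in PATH_CLASSES:
                raise ValueError(f"unknown path {name!r}; choose from {sorted(PATH_CLASSES)}")
        widths = tuple(int(w) for w in widths)
        if len(widths) != 4 or any(w < 1 for w in widths):
            raise ValueError(f"widths must be four positive ints, got {widths}")
        if any(w % 4 for w in widths) and "haar" in enabled_paths:
            raise ValueError(
                f"widths {widths} must be divisible by 4 for the Haar path "
                "(wavelet synthesis splits channels into four subband groups)"
            )
        self.widths = widths
        self.enabled_paths = tuple(enabled_paths)
        self.use_dsl = bool(use_dsl)
        self.use_ae = bool(use_ae)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.paths = [PATH_CLASSES[name](widths, rng=rng) for name in self.enabled_paths]
        n = len(self.paths)
        # decoder features all carry width_i channels, so head input is n*width_i
        n_heads = 4 if use_dsl else 1
        self.heads = [DSLHead(n * widths[i], rng) for i in range(n_heads)]
        if use_ae:
            e4_channels = sum(
                4 * widths[2] if name == "haar" else widths[3] for name in self.enabled_paths
            )
            self.ae_head = AEHead(e4_channels, widths[3], rng)

    # -- forward --------------------------------------------------------
    def forward(self, x) -> ModelOutput:
        x = nn.as_tensor(x)
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(1, *x.shape)
        h, w = x.shape[-2:]
        if h % 8 or w % 8:
            raise ValueError(
                f"input spatial size ({h},{w}) must be a multiple of 8 "
                "(three 2x downsamplings); pad beforehand"
            )
        states = [path(x) for path in self.paths]
        u: list = [None] * 4
        for i, head in enumerate(self.heads):
            u[i] = head([s.decoder[i] for s in states])
        x_r = self.ae_head([s.encoder[3] for s in states]) if self.use_ae else None
        return ModelOutput(u=u, x_r=x_r, states=states)

    __call__ = forward

    def predict(self, x) -> np.ndarray:
        """Vessel-probability map (channel 1 of u_1) for one image.

        Accepts (H,W), (1,H,W) or (N,1,H,W); returns the same leading
        layout with the channel axis dropped.  Runs in inference mode
        without building the autodiff tape.
        """
        arr = np.asarray(x, dtype=nn.DTYPE)
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(arr)
        finally:
            self.train(was_training)
        prob = out.u[0].data[:, 1]  # (N,H,W)
        if arr.ndim == 2:
            return prob[0]
        if arr.ndim == 3:
            return prob[0]
        return prob

    # -- serialization ---------------------------------------------------
    def config(self) -> dict:
        return {
            "widths": list(self.widths),
            "enabled_paths": list(self.enabled_paths),
            "use_dsl": self.use_dsl,
            "use_ae": self.use_ae,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        """Write a self-describing checkpoint (config + weights + BN stats)."""
        state = self.state_dict()
        buf = io.BytesIO()
        np.savez(buf, __config__=np.frombuffer(
            json.dumps(self.config()).encode(), dtype=np.uint8), **state)
        with open(path, "wb") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "TriplePathNet":
        with np.load(path) as z:
            cfg = json.loads(bytes(z["__config__"]).decode())
            state = {k: z[k] for k in z.files if k != "__config__"}
        model = cls(widths=cfg["widths"], enabled_paths=cfg["enabled_paths"],
                    use_dsl=cfg["use_dsl"], use_ae=cfg["use_ae"], seed=cfg["seed"])
        model.load_state_dict(state)
        return model


def build_model(preset: str | None = None, widths=None, enabled_paths=None,
                use_dsl: bool | None = None, use_ae: bool | None = None,
                seed: int = 0) -> TriplePathNet:
    """Build a model from an ablation preset name and/or explicit switches.

    Explicit arguments override the preset.  Known presets:
    ``unet``, ``segnet``, ``haarnet``, pairwise fusions, ``tp-unet``,
    ``tp-unet+ae``, ``tp-unet+dsl``, ``tp-unet+ae+dsl``.
    """
    cfg = {"paths": ("unet", "segnet", "haar"), "dsl": True, "ae": True}
    if preset is not None:
        key = preset.lower()
        if key not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        cfg = dict(PRESETS[key])
    if enabled_paths is not None:
        cfg["paths"] = tuple(enabled_paths)
    if use_dsl is not None:
        cfg["dsl"] = use_dsl
    if use_ae is not None:
        cfg["ae"] = use_ae
    return TriplePathNet(
        widths=widths if widths is not None else DEFAULT_WIDTHS,
        enabled_paths=cfg["paths"], use_dsl=cfg["dsl"], use_ae=cfg["ae"], seed=seed,
    )
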