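"""Composite training objective: reconstruction MSE plus equilibrium-
weighted per-level cross-entropy deep supervision.

    Loss = beta * Loss_AE + Loss_DSL
         = beta * (1/n) sum_j |X(j) - X^R(j)|^2
           + sum_{i=1..4} alpha_i * L^i(u_i, v_i)

where L^i is the mean pixelwise cross-entropy of the level-i probability
map u_i against the level-i label map v_i, and the equilibrium
coefficients default to [beta, a1, a2, a3, a4] = [0.1, 1, 0.2, 0.2, 0.2].

L^i averages (rather than sums) over pixels so the alpha weighting is
resolution-independent.  Level labels v_2..v_4 are built by top-left
nearest-neighbour subsampling, which keeps them strictly binary.  The log
inside the cross-entropy is clamped below at 1e-12 so a saturated softmax
cannot produce an infinite loss.

All losses accept either plain arrays or autodiff tensors and return a
scalar :class:`~vesselseg.nn.Tensor` (use ``float(...)`` for the value);
gradients flow when the inputs are part of a tape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import ModelOutput

LOG_CLAMP = 1e-12


@dataclass
class EquilibriumCoefficients:
    """Weights balancing the reconstruction and deep-supervision terms."""

    beta: float = 0.1
    alpha: tuple[float, float, float, float] = (1.0, 0.2, 0.2, 0.2)

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be nonnegative, got {self.beta}")
        self.alpha = tuple(float(a) for a in self.alpha)
        if len(self.alpha) != 4 or any(a < 0 for a in self.alpha):
            raise ValueError(f"alpha must be four nonnegative reals, got {self.alpha}")


def loss_ae(x, x_r) -> nn.Tensor:
    """Mean squared reconstruction error (1/n) sum |X(j) - X^R(j)|^2."""
    x = nn.as_tensor(x)
    x_r = nn.as_tensor(x_r)
    if x.data.size != x_r.data.size:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_r.shape}")
    diff = x.reshape(-1) - x_r.reshape(-1)
    return (diff * diff).mean()


def downsample_labels(v: np.ndarray, levels: int = 4) -> list[np.ndarray]:
    """Build per-level label maps v_1..v_levels by top-left 2x subsampling.

    ``v`` is a binary (H,W) or (N,H,W) class map with H, W multiples of
    2^(levels-1); v_1 is ``v`` itself.
    """
    v = np.asarray(v)
    uniq = np.unique(v)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"labels must be binary 0/1, found values {uniq[:8]}")
    v = v.astype(np.int64)
    out = [v]
    for _ in range(levels - 1):
        v = v[..., 0::2, 0::2]
        out.append(v)
    return out


def _cross_entropy(u, v: np.ndarray) -> nn.Tensor:
    """Mean over pixels of -log u[correct class], clamped at LOG_CLAMP."""
    u = nn.as_tensor(u)
    data = u.data
    if data.ndim == 3:  # (2,H,W) -> (1,2,H,W)
        u = u.reshape(1, *data.shape)
        data = u.data
    v = np.asarray(v, dtype=np.int64)
    if v.ndim == 2:
        v = v[None]
    if data.shape[0] != v.shape[0] or data.shape[2:] != v.shape[1:]:
        raise ValueError(f"probability map {data.shape} and labels {v.shape} mismatch")
    picked = np.take_along_axis(data, v[:, None], axis=1)[:, 0]  # (N,H,W)
    clamped = np.maximum(picked, LOG_CLAMP)
    val = -np.log(clamped).mean()

    def bw(g):
        du = np.zeros_like(data)
        mask = (picked >= LOG_CLAMP) / (clamped * picked.size)
        np.put_along_axis(du, v[:, None], (-g * mask)[:, None], axis=1)
        u._accum(du)

    return nn.Tensor._make(np.asarray(val), (u,), bw)


def loss_dsl(u: list, v: list[np.ndarray],
             alpha=(1.0, 0.2, 0.2, 0.2)) -> nn.Tensor:
    """Equilibrium-weighted sum of per-level mean cross-entropies.

    ``u`` is the list of per-level probability maps (entries may be None
    when a head is disabled, provided the matching alpha is 0), ``v`` the
    matching label maps from :func:`downsample_labels`.
    """
    total = nn.Tensor(0.0)
    for i, (ui, ai) in enumerate(zip(u, alpha)):
        if ai == 0:
            continue
        if ui is None:
            raise ValueError(f"level {i + 1} head is disabled but alpha_{i + 1}={ai} != 0")
        total = total + ai * _cross_entropy(ui, v[i])
    return total


def total_loss(x, output: ModelOutput, v: np.ndarray,
               coeffs: EquilibriumCoefficients | None = None) -> "LossBreakdown":
    """beta * Loss_AE + Loss_DSL for one batch.

    ``x`` is the network input (reconstruction target), ``v`` the
    full-resolution binary label.  Heads that are disabled contribute
    nothing: with no AE head the reconstruction term is dropped; with deep
    supervision off only level 1 (alpha_1) is scored.
    """
    coeffs = coeffs if coeffs is not None else EquilibriumCoefficients()
    levels = downsample_labels(v)
    alpha = list(coeffs.alpha)
    if output.u[1] is None:  # deep supervision disabled: only u_1 exists
        alpha = [alpha[0], 0.0, 0.0, 0.0]
    dsl = loss_dsl(output.u, levels, alpha)
    if output.x_r is not None and coeffs.beta > 0:
        ae = loss_ae(x, output.x_r)
        total = coeffs.beta * ae + dsl
    else:
        ae = loss_ae(x, output.x_r) if output.x_r is not None else None
        total = dsl
    return LossBreakdown(total=total, ae=ae, dsl=dsl)


@dataclass
class LossBreakdown:
    """Total plus per-component losses for one step (tensors)."""

    total: nn.Tensor
    ae: nn.Tensor | None
    dsl: nn.Tensor

    def as_floats(self) -> dict[str, float]:
        d = {"total": float(self.total), "dsl": float(self.dsl)}
        if self.ae is not None:
            d["ae"] = float(self.ae)
        return d
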