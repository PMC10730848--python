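"""Single-level 2-D Haar wavelet analysis/synthesis.

The orthonormal Haar transform is the down/up-sampling operator of the
frequency path of the segmentation network: one analysis step halves both
spatial dimensions and splits a grid into an approximation band (LL) and
three detail bands responding to horizontal (HL), vertical (LH) and
diagonal (HH) intensity change.  Because the transform is orthonormal it
conserves energy and is exactly invertible, which makes lossless
down/up-sampling layers possible.

Conventions (fixed so the mapping onto reference wavelet libraries is
unambiguous):

* per non-overlapping 2x2 block ``[[a, b], [c, d]]``::

      ll = ( a + b + c + d) / 2
      hl = (-a + b - c + d) / 2      # horizontal change
      lh = (-a - b + c + d) / 2      # vertical change
      hh = ( a - b - c + d) / 2      # diagonal change

* multi-channel stacks concatenate subbands grouped by band:
  ``[LL..., HL..., LH..., HH...]``, each group in input channel order.

Odd-sized inputs are a hard error here; callers pad beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SubbandSet", "dwt2_haar", "idwt2_haar", "dwt_concat", "split_idwt"]


@dataclass
class SubbandSet:
    """The four half-resolution Haar subbands of one 2-D grid."""

    ll: np.ndarray
    hl: np.ndarray
    lh: np.ndarray
    hh: np.ndarray

    def __post_init__(self) -> None:
        shapes = {b.shape for b in (self.ll, self.hl, self.lh, self.hh)}
        if len(shapes) != 1:
            raise ValueError(f"subbands must share one shape, got {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ll.shape


def _check_even(shape: tuple[int, int]) -> None:
    h, w = shape[-2], shape[-1]
    if h % 2:
        raise ValueError(f"height {h} is odd; Haar analysis needs an even height axis")
    if w % 2:
        raise ValueError(f"width {w} is odd; Haar analysis needs an even width axis")
    if h < 2 or w < 2:
        raise ValueError(f"grid must be at least 2x2, got {h}x{w}")


def _corners(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    # a=top-left, b=top-right, c=bottom-left, d=bottom-right of each 2x2 block
    return (
        x[..., 0::2, 0::2],
        x[..., 0::2, 1::2],
        x[..., 1::2, 0::2],
        x[..., 1::2, 1::2],
    )


def _analysis(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    a, b, c, d = _corners(x)
    ll = (a + b + c + d) * 0.5
    hl = (-a + b - c + d) * 0.5
    lh = (-a - b + c + d) * 0.5
    hh = (a - b - c + d) * 0.5
    return ll, hl, lh, hh


def _synthesis(ll, hl, lh, hh) -> np.ndarray:
    shape = list(ll.shape)
    out = np.empty(shape[:-2] + [shape[-2] * 2, shape[-1] * 2], dtype=ll.dtype)
    out[..., 0::2, 0::2] = (ll - hl - lh + hh) * 0.5
    out[..., 0::2, 1::2] = (ll + hl - lh - hh) * 0.5
    out[..., 1::2, 0::2] = (ll - hl + lh - hh) * 0.5
    out[..., 1::2, 1::2] = (ll + hl + lh + hh) * 0.5
    return out


def dwt2_haar(x: np.ndarray) -> SubbandSet:
    """Orthonormal single-level 2-D Haar analysis of one grid.

    Parameters
    ----------
    x
        Real 2-D array with even height and width, all values finite.

    Returns
    -------
    SubbandSet
        ll/hl/lh/hh at half resolution.  Energy is conserved:
        ``sum(x**2) == sum(ll**2 + hl**2 + lh**2 + hh**2)``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D grid, got ndim={x.ndim}")
    _check_even(x.shape)
    if not np.all(np.isfinite(x)):
        raise ValueError("input grid contains non-finite values")
    return SubbandSet(*_analysis(x))


def idwt2_haar(s: SubbandSet) -> np.ndarray:
    """Exact inverse of :func:`dwt2_haar`; output shape ``(2*H', 2*W')``."""
    bands = [np.asarray(b, dtype=np.float64) for b in (s.ll, s.hl, s.lh, s.hh)]
    shapes = {b.shape for b in bands}
    if len(shapes) != 1:
        raise ValueError(f"subbands must share one shape, got {shapes}")
    return _synthesis(*bands)


def dwt_concat(x: np.ndarray) -> np.ndarray:
    """Haar-analyse every channel of a ``(C, H, W)`` stack and concatenate.

    Output has shape ``(4C, H/2, W/2)`` with channels grouped by subband:
    all LL channels first, then HL, LH, HH, each group in input order.
    A leading batch axis ``(N, C, H, W)`` is also accepted.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim not in (3, 4):
        raise ValueError(f"expected (C,H,W) or (N,C,H,W), got ndim={x.ndim}")
    _check_even(x.shape)
    ll, hl, lh, hh = _analysis(x)
    return np.concatenate([ll, hl, lh, hh], axis=-3)


def split_idwt(x: np.ndarray) -> np.ndarray:
    """Invert :func:`dwt_concat`: split grouped subbands, synthesise.

    Input channel count must be divisible by 4; output is ``(C, 2H', 2W')``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim not in (3, 4):
        raise ValueError(f"expected (4C,H,W) or (N,4C,H,W), got ndim={x.ndim}")
    c4 = x.shape[-3]
    if c4 % 4:
        raise ValueError(f"channel count {c4} not divisible by 4")
    c = c4 // 4
    ll, hl, lh, hh = (x[..., i * c : (i + 1) * c, :, :] for i in range(4))
    return _synthesis(ll, hl, lh, hh)
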