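"""Blind-spot mask construction and feed-forward lesioning.

The lesion zeroes the feed-forward error pathway over a central square of
the input patch. It is applied as a multiplicative {0,1} mask on the
bottom-up error inside the dynamics — mathematically identical to zeroing
the corresponding rows of the feed-forward efficacies, while leaving the
stored basis (and thus the generative/feedback pathway) untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .model_core import HPCNetwork
from .preprocessing import TilingGeometry

__all__ = ["BlindSpotMask", "make_bs_mask", "module_local_mask", "apply_blind_spot"]


@dataclass(frozen=True)
class BlindSpotMask:
    """Indicator grid (1 = intact, 0 = lesioned) with the zeroed ranges.

    ``bs_rows``/``bs_cols`` are inclusive 0-based ranges; for a degenerate
    (empty) blind spot they are ``None``.
    """

    indicator: np.ndarray
    bs_rows: tuple[int, int] | None
    bs_cols: tuple[int, int] | None


def make_bs_mask(patch_size: int = 30, bs_size: int = 8) -> BlindSpotMask:
    """Central ``bs_size`` x ``bs_size`` blind spot in a square patch."""
    if not (0 <= bs_size < patch_size):
        raise ValueError("require 0 <= bs_size < patch_size")
    margin = patch_size - bs_size
    if margin % 2 != 0:
        raise ValueError("blind spot cannot be centred: patch_size - bs_size is odd")
    indicator = np.ones((patch_size, patch_size))
    if bs_size == 0:
        return BlindSpotMask(indicator=indicator, bs_rows=None, bs_cols=None)
    lo = margin // 2
    hi = lo + bs_size - 1
    indicator[lo : hi + 1, lo : hi + 1] = 0.0
    return BlindSpotMask(indicator=indicator, bs_rows=(lo, hi), bs_cols=(lo, hi))


def module_local_mask(
    mask: BlindSpotMask, geometry: TilingGeometry, m: int
) -> np.ndarray:
    """Restrict the global indicator to module m's window."""
    if not (0 <= m < geometry.n_modules):
        raise ValueError(f"module index {m} out of range 0..{geometry.n_modules - 1}")
    r, c = geometry.windows[m]
    s = geometry.sub_size
    return mask.indicator[r : r + s, c : c + s].copy()


def apply_blind_spot(network: HPCNetwork, mask: BlindSpotMask) -> HPCNetwork:
    """Return a lesioned copy of a network trained with intact feed-forward.

    The original network is untouched; the copy's bottom-up error pathway
    zeroes masked pixels in every module window intersecting the blind
    spot. The feedback prediction U r is unchanged.
    """
    if network.ff_mask is not None and not np.all(network.ff_mask == 1.0):
        raise ValueError("network already carries a feed-forward lesion")
    if mask.indicator.shape != (network.geometry.patch_size,) * 2:
        raise ValueError("mask size does not match the network patch size")
    return dataclasses.replace(network, ff_mask=mask.indicator.copy())
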