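"""Depth-map hole filling from the 16 peripheral pixels of a 5x5 window.

A pixel with value 0 is "missing".  For each missing pixel (i, j), the 5x5
window centered there is formed and the 16 pixels on its outer ring — the
offsets (m, n) with max(|m|, |n|) = 2 — are extracted; the hole is replaced
by the arithmetic mean of the valid (> 0) ring values.  Valid pixels are
never modified.

Passes use Jacobi semantics: every fill in a pass reads only the previous
pass's values, so the result is independent of pixel scan order.  A single
pass is the strict neighborhood-mean behavior; additional passes extend the
fill into hole blobs wider than the ring (e.g. the gap between the front and
hind limbs).  Windows are clipped at the image border: only ring positions
inside the image contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

from .frames import DepthMap

__all__ = ["RING_OFFSETS", "complete_depth", "hole_statistics", "HoleStatistics"]

#: The 16 outer-ring offsets of a 5x5 window: Chebyshev distance exactly 2.
RING_OFFSETS = tuple(
    (m, n) for m in range(-2, 3) for n in range(-2, 3) if max(abs(m), abs(n)) == 2
)

_RING_KERNEL = np.zeros((5, 5))
for _m, _n in RING_OFFSETS:
    _RING_KERNEL[_m + 2, _n + 2] = 1.0


def complete_depth(depth: DepthMap, max_passes: int = 5) -> DepthMap:
    """Fill missing depth values by the mean of valid 5x5 outer-ring pixels.

    Repeats until no pixel changes or ``max_passes`` is reached.  Holes whose
    ring never gains a valid pixel remain 0.  Returns a new DepthMap; the
    input is left untouched.
    """
    if max_passes < 1:
        raise ValueError(f"max_passes must be >= 1, got {max_passes}")
    d = depth.values.copy()
    for _ in range(max_passes):
        valid = d > 0
        holes = ~valid
        if not holes.any():
            break
        # zero-padded convolution: out-of-image ring positions contribute
        # nothing to either sum or count, i.e. the window is clipped.
        sums = convolve2d(np.where(valid, d, 0.0), _RING_KERNEL, mode="same")
        counts = convolve2d(valid.astype(np.float64), _RING_KERNEL, mode="same")
        fillable = holes & (counts > 0.5)
        if not fillable.any():
            break
        d = np.where(fillable, sums / np.where(counts > 0.5, counts, 1.0), d)
    return DepthMap(d, missing_marker=depth.missing_marker)


@dataclass(frozen=True)
class HoleStatistics:
    missing_before: int
    missing_after: int
    fill_fraction: float


def hole_statistics(before: DepthMap, after: DepthMap) -> HoleStatistics:
    """Count missing pixels before/after completion and the fraction filled.

    fill_fraction = (missing_before - missing_after) / missing_before, with
    0/0 defined as 1 (nothing to fill means completion is vacuously total).
    """
    if before.shape != after.shape:
        raise ValueError(f"shape mismatch: {before.shape} vs {after.shape}")
    nb, na = before.missing_count(), after.missing_count()
    if na > nb:
        raise ValueError(
            f"completion cannot create holes: {nb} missing before, {na} after"
        )
    frac = 1.0 if nb == 0 else (nb - na) / nb
    return HoleStatistics(missing_before=nb, missing_after=na, fill_fraction=frac)
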