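"""Baseline single-scale local contrast method and external inhibition.

The local contrast map compares, at every pixel, the mean of the centre cell
(a ``cell`` x ``cell`` block) with the largest mean among the eight
surrounding cells of the same size.  The signed difference form is used so
that dark targets produce negative local contrast, matching a minimum-seeking
winner-take-all stage.  A single scale suffices because every simulated
target fits within the smallest 3x3 cell.

``inhibit_external`` applies the motion-derived suppression map frame-wise to
any saliency map, signed or not, shrinking magnitudes toward zero in
cluttered regions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .filters import SPATIAL_MODE


def lcm(frame, cell=3):
    """Signed single-scale local contrast: centre-cell mean minus the maximum
    of the eight neighbouring cell means."""
    frame = np.asarray(frame, dtype=float)
    if np.any(frame < 0):
        raise ValueError("frame must be non-negative")
    if min(frame.shape) < 3 * cell:
        raise ValueError("frame smaller than 3 cells")
    centre = ndimage.uniform_filter(frame, size=cell, mode=SPATIAL_MODE)
    h, _ = frame.shape
    neighbour_max = None
    for dr in (-cell, 0, cell):
        for dc in (-cell, 0, cell):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(centre, (-dr, -dc), axis=(0, 1))
            # vertical replicate-padding: wrapped rows take the edge value
            if dr > 0:
                shifted[h - dr:, :] = shifted[h - dr - 1, :]
            elif dr < 0:
                shifted[:-dr, :] = shifted[-dr, :]
            neighbour_max = shifted if neighbour_max is None else \
                np.maximum(neighbour_max, shifted)
    return centre - neighbour_max


def inhibit_external(saliency, suppression):
    """Pointwise product of a (possibly signed) saliency map with the
    suppression map; |output| <= |input| everywhere."""
    saliency = np.asarray(saliency, dtype=float)
    suppression = np.asarray(suppression, dtype=float)
    if saliency.shape != suppression.shape:
        raise ValueError("saliency and suppression shapes differ")
    return saliency * suppression
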