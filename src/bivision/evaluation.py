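"""Detection extraction, matching, ROC scoring and clutter metrics.

A winner-take-all pass reduces a saliency map to isolated candidates (strict
local extrema of a 7x7 neighbourhood).  Candidates are matched greedily
(highest score first, one detection per target per frame) against ground
truth within a 5x5 window; for model variants that respond on the trailing
edge of a right-to-left moving target, the window centre is shifted one pixel
to the right of the true centre.  The headline score integrates the ROC
curve's true-positive rate over the false-positive-count axis from 0 to 20
false positives per frame and normalises by that span, giving a score in
[0, 1].

Two scalar clutter metrics characterise a frame: mean contrast per pixel
(MCPP, the average local RMS contrast) and mean frequency magnitude (MFM,
the mean spectral magnitude over the 1.044-1.389 cycles/degree band, i.e.
2-2.7 px/cycle at 0.36 deg/px).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .filters import SPATIAL_MODE


@dataclass
class Detection:
    frame: int
    row: int
    col: int
    score: float
    is_tp: bool = False
    target_id: int | None = None


def winner_take_all(saliency, kernel=7, polarity="max"):
    """Strict local extrema of a square neighbourhood.

    ``polarity`` is "max" for positive saliency scores or "min" for signed
    local-contrast maps whose targets are minima.  Ties inside a window keep
    only the lexicographically first position; a constant map yields no
    detections.  Returns an (n, 3) array of (row, col, score) with scores
    oriented so larger is always better.
    """
    if kernel % 2 == 0:
        raise ValueError("kernel must be odd")
    m = np.asarray(saliency, dtype=float)
    if polarity == "min":
        m = -m
    elif polarity != "max":
        raise ValueError(f"unknown polarity {polarity!r}")
    maxf = ndimage.maximum_filter(m, size=kernel, mode=SPATIAL_MODE)
    minf = ndimage.minimum_filter(m, size=kernel, mode=SPATIAL_MODE)
    candidate = (m == maxf) & (maxf > minf)
    rows, cols = np.nonzero(candidate)
    half = kernel // 2
    h, w = m.shape
    out = []
    for r, c in zip(rows, cols):    # lexicographic order from nonzero
        window_rows = np.arange(max(r - half, 0), min(r + half + 1, h))
        window_cols = (np.arange(c - half, c + half + 1)) % w
        window = m[np.ix_(window_rows, window_cols)]
        ties = np.argwhere(window == m[r, c])
        tie_pos = np.column_stack([window_rows[ties[:, 0]],
                                   window_cols[ties[:, 1]]])
        first = min((int(tr), int(tc)) for tr, tc in tie_pos)
        if first == (int(r), int(c)):
            out.append((int(r), int(c), float(m[r, c])))
    return np.asarray(out, dtype=float).reshape(-1, 3)


def match(detections, truth, frame, window=5, shift_px=(0, 1), frame_width=None):
    """Greedily label detections as true or false positives.

    ``truth`` holds continuous (row, col) target centres; a detection within
    the ``window`` x ``window`` box centred on a (shifted) unclaimed centre
    is a true positive.  ``shift_px`` is (d_row, d_col): (0, 1) aligns the
    window with the trailing edge of right-to-left motion; use (0, 0) for
    purely spatial methods.  Horizontal distances wrap when ``frame_width``
    is given.
    """
    half = window // 2
    truth = np.asarray(truth, dtype=float)
    shifted = truth.copy()
    shifted[:, 0] += shift_px[0]
    shifted[:, 1] += shift_px[1]
    claimed = np.zeros(len(truth), dtype=bool)
    order = np.argsort(-detections[:, 2]) if len(detections) else []
    labelled = []
    for idx in order:
        r, c, score = detections[idx]
        dr = np.abs(shifted[:, 0] - r)
        dc = np.abs(shifted[:, 1] - c)
        if frame_width is not None:
            dc = np.minimum(dc, frame_width - dc)
        inside = (dr <= half) & (dc <= half) & ~claimed
        det = Detection(frame=frame, row=int(r), col=int(c), score=float(score))
        if np.any(inside):
            # nearest unclaimed target inside the window
            cand = np.nonzero(inside)[0]
            nearest = cand[np.argmin(np.hypot(dr[cand], dc[cand]))]
            claimed[nearest] = True
            det.is_tp = True
            det.target_id = int(nearest)
        labelled.append(det)
    return labelled


@dataclass
class ROCCurve:
    """Operating points of a threshold sweep: per-frame mean true- and
    false-positive counts and the true-positive rate at each threshold."""

    thresholds: np.ndarray
    tp: np.ndarray          # per-frame mean true positives
    fp: np.ndarray          # per-frame mean false positives
    tpr: np.ndarray
    n_frames: int
    targets_per_frame: int


def roc(labelled, n_frames, targets_per_frame):
    """Threshold sweep over all labelled detections.

    TP and FP at each threshold are per-frame means over the evaluation
    frames; TPR divides by the number of targets per frame.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    scores = np.array([d.score for d in labelled], dtype=float)
    is_tp = np.array([d.is_tp for d in labelled], dtype=bool)
    if scores.size == 0:
        z = np.zeros(1)
        return ROCCurve(thresholds=z, tp=z.copy(), fp=z.copy(), tpr=z.copy(),
                        n_frames=n_frames, targets_per_frame=targets_per_frame)
    order = np.argsort(-scores)
    scores, is_tp = scores[order], is_tp[order]
    thresholds, first_idx = np.unique(-scores, return_index=True)
    thresholds = -thresholds
    cum_tp = np.cumsum(is_tp)
    cum_fp = np.cumsum(~is_tp)
    # last occurrence of each unique score in the sorted order
    last_idx = np.append(first_idx[1:], len(scores)) - 1
    tp = cum_tp[last_idx] / n_frames
    fp = cum_fp[last_idx] / n_frames
    return ROCCurve(thresholds=thresholds, tp=tp, fp=fp,
                    tpr=tp / targets_per_frame, n_frames=n_frames,
                    targets_per_frame=targets_per_frame)


def auroc(curve: ROCCurve, fp_max=20.0):
    """Mean TPR over the false-positive interval [0, fp_max].

    Trapezoidal integration over the FP axis, the curve extended
    horizontally from its last point below ``fp_max``, normalised by
    ``fp_max`` so a perfect detector scores 1.
    """
    if fp_max <= 0:
        raise ValueError("fp_max must be positive")
    fp = np.concatenate([[0.0], curve.fp])
    tpr = np.concatenate([[curve.tpr[0] if len(curve.fp) and curve.fp[0] == 0
                           else 0.0], curve.tpr])
    # restrict to [0, fp_max], interpolating the crossing point
    if fp[-1] < fp_max:
        fp = np.append(fp, fp_max)
        tpr = np.append(tpr, tpr[-1])
    else:
        inside = fp <= fp_max
        crossing = np.interp(fp_max, fp, tpr)
        fp = np.append(fp[inside], fp_max)
        tpr = np.append(tpr[inside], crossing)
    return float(np.trapezoid(tpr, fp) / fp_max)


def mcpp(frame, cell=3):
    """Mean contrast per pixel: average local RMS contrast (neighbourhood
    standard deviation over neighbourhood mean).  Scale-invariant."""
    frame = np.asarray(frame, dtype=float)
    if np.any(frame < 0):
        raise ValueError("frame must be non-negative")
    mean = ndimage.uniform_filter(frame, size=cell, mode=SPATIAL_MODE)
    sq = ndimage.uniform_filter(frame * frame, size=cell, mode=SPATIAL_MODE)
    var = np.maximum(sq - mean * mean, 0.0)
    if np.all(mean == 0):
        raise ValueError("zero-luminance frame")
    with np.errstate(invalid="ignore", divide="ignore"):
        contrast = np.where(mean > 0, np.sqrt(var) / mean, 0.0)
    return float(contrast.mean())


def cycles_per_degree(pixels_per_cycle, degrees_per_px=0.36):
    """Band-edge conversion: 2 px/cycle at 0.36 deg/px = 1.389 cycles/deg."""
    return 1.0 / (pixels_per_cycle * degrees_per_px)


def mfm(frame, pixels_per_cycle=(2.0, 2.7), degrees_per_px=None,
        band_cpd=None):
    """Mean frequency magnitude: mean 2-D spectral magnitude over a high
    spatial-frequency band.

    The band defaults to 2-2.7 pixels/cycle, which at the reference angular
    sampling of 0.36 deg/px equals 1.044-1.389 cycles/degree; pass
    ``band_cpd`` together with ``degrees_per_px`` to specify it angularly.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    if band_cpd is not None:
        if degrees_per_px is None:
            raise ValueError("band_cpd requires degrees_per_px")
        lo, hi = band_cpd[0] * degrees_per_px, band_cpd[1] * degrees_per_px
    else:
        lo, hi = 1.0 / pixels_per_cycle[1], 1.0 / pixels_per_cycle[0]
    spectrum = np.abs(np.fft.rfft2(frame)) / frame.size
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.rfftfreq(w)[None, :]
    f = np.hypot(fy, fx)           # cycles / px
    in_band = (f >= lo) & (f <= hi)
    if not np.any(in_band):
        raise ValueError(f"band {lo:.3g}-{hi:.3g} cycles/px is empty for a "
                         f"{h}x{w} frame")
    return float(spectrum[in_band].mean())
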