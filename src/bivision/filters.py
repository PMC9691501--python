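"""First-order spatio-temporal filter primitives shared by every model stage.

All temporal filtering in the model is built from the discrete first-order
recursion

    y[t] = y[t-1] + alpha * (x[t] - y[t-1]),   alpha = dt / (tau + dt)

with ``tau = 1 / (2 pi fc)`` so that ``fc`` is the analog corner frequency in
Hz.  The corner may be a scalar or a per-pixel map (the photoreceptor stage
drives its low-pass corner from local intensity).  The high-pass is defined as
the complement ``x - lowpass(x)`` so that low-pass + high-pass reconstruct the
input exactly at every step.

Spatial filtering treats the horizontal axis as periodic (the input is a 360
degree panorama) and replicates the vertical edges.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

#: boundary convention for every spatial operator in the package:
#: vertical axis replicate-padded, horizontal axis wraps at the panorama seam
SPATIAL_MODE = ("nearest", "wrap")


def _alpha(corner_hz, sample_rate):
    """Smoothing coefficient for a first-order recursion at ``corner_hz``."""
    corner = np.asarray(corner_hz, dtype=float)
    if not np.all(np.isfinite(corner)):
        raise ValueError("corner frequency must be finite")
    if np.any(corner <= 0):
        raise ValueError("corner frequency must be positive")
    if np.any(corner >= sample_rate / 2):
        raise ValueError(
            f"corner frequency must be below the Nyquist limit "
            f"({sample_rate / 2} Hz)"
        )
    dt = 1.0 / sample_rate
    tau = 1.0 / (2.0 * np.pi * corner)
    return dt / (tau + dt)


class TemporalLowpass:
    """Per-pixel first-order temporal low-pass filter.

    Parameters
    ----------
    corner_hz : float or ndarray
        Corner frequency in Hz; scalar or a map broadcastable to the frame
        shape.  Must lie strictly below the Nyquist limit.
    sample_rate : float
        Frame rate in Hz (100 by default, the model's native update rate).

    The first frame seeds the state, so there is no start-up transient from an
    arbitrary zero initial condition; the warm-up period of a simulation then
    guarantees stationarity of the slower feedback loops.
    """

    def __init__(self, corner_hz=1.0, sample_rate=100.0):
        self.sample_rate = float(sample_rate)
        self.corner_hz = corner_hz
        _alpha(corner_hz, self.sample_rate)  # validate eagerly
        self.state = None

    def step(self, frame, corner_hz=None):
        """Advance one sample and return the smoothed frame.

        ``corner_hz`` optionally overrides the corner for this step (used by
        the stages whose corner is driven by a control signal).
        """
        frame = np.asarray(frame, dtype=float)
        if self.state is None:
            self.state = frame.copy()
            return self.state.copy()
        if self.state.shape != frame.shape:
            raise ValueError(
                f"frame shape {frame.shape} does not match filter state "
                f"shape {self.state.shape}"
            )
        a = _alpha(self.corner_hz if corner_hz is None else corner_hz,
                   self.sample_rate)
        self.state = self.state + a * (frame - self.state)
        return self.state.copy()

    def reset(self):
        self.state = None


class TemporalHighpass:
    """Leaky first-order temporal high-pass: input minus its own low-pass."""

    def __init__(self, corner_hz=1.0, sample_rate=100.0):
        self.lowpass = TemporalLowpass(corner_hz, sample_rate)

    def step(self, frame, corner_hz=None):
        frame = np.asarray(frame, dtype=float)
        return frame - self.lowpass.step(frame, corner_hz=corner_hz)

    def reset(self):
        self.lowpass.reset()


def spatial_highpass(frame, kernel_radius=1):
    """Centre minus local mean over a square window of the given radius.

    The horizontal axis wraps (panorama seam); vertical edges replicate.  The
    output is invariant to adding a constant to the input.
    """
    if kernel_radius < 1:
        raise ValueError("kernel_radius must be >= 1")
    frame = np.asarray(frame, dtype=float)
    size = 2 * kernel_radius + 1
    if size > min(frame.shape):
        raise ValueError("kernel larger than frame")
    local_mean = ndimage.uniform_filter(frame, size=size, mode=SPATIAL_MODE)
    return frame - local_mean


def naka_rushton(values, gain=1.0, half_saturation=1.0, ceiling=1.0):
    """Saturating hyperbolic-ratio nonlinearity ``min(G v / (v + c), ceiling)``.

    Monotone non-decreasing in ``values`` and hard-limited at ``ceiling``;
    used both as the photoreceptor's compressive output stage and to condition
    the motion-derived inhibition signal.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("naka_rushton input must be non-negative")
    if half_saturation <= 0:
        raise ValueError("half_saturation must be positive")
    if gain <= 0:
        raise ValueError("gain must be positive")
    return np.minimum(gain * values / (values + half_saturation), ceiling)
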