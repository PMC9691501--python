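"""Target pathway: rectifying transient cell (RTC) and per-pixel small-target
correlator (ESTMD).

The RTC separates temporal transients into rising (ON) and falling (OFF)
channels.  Each channel carries a per-pixel adaptation state: when the
channel's temporal derivative exceeds a threshold the state snaps to the
one-frame-delayed channel value (fast adaptation), otherwise it relaxes
toward the channel through a slow low-pass (the refractory behaviour).  The
channel output is the rectified excess of the signal over its adaptation
state, followed by a centre-minus-surround spatial inhibition that suppresses
extended bars and large-scale flicker while sparing pixel-scale targets.

The small-target correlator multiplies, at the same pixel, one channel with
the low-pass-delayed other channel: a dark target passing a pixel produces an
OFF transient (leading edge) followed by an ON transient (trailing edge), so
``dark = delay(off) * on``; ``bright`` is the mirror image.

Lateral-inhibition hooks: a suppression map can multiply the RTC input
(location A), rescale the derivative threshold (location B, restoring
triggering for transients attenuated at A), multiply the two rectified
channels separately (location C) or multiply the correlator outputs
(location D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .filters import SPATIAL_MODE, TemporalHighpass, TemporalLowpass


@dataclass
class RTCConfig:
    input_corner_hz: float = 1.0      # leaky high-pass on the RTC input
    slow_corner_hz: float = 0.5       # slow adaptation decay
    derivative_threshold: float = 0.01  # in lamina-output units, per frame
    surround_size: int = 5
    sample_rate: float = 100.0


class RectifyingTransientCell:
    """ON/OFF transient separation with fast/slow adaptation."""

    def __init__(self, config: RTCConfig | None = None):
        self.config = config or RTCConfig()
        if self.config.derivative_threshold <= 0:
            raise ValueError("derivative threshold must be positive")
        c = self.config
        self._hpf = TemporalHighpass(c.input_corner_hz, c.sample_rate)
        self._alpha_slow = None
        self._prev = {}      # previous channel values (the one-frame delay)
        self._adapt = {}     # per-channel adaptation states

    def _channel(self, name, ch, threshold):
        prev = self._prev.get(name)
        adapt = self._adapt.get(name)
        if prev is None:
            prev = np.zeros_like(ch)
            adapt = np.zeros_like(ch)
        if self._alpha_slow is None:
            dt = 1.0 / self.config.sample_rate
            tau = 1.0 / (2.0 * np.pi * self.config.slow_corner_hz)
            self._alpha_slow = dt / (tau + dt)
        deriv = ch - prev
        # slow relaxation everywhere; snap to the delayed value where the
        # derivative clears the (possibly locally rescaled) threshold
        adapt = adapt + self._alpha_slow * (ch - adapt)
        trigger = deriv > threshold
        adapt = np.where(trigger, prev, adapt)
        out = np.maximum(ch - adapt, 0.0)
        self._prev[name] = ch
        self._adapt[name] = adapt
        return out

    def _surround_inhibit(self, ch):
        """Centre minus surround mean (uniform patch maps to 0), rectified."""
        size = self.config.surround_size
        n = size * size
        box = ndimage.uniform_filter(ch, size=size, mode=SPATIAL_MODE)
        surround = (box * n - ch) / (n - 1)
        return np.maximum(ch - surround, 0.0)

    def step(self, frame, suppression=None, threshold_scale=None):
        """One frame -> (on, off) channel outputs.

        ``suppression`` multiplies the input (inhibition location A);
        ``threshold_scale`` rescales the derivative threshold pointwise
        (location B).
        """
        x = np.asarray(frame, dtype=float)
        if suppression is not None:
            x = x * suppression
        x = self._hpf.step(x)
        on_raw = np.maximum(x, 0.0)
        off_raw = np.maximum(-x, 0.0)
        threshold = self.config.derivative_threshold
        if threshold_scale is not None:
            threshold = threshold * threshold_scale
        on = self._channel("on", on_raw, threshold)
        off = self._channel("off", off_raw, threshold)
        return self._surround_inhibit(on), self._surround_inhibit(off)

    def reset(self):
        self._hpf.reset()
        self._prev = {}
        self._adapt = {}


class SmallTargetCorrelator:
    """Per-pixel delay-and-correlate of the ON and OFF channels."""

    def __init__(self, delay_corner_hz=3.0, sample_rate=100.0):
        self._delay_on = TemporalLowpass(delay_corner_hz, sample_rate)
        self._delay_off = TemporalLowpass(delay_corner_hz, sample_rate)

    def step(self, on, off):
        """Return ``(dark, bright)`` saliency maps (both >= 0)."""
        d_on = self._delay_on.step(np.asarray(on, dtype=float))
        d_off = self._delay_off.step(np.asarray(off, dtype=float))
        dark = d_off * on
        bright = d_on * off
        return dark, bright

    def reset(self):
        self._delay_on.reset()
        self._delay_off.reset()
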