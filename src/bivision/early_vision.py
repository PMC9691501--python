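"""Photoreceptor (PRC) and lamina monopolar cell (LMC) pre-processing stages.

The photoreceptor stage compresses linear high-dynamic-range luminance into
[0, 1) on a per-pixel basis: an intensity-dependent low-pass (brighter pixels
respond faster), a fast divisive feedback loop and a slow subtractive
exponential feedback loop provide light adaptation over two time scales, and a
hyperbolic-ratio (Naka-Rushton) transform performs the final range
compression.

The lamina stage removes spatio-temporal redundancy: a leaky temporal
high-pass whose per-pixel corner follows the photoreceptor adaptation level,
followed by a spatial centre-surround high-pass, with an optional tanh squash.
Its steady-state response to any static uniform scene is zero.

The exact time constants of the biological fit are not reproduced here; every
corner is a config parameter with defaults of the right order of magnitude
for a 100 Hz model tracking 0.1-0.5 px/frame motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import TemporalHighpass, TemporalLowpass, naka_rushton, spatial_highpass


def _log_linear_map(values, in_lo, in_hi, out_lo, out_hi):
    """Map ``log(values)`` affinely from [log in_lo, log in_hi] to
    [out_lo, out_hi], clipping outside the range."""
    v = np.clip(np.asarray(values, dtype=float), in_lo, in_hi)
    u = (np.log(v) - np.log(in_lo)) / (np.log(in_hi) - np.log(in_lo))
    return out_lo + u * (out_hi - out_lo)


@dataclass
class PRCConfig:
    """Photoreceptor constants.

    ``corner_lo/hi_hz`` bound the intensity-driven low-pass corner, mapped
    log-linearly from luminance over ``lum_lo..lum_hi``.  ``fast_corner_hz``
    and ``slow_corner_hz`` set the adaptation loop speeds.  ``nr_half`` is the
    half-saturation of the output compression (same units as the adapted
    signal).
    """

    corner_lo_hz: float = 2.0
    corner_hi_hz: float = 40.0
    lum_lo: float = 1e-2
    lum_hi: float = 1e4
    fast_corner_hz: float = 5.0
    slow_corner_hz: float = 0.1
    fast_strength: float = 1.0
    slow_strength: float = 1.0
    nr_half: float = 0.5
    sample_rate: float = 100.0


class Photoreceptor:
    """Adaptive luminance-to-[0,1) compression (one instance per pipeline)."""

    def __init__(self, config: PRCConfig | None = None):
        self.config = config or PRCConfig()
        c = self.config
        self._vlpf = TemporalLowpass(c.corner_lo_hz, c.sample_rate)
        self._fast = TemporalLowpass(c.fast_corner_hz, c.sample_rate)
        self._slow = TemporalLowpass(c.slow_corner_hz, c.sample_rate)

    def step(self, raw_frame):
        """Process one linear-luminance frame.

        Returns ``(compressed, adaptation)`` where ``compressed`` lies in
        [0, 1) and ``adaptation`` is the slow adaptation state consumed by the
        lamina stage to set its temporal corner.
        """
        raw = np.asarray(raw_frame, dtype=float)
        if np.any(raw < 0):
            raise ValueError("luminance must be non-negative")
        if not np.all(np.isfinite(raw)):
            raise ValueError("luminance must be finite")
        c = self.config
        corner = _log_linear_map(raw, c.lum_lo, c.lum_hi,
                                 c.corner_lo_hz, c.corner_hi_hz)
        smoothed = self._vlpf.step(raw, corner_hz=corner)
        # fast divisive feedback: the loop state tracks the divided output.
        # The first frame seeds both loops at their fixed point, otherwise
        # the exponential loop starts from an enormous un-adapted value and
        # shuts the output down for hundreds of frames.
        if self._fast.state is None:
            kf = c.fast_strength
            self._fast.state = (np.sqrt(1.0 + 4.0 * kf * smoothed) - 1.0) \
                / (2.0 * kf)
        divided = smoothed / (1.0 + c.fast_strength * self._fast.state)
        self._fast.step(divided)
        # slow subtractive-exponential feedback; fixed point S = d e^(-k S)
        # is S = W(k d) / k (Lambert W, principal branch)
        if self._slow.state is None:
            from scipy.special import lambertw
            ks = c.slow_strength
            self._slow.state = np.real(lambertw(ks * divided)) / ks
        adapted = divided * np.exp(-c.slow_strength * self._slow.state)
        self._slow.step(adapted)
        compressed = naka_rushton(adapted, gain=1.0, half_saturation=c.nr_half)
        return compressed, self._slow.state.copy()

    def reset(self):
        self._vlpf.reset()
        self._fast.reset()
        self._slow.reset()


@dataclass
class LMCConfig:
    """Lamina constants: adaptation-driven temporal corner range, the
    adaptation range it maps from, spatial surround radius and the optional
    output squash."""

    corner_lo_hz: float = 0.5
    corner_hi_hz: float = 10.0
    adapt_lo: float = 1e-3
    adapt_hi: float = 10.0
    spatial_kernel_radius: int = 1
    use_tanh: bool = False
    sample_rate: float = 100.0


class Lamina:
    """Spatio-temporal redundancy reduction / edge enhancement."""

    def __init__(self, config: LMCConfig | None = None):
        self.config = config or LMCConfig()
        self._hpf = TemporalHighpass(self.config.corner_lo_hz,
                                     self.config.sample_rate)

    def step(self, compressed, adaptation):
        """One step: temporal leaky high-pass (per-pixel corner a monotone
        function of the photoreceptor adaptation level), then spatial
        high-pass, then optional tanh."""
        compressed = np.asarray(compressed, dtype=float)
        adaptation = np.asarray(adaptation, dtype=float)
        if compressed.shape != adaptation.shape:
            raise ValueError("compressed frame and adaptation map shapes differ")
        c = self.config
        corner = _log_linear_map(adaptation, c.adapt_lo, c.adapt_hi,
                                 c.corner_lo_hz, c.corner_hi_hz)
        out = self._hpf.step(compressed, corner_hz=corner)
        out = spatial_highpass(out, c.spatial_kernel_radius)
        if c.use_tanh:
            out = np.tanh(out)
        return out

    def reset(self):
        self._hpf.reset()


class EarlyVision:
    """Convenience wrapper chaining one photoreceptor and one lamina stage.

    The motion and target pipelines each own an independent instance: the
    stages share code but never state.
    """

    def __init__(self, prc_config: PRCConfig | None = None,
                 lmc_config: LMCConfig | None = None):
        self.prc = Photoreceptor(prc_config)
        self.lmc = Lamina(lmc_config)

    def step(self, raw_frame):
        compressed, adaptation = self.prc.step(raw_frame)
        return self.lmc.step(compressed, adaptation)

    def reset(self):
        self.prc.reset()
        self.lmc.reset()
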