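"""Full model wiring: early vision -> motion and target pathways, with the
suppression map routed to the configured inhibition locations.

Variant presets
---------------
``biv08``
    The original target-detection chain, no inhibition.
``biv19``
    Linear conditioning of the motion tap (gain 6, clipped at 1), injected
    at locations D and A.
``biv22-static``
    Saturating (Naka-Rushton) conditioning, G = 1.1, c = 0.02, locations
    A + B, pooling low-pass at the published 0.453 Hz corner.
``biv22-mli``
    As ``biv22-static`` with the pooling corner tuned to 4.0 Hz.
``biv22-dynamic``
    As ``biv22-mli`` with the half-saturation recomputed every frame from
    the global motion estimate.
``biv22-natural`` / ``biv22-manufactured``
    Static presets with c = 0.04 / 0.008, the operating points for purely
    natural and man-made-structure scenes.

The motion and target pathways own independent early-vision instances: they
share code, never state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import inhibition as inhib
from .early_vision import EarlyVision, LMCConfig, PRCConfig
from .inhibition import DynamicConditioningParams, InhibitionConfig
from .motion import (MLI_CORNER_PUBLISHED, MLI_CORNER_TUNED, MotionDetector,
                     MotionPooling, PoolingConfig, global_motion)
from .target import RectifyingTransientCell, RTCConfig, SmallTargetCorrelator


@dataclass
class StepResult:
    """Per-frame model outputs: dark/bright saliency, the raw motion tap,
    the suppression map actually applied (None for the uninhibited model),
    the scalar global motion estimate and the half-saturation in effect."""

    dark: np.ndarray
    bright: np.ndarray
    tap: np.ndarray
    suppression: np.ndarray | None
    global_motion: float
    half_saturation: float | None


class MotionBranch:
    """Early vision + motion detector + pooling; yields the inhibition tap."""

    def __init__(self, prc: PRCConfig | None = None,
                 lmc: LMCConfig | None = None,
                 emd_corner_hz: float = 3.0,
                 pooling: PoolingConfig | None = None,
                 sample_rate: float = 100.0):
        self.early = EarlyVision(prc, lmc)
        self.emd = MotionDetector(emd_corner_hz, sample_rate)
        self.pooling = MotionPooling(pooling)

    def step(self, raw_frame):
        """One frame -> (tap, global motion estimate)."""
        contrast = self.early.step(raw_frame)
        flow = self.emd.step(contrast)
        tap = self.pooling.tap(flow)
        return tap, global_motion(tap)

    def reset(self):
        self.early.reset()
        self.emd.reset()
        self.pooling.reset()


class BIVModel:
    """Complete small-target detection model with optional lateral inhibition.

    Construct from a preset name (``BIVModel.from_variant``) or from explicit
    stage configs.  ``inhibition_config=None`` gives the uninhibited model.
    """

    def __init__(self,
                 inhibition_config: InhibitionConfig | None = None,
                 pooling: PoolingConfig | None = None,
                 prc: PRCConfig | None = None,
                 lmc: LMCConfig | None = None,
                 rtc: RTCConfig | None = None,
                 emd_corner_hz: float = 3.0,
                 estmd_corner_hz: float = 3.0,
                 dynamic_params: DynamicConditioningParams | None = None,
                 sample_rate: float = 100.0):
        self.inhibition_config = inhibition_config
        self.dynamic_params = dynamic_params or DynamicConditioningParams()
        self.motion = MotionBranch(prc, lmc, emd_corner_hz, pooling,
                                   sample_rate)
        self.early = EarlyVision(prc, lmc)
        self.rtc = RectifyingTransientCell(rtc)
        self.estmd = SmallTargetCorrelator(estmd_corner_hz, sample_rate)

    @classmethod
    def from_variant(cls, name, **overrides):
        cfg = variant_config(name)
        return cls(inhibition_config=cfg["inhibition"],
                   pooling=cfg["pooling"], **overrides)

    def _suppression(self, tap, gm):
        cfg = self.inhibition_config
        if cfg is None:
            return None, None
        half = None
        if cfg.dynamic and gm > 0:
            half = inhib.dynamic_c(gm, self.dynamic_params)
        conditioned = inhib.condition(tap, cfg, half_saturation=half)
        return inhib.to_suppression(conditioned), \
            half if half is not None else cfg.half_saturation

    def step(self, raw_frame) -> StepResult:
        tap, gm = self.motion.step(raw_frame)
        suppression, half = self._suppression(tap, gm)
        locations = (self.inhibition_config.locations
                     if self.inhibition_config else frozenset())
        contrast = self.early.step(raw_frame)
        sup_a = suppression if "A" in locations else None
        thr_b = suppression if "B" in locations else None
        on, off = self.rtc.step(contrast, suppression=sup_a,
                                threshold_scale=thr_b)
        if "C" in locations:
            on = inhib.apply(on, suppression)
            off = inhib.apply(off, suppression)
        dark, bright = self.estmd.step(on, off)
        if "D" in locations:
            dark = inhib.apply(dark, suppression)
            bright = inhib.apply(bright, suppression)
        return StepResult(dark=dark, bright=bright, tap=tap,
                          suppression=suppression, global_motion=gm,
                          half_saturation=half)

    def reset(self):
        self.motion.reset()
        self.early.reset()
        self.rtc.reset()
        self.estmd.reset()


def variant_config(name):
    """Inhibition + pooling configuration for a named preset."""
    pooling_published = PoolingConfig(corner_hz=MLI_CORNER_PUBLISHED)
    pooling_tuned = PoolingConfig(corner_hz=MLI_CORNER_TUNED)
    presets = {
        "biv08": dict(inhibition=None, pooling=pooling_published),
        "biv19": dict(
            inhibition=InhibitionConfig(conditioning="linear",
                                        locations=frozenset("AD")),
            pooling=pooling_published),
        "biv22-static": dict(
            inhibition=InhibitionConfig(locations=frozenset("AB")),
            pooling=pooling_published),
        "biv22-mli": dict(
            inhibition=InhibitionConfig(locations=frozenset("AB")),
            pooling=pooling_tuned),
        "biv22-dynamic": dict(
            inhibition=InhibitionConfig(locations=frozenset("AB"),
                                        dynamic=True),
            pooling=pooling_tuned),
        "biv22-natural": dict(
            inhibition=InhibitionConfig(
                half_saturation=inhib.HALF_SATURATION_NATURAL,
                locations=frozenset("AB")),
            pooling=pooling_published),
        "biv22-manufactured": dict(
            inhibition=InhibitionConfig(
                half_saturation=inhib.HALF_SATURATION_MANUFACTURED,
                locations=frozenset("AB")),
            pooling=pooling_published),
    }
    if name not in presets:
        raise ValueError(f"unknown variant {name!r}; "
                         f"choose from {sorted(presets)}")
    return presets[name]


VARIANTS = ("biv08", "biv19", "biv22-static", "biv22-mli", "biv22-dynamic",
            "biv22-natural", "biv22-manufactured")
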