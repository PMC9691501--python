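"""Nonlinear optic-flow lateral inhibition.

The pooled local-motion tap ``E_MLI`` from the motion pathway is conditioned
with a saturating (Naka-Rushton) nonlinearity,

    E_MLIc_i = min(G * E_i / (E_i + c), 1),

subtracted from unity to give a per-pixel suppression factor

    s_i = 1 - E_MLIc_i      (1 where the scene is static, -> 0 in clutter)

and multiplied with the target-pathway signal at one or more injection
points.  The product form is algebraically identical to

    y_i = max((x_i c - x_i (G - 1) E_i) / (E_i + c), 0).

Defaults ``G = 1.1``, ``c = 0.02`` are the best general operating point
found on the original tuning scenes; ``c = 0.008`` suits scenes dominated by
man-made structure and ``c = 0.04`` purely natural scenes.  The optional
dynamic mode recomputes the half-saturation every frame from the global
motion estimate ``m`` through the log-linear law

    c = 0.013488 * ln(m) + 0.05514,

clamped below by ``c_floor`` because the law goes non-positive for very
small global motion.

The earlier linear scheme (the '19 model) conditions the tap as
``min(k * E, 1)`` with gain ``k = 6``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import naka_rushton

DEFAULT_GAIN = 1.1
DEFAULT_HALF_SATURATION = 0.02
HALF_SATURATION_MANUFACTURED = 0.008
HALF_SATURATION_NATURAL = 0.04
LINEAR_GAIN_BIV19 = 6.0

#: coefficients of the dynamic half-saturation law, c = slope*ln(m) + intercept
DYNAMIC_SLOPE = 0.013488
DYNAMIC_INTERCEPT = 0.05514

VALID_LOCATIONS = frozenset("ABCD")


@dataclass
class InhibitionConfig:
    """Where and how the suppression map is produced and injected.

    ``locations`` is a subset of {A, B, C, D}; B only makes sense together
    with A (it restores RTC triggering for transients attenuated at A).
    ``conditioning`` is "nonlinear" (saturating, the '22 scheme) or "linear"
    (the '19 scheme with gain ``linear_gain``).
    """

    gain: float = DEFAULT_GAIN
    half_saturation: float = DEFAULT_HALF_SATURATION
    locations: frozenset = field(default_factory=lambda: frozenset("AB"))
    conditioning: str = "nonlinear"
    linear_gain: float = LINEAR_GAIN_BIV19
    dynamic: bool = False
    c_floor: float = 1e-4

    def __post_init__(self):
        self.locations = frozenset(self.locations)
        if not self.locations <= VALID_LOCATIONS:
            raise ValueError(f"invalid inhibition locations {self.locations}")
        if "B" in self.locations and "A" not in self.locations:
            raise ValueError("location B is only valid together with location A")
        if self.conditioning not in ("nonlinear", "linear"):
            raise ValueError(f"unknown conditioning {self.conditioning!r}")
        if self.gain <= 0 or self.half_saturation <= 0:
            raise ValueError("gain and half_saturation must be positive")


@dataclass
class DynamicConditioningParams:
    """Log-linear law mapping global motion to the half-saturation c."""

    slope: float = DYNAMIC_SLOPE
    intercept: float = DYNAMIC_INTERCEPT
    c_floor: float = 1e-4

    def __post_init__(self):
        if self.c_floor <= 0:
            raise ValueError("c_floor must be positive")


def condition(tap, cfg: InhibitionConfig, half_saturation=None):
    """Condition the motion tap into [0, 1].

    ``half_saturation`` overrides the static c (used by the dynamic mode).
    """
    tap = np.asarray(tap, dtype=float)
    if cfg.conditioning == "linear":
        return np.minimum(cfg.linear_gain * tap, 1.0)
    c = cfg.half_saturation if half_saturation is None else half_saturation
    return naka_rushton(tap, gain=cfg.gain, half_saturation=c)


def to_suppression(conditioned):
    """Suppression factor s = 1 - conditioned motion, in [0, 1]."""
    conditioned = np.asarray(conditioned, dtype=float)
    if np.any(conditioned < 0) or np.any(conditioned > 1):
        raise ValueError("conditioned motion must lie in [0, 1]")
    return 1.0 - conditioned


def apply(signal, suppression):
    """Multiply a signal map by the suppression map."""
    signal = np.asarray(signal, dtype=float)
    suppression = np.asarray(suppression, dtype=float)
    if signal.shape != suppression.shape:
        raise ValueError("signal and suppression shapes differ")
    return signal * suppression


def dynamic_c(global_motion_value, params: DynamicConditioningParams | None = None):
    """Per-frame half-saturation from the global motion estimate.

    Returns ``max(slope * ln(m) + intercept, c_floor)``.  Raises for
    non-positive global motion; callers fall back to the static c in that
    case.
    """
    params = params or DynamicConditioningParams()
    m = float(global_motion_value)
    if m <= 0:
        raise ValueError("global motion must be positive for dynamic conditioning")
    return max(params.slope * np.log(m) + params.intercept, params.c_floor)


def fit_dynamic_coeffs(global_motions, best_cs, c_floor=1e-4):
    """Least-squares fit of c against ln(global motion).

    Mirrors how the dynamic law was obtained: each scenario contributes its
    best-performing half-saturation and its mean local motion; a straight
    line through (ln m, c) gives the slope and intercept.
    """
    m = np.asarray(global_motions, dtype=float)
    c = np.asarray(best_cs, dtype=float)
    if m.size != c.size or m.size < 2:
        raise ValueError("need at least two (motion, c) pairs")
    if np.any(m <= 0):
        raise ValueError("all global motions must be positive")
    x = np.log(m)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in ln(motion)")
    slope, intercept = np.polyfit(x, c, 1)
    return DynamicConditioningParams(slope=float(slope),
                                     intercept=float(intercept),
                                     c_floor=c_floor)
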