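"""Panoramic scene simulation.

Test imagery is a full 360-degree panorama rotating horizontally (right to
left) past the camera, with pixel-scale black square targets drifting at
their own speed.  Rendering happens at full resolution (8x the working
resolution), applies a Gaussian blur calibrated so the decimated point-spread
full-width-half-maximum is 1.0 px, and decimates with nearest-neighbour
sampling, emitting continuous-valued ground-truth target centres in decimated
coordinates.

Because the original high-dynamic-range panoramas are not redistributable,
the module also synthesises panoramas with natural-image statistics: a
random-phase field whose amplitude spectrum falls as 1/f (power as 1/f^2),
exponentiated into positive HDR luminance.  A ``clutter_gain`` factor boosts
spectral amplitudes above 0.5 cycles/degree to emulate scenes with differing
amounts of high-frequency clutter.

Sub-pixel motion uses linear interpolation at full resolution; when target
and background speeds are equal the composite is static relative to the
background, so the blurred composite is precomputed once and only shifted
per frame (exact, and much faster).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .filters import SPATIAL_MODE

#: FWHM of a Gaussian = FWHM_SIGMA_RATIO * sigma
FWHM_SIGMA_RATIO = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class ScenarioConfig:
    """Simulation parameters, in decimated coordinates unless stated.

    Defaults mirror the reference protocol: a 1000x200 working resolution
    decimated 8x from an 8000x1600 panorama spanning 360 x 72 degrees,
    100 frames/s, 500 black 1.2 px targets at least 10 px apart, blur FWHM
    1.0 px after decimation, 300 warm-up + 100 evaluation frames, and
    right-to-left motion at one of 10 / 17 / 29 / 50 px/s.
    """

    decimated_shape: tuple = (200, 1000)   # (rows, cols)
    decimation_factor: int = 8
    fps: float = 100.0
    background_speed: float = 29.0   # px/s, decimated coordinates
    target_speed: float = 29.0
    n_targets: int = 500
    target_size: float = 1.2         # px, decimated
    min_spacing: float = 10.0        # px between target centres, decimated
    blur_fwhm: float = 1.0           # decimated px
    warmup_frames: int = 300
    eval_frames: int = 100

    @property
    def full_shape(self):
        f = self.decimation_factor
        return (self.decimated_shape[0] * f, self.decimated_shape[1] * f)

    @property
    def n_frames(self):
        return self.warmup_frames + self.eval_frames

    @property
    def degrees_per_px(self):
        """Angular size of one decimated pixel (0.36 deg at 1000 px/360 deg)."""
        return 360.0 / self.decimated_shape[1]

    def px_to_degrees(self, px):
        return px * self.degrees_per_px

    def px_per_s_to_degrees_per_s(self, speed):
        return speed * self.degrees_per_px

    @property
    def blur_sigma_full(self):
        """Gaussian sigma at full resolution giving the decimated FWHM."""
        return self.blur_fwhm * self.decimation_factor / FWHM_SIGMA_RATIO


def _random_field(rng, size, amplitude):
    """Real random-phase field with the given rfft2 amplitude spectrum,
    normalised to zero mean, unit standard deviation."""
    spectrum = amplitude * (rng.standard_normal(amplitude.shape)
                            + 1j * rng.standard_normal(amplitude.shape))
    field = np.fft.irfft2(spectrum, s=size)
    field -= field.mean()
    std = field.std()
    return field / std if std > 0 else field


def _sigmoid_envelope(values, floor, sharpness, bias):
    return floor + (1.0 - floor) * 0.5 \
        * (1.0 + np.tanh(sharpness * (values - bias)))


def _envelope_rms(floor, sharpness, bias):
    """RMS of the clutter envelope over a standard normal driving field
    (Gauss-Legendre quadrature on +-8 sigma)."""
    x, wts = np.polynomial.legendre.leggauss(200)
    x = 8.0 * x
    wts = 8.0 * wts * np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    e = _sigmoid_envelope(x, floor, sharpness, bias)
    return float(np.sqrt(np.sum(wts * e * e)))


def synthesize_panorama(seed, clutter_gain=1.0, size=(1600, 8000),
                        mean_luminance=100.0, log_contrast=0.5,
                        clutter_cutoff_cpd=0.5, clutter_scale_deg=45.0,
                        clutter_floor=0.01, clutter_sharpness=1.5,
                        clutter_bias=2.0):
    """Random panorama with a 1/f amplitude (1/f^2 power) spectrum and
    spatially heterogeneous high-frequency clutter.

    The log-luminance field sums three bands: large-scale illumination
    (below ``1/clutter_scale_deg`` cycles/degree, unmodulated), mid-band
    structure, and high-frequency clutter above ``clutter_cutoff_cpd``
    cycles/degree.  The structured bands are modulated by a smooth random
    envelope so clutter forms patches (vegetation, rubble, buildings)
    against otherwise featureless regions (sky, open ground) — the
    heterogeneity a clutter-adaptive mechanism needs to have something to
    adapt to.  The modulated bands are rescaled by the reciprocal RMS of
    the default-coverage envelope, so at ``clutter_gain = 1`` the radially
    averaged power spectrum continues the 1/f^2 law across the bands while
    the sparse patches carry several log-units of local contrast (deep
    shadow gaps next to bright glints, as in real high-dynamic-range
    foliage).  ``clutter_gain`` widens the coverage: the envelope bias
    shifts by ``-ln(clutter_gain)``, so a higher gain clutters a larger
    fraction of the panorama and raises the high-band spectral magnitude.
    The field is exponentiated so luminance is strictly positive with an
    HDR-like long tail.  Horizontally periodic by construction;
    deterministic per seed.
    """
    h, w = size
    if h % 2 or w % 2:
        raise ValueError("panorama size must be even")
    if clutter_gain <= 0:
        raise ValueError("clutter_gain must be positive")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(h)[:, None]          # cycles / px
    fx = np.fft.rfftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    inv_f = np.zeros_like(f)
    inv_f[f > 0] = 1.0 / f[f > 0]
    px_per_degree = w / 360.0
    f_cpd = f * px_per_degree
    f_env = 1.0 / clutter_scale_deg
    # three bands: large-scale illumination (sky/ground luminance, not
    # modulated), mid-frequency structure and high-frequency clutter (both
    # modulated by the envelope so featureless regions really are flat)
    illum = _random_field(rng, size, np.where(f_cpd <= f_env, inv_f, 0.0))
    mid = _random_field(
        rng, size,
        np.where((f_cpd > f_env) & (f_cpd <= clutter_cutoff_cpd), inv_f, 0.0))
    high = _random_field(rng, size,
                         np.where(f_cpd > clutter_cutoff_cpd, inv_f, 0.0))
    envelope = _random_field(rng, size,
                             np.where(f_cpd <= f_env, inv_f, 0.0))
    bias = clutter_bias - np.log(clutter_gain)
    envelope = _sigmoid_envelope(envelope, clutter_floor, clutter_sharpness,
                                 bias)
    # frozen at the default coverage so clutter_gain raises total high-band
    # power instead of being renormalised away
    strength = 1.0 / _envelope_rms(clutter_floor, clutter_sharpness,
                                   clutter_bias)
    field = illum + strength * envelope * (mid + high)
    return mean_luminance * np.exp(log_contrast * field)


def place_targets(full_shape, cfg: ScenarioConfig, seed):
    """Rejection-sample target centres on the full-resolution panorama.

    Returns an (n, 2) array of continuous (row, col) centres whose pairwise
    distance (horizontal axis wrap-aware) is at least the configured spacing.
    Raises if the density is infeasible within the retry budget.
    """
    h, w = full_shape
    f = cfg.decimation_factor
    spacing = cfg.min_spacing * f
    half = cfg.target_size * f / 2.0
    rng = np.random.default_rng(seed)
    centres = []
    max_tries = 1000 * cfg.n_targets
    tries = 0
    while len(centres) < cfg.n_targets:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {cfg.n_targets} targets with spacing "
                f"{spacing:.1f} px on a {h}x{w} panorama"
            )
        row = rng.uniform(half, h - half)
        col = rng.uniform(0, w)
        ok = True
        for r, c in centres:
            dx = abs(col - c)
            dx = min(dx, w - dx)           # wrap at the panorama seam
            if np.hypot(row - r, dx) < spacing:
                ok = False
                break
        if ok:
            centres.append((row, col))
    return np.asarray(centres, dtype=float).reshape(-1, 2)


def fractional_roll(arr, shift):
    """Shift columns so that ``out[:, x] = arr[:, x + shift]`` (periodic),
    linearly interpolating fractional shifts."""
    i0 = int(np.floor(shift))
    frac = shift - i0
    out = np.roll(arr, -i0, axis=1)
    if frac:
        out = (1.0 - frac) * out + frac * np.roll(arr, -(i0 + 1), axis=1)
    return out


def _draw_targets(frame, centres, half_size):
    """Composite black squares (area-weighted sub-pixel edge coverage)."""
    h, w = frame.shape
    for row, col in centres:
        r0 = int(np.floor(row - half_size - 0.5))
        r1 = int(np.ceil(row + half_size + 0.5))
        c0 = int(np.floor(col - half_size - 0.5))
        c1 = int(np.ceil(col + half_size + 0.5))
        rows = np.arange(r0, r1 + 1)
        cols = np.arange(c0, c1 + 1)
        ov_r = np.clip(np.minimum(row + half_size, rows + 0.5)
                       - np.maximum(row - half_size, rows - 0.5), 0.0, 1.0)
        ov_c = np.clip(np.minimum(col + half_size, cols + 0.5)
                       - np.maximum(col - half_size, cols - 0.5), 0.0, 1.0)
        cov = ov_r[:, None] * ov_c[None, :]
        rr = np.clip(rows, 0, h - 1)
        cc = cols % w
        frame[np.ix_(rr, cc)] *= 1.0 - cov


class SceneRenderer:
    """Render decimated frames plus ground truth for one scenario.

    The background and the targets each translate right-to-left at their own
    speed.  When the two speeds are equal the blurred full-resolution
    composite is built once and shifted per frame; otherwise each frame is
    composited and blurred independently.
    """

    def __init__(self, panorama, targets, cfg: ScenarioConfig):
        panorama = np.asarray(panorama, dtype=float)
        if panorama.shape != cfg.full_shape:
            raise ValueError(
                f"panorama shape {panorama.shape} does not match the "
                f"configured full resolution {cfg.full_shape}"
            )
        self.cfg = cfg
        self.panorama = panorama
        self.targets = np.asarray(targets, dtype=float)
        self._matched = cfg.target_speed == cfg.background_speed
        if self._matched:
            composite = panorama.copy()
            half = cfg.target_size * cfg.decimation_factor / 2.0
            _draw_targets(composite, self.targets, half)
            self._blurred = ndimage.gaussian_filter(
                composite, cfg.blur_sigma_full, mode=SPATIAL_MODE)

    def _shifts(self, frame_index):
        f = self.cfg.decimation_factor
        t = frame_index / self.cfg.fps
        return (self.cfg.background_speed * f * t,
                self.cfg.target_speed * f * t)

    def ground_truth(self, frame_index):
        """Continuous decimated-coordinate target centres for a frame."""
        _, s_t = self._shifts(frame_index)
        f = self.cfg.decimation_factor
        w = self.cfg.full_shape[1]
        cols = (self.targets[:, 1] - s_t) % w
        return np.column_stack([self.targets[:, 0] / f, cols / f])

    def render(self, frame_index):
        """Return ``(decimated_frame, ground_truth)`` for one frame."""
        if frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        cfg = self.cfg
        s_b, s_t = self._shifts(frame_index)
        if self._matched:
            full = fractional_roll(self._blurred, s_b)
        else:
            full = fractional_roll(self.panorama, s_b)
            half = cfg.target_size * cfg.decimation_factor / 2.0
            w = cfg.full_shape[1]
            moved = self.targets.copy()
            moved[:, 1] = (moved[:, 1] - s_t) % w
            _draw_targets(full, moved, half)
            full = ndimage.gaussian_filter(full, cfg.blur_sigma_full,
                                           mode=SPATIAL_MODE)
        f = cfg.decimation_factor
        frame = full[::f, ::f]
        return frame, self.ground_truth(frame_index)

    def frames(self, n_frames=None):
        """Iterate ``(frame, truth)`` over the scenario."""
        n = self.cfg.n_frames if n_frames is None else n_frames
        for i in range(n):
            yield self.render(i)


def make_scene(cfg: ScenarioConfig, panorama_seed, placement_seed=None,
               clutter_gain=1.0):
    """Build a renderer from a synthetic panorama: the standard entry point
    when no measured panorama is available."""
    if placement_seed is None:
        placement_seed = panorama_seed + 10_000
    panorama = synthesize_panorama(panorama_seed, clutter_gain=clutter_gain,
                                   size=cfg.full_shape)
    targets = place_targets(cfg.full_shape, cfg, placement_seed)
    return SceneRenderer(panorama, targets, cfg)


def load_panorama(path):
    """Load a linear-radiometry panorama, keeping only the green channel.

    Accepts float TIFF/EXR-style images; gamma-encoded 8-bit input is
    rejected because the model expects linear luminance.
    """
    import imageio.v3 as iio

    image = iio.imread(path)
    if image.dtype == np.uint8:
        raise ValueError(
            f"{path}: 8-bit input is gamma-encoded; the model requires "
            "linear float radiometry"
        )
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        if image.shape[2] < 2:
            image = image[:, :, 0]
        else:
            image = image[:, :, 1]      # green channel
    if np.any(image < 0):
        raise ValueError(f"{path}: negative luminance values")
    return image
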