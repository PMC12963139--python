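"""Synthetic MTT drawings and twin cohorts with known ground truth.

Drawings are generated directly in the canonical channel convention.  A
pattern is an analytic deviation g(phi) expressed in units of the *local*
band width, so archetypes transfer across star shapes and sizes:

- ``ideal``            g = 0 (a well-performed trace)
- ``oscillation``      g = A sin(freq * phi): wiggling inside the band
- ``wide_oscillation`` the same with amplitude > 0.5, crossing both contours
- ``offset_out``/``offset_in``  constant radial displacement
- ``shortcut``         straight chords replacing the path around corners
- ``corner_error``     a burst of high-amplitude tremor in one angular window

The drawn radius is r(phi) = ideal_radius(phi) + g(phi) * band_width(phi);
the path is sampled densely (consecutive samples <= 0.5 px apart) and
stamped with a disk brush of diameter theta.  Radial tremor noise is drawn
at half-degree knots and interpolated, giving a pixel-coherent jitter; the
realized g (pattern plus noise) is returned for oracle checks.

Cohorts emulate a twin sample: one age per pair, a latent skill correlated
within pairs, and linear age effects injected into the oscillation
amplitude and radial offset.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from skimage.morphology import dilation, disk

from .errors import GeometryError
from .image import HarmonizedImage
from .metrics import angular_profile, count_errors, summarize
from .star import (StarBand, StarShape, _check_fits, band_mask, band_width,
                   ideal_radius, polar_to_pixel, shape_function)

TWO_PI = 2.0 * math.pi

PATTERNS = ("ideal", "oscillation", "offset_out", "offset_in",
            "wide_oscillation", "shortcut", "corner_error")

__all__ = [
    "PatternSpec",
    "CohortSpec",
    "default_band",
    "generate_star_image",
    "generate_drawing",
    "generate_cohort",
    "PATTERNS",
]


@dataclasses.dataclass(frozen=True)
class PatternSpec:
    """Controls for one synthetic drawing; the seed fixes it bit-exactly.

    ``amplitude``, ``offset`` and ``radial_noise_sd`` are fractions of the
    local band width; ``frequency`` is in cycles per revolution; ``theta``
    is the brush diameter in pixels.
    """

    pattern: str = "ideal"
    amplitude: float = 0.3
    frequency: float = 30.0
    offset: float = 0.0
    shortcut_corners: tuple[float, ...] = ()
    error_center_deg: float = 216.0
    error_window_deg: float = 20.0
    radial_noise_sd: float = 0.04
    theta: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.amplitude < 0 or self.radial_noise_sd < 0:
            raise ValueError("amplitude and noise sd must be non-negative")
        if not (0 < self.error_window_deg <= 90):
            raise ValueError("error_window_deg must lie in (0, 90]")
        if self.theta < 1:
            raise ValueError("theta must be >= 1")


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Controls for a synthetic twin cohort with injected linear age effects."""

    n_pairs: int = 60
    age_range: tuple[float, float] = (16.0, 79.0)
    within_pair_correlation: float = 0.5
    age_effect_on_amplitude: float = 0.003
    age_effect_on_offset: float = 0.0
    sex_ratio: float = 0.69  # fraction female
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 2:
            raise ValueError("need at least 2 pairs")
        if not (0.0 <= self.within_pair_correlation <= 1.0):
            raise ValueError("within_pair_correlation must be in [0, 1]")


def default_band(image_size: int = 512) -> StarBand:
    """Canonical five-pointed MTT star centred in a square raster."""
    shape = StarShape(r0=1.0, k=0.99, m=3.0, n=5, omega=0.0)
    c = (image_size - 1) / 2.0
    return StarBand(shape=shape, r_ext=0.41 * image_size,
                    r_int=0.31 * image_size, center=(c, c))


def _stamp(points_rc: np.ndarray, theta: int, dims) -> np.ndarray:
    """Mark sample pixels and dilate with a disk brush of diameter theta."""
    mask = np.zeros(dims, dtype=bool)
    ir = np.rint(points_rc[:, 0]).astype(int)
    ic = np.rint(points_rc[:, 1]).astype(int)
    if (ir < 0).any() or (ic < 0).any() or (ir >= dims[0]).any() or (ic >= dims[1]).any():
        raise GeometryError("path leaves the raster")
    mask[ir, ic] = True
    radius = (int(theta) - 1) // 2
    if radius > 0:
        mask = dilation(mask, disk(radius))
    return mask


def generate_star_image(band: StarBand, dims, border_px: int = 3) -> HarmonizedImage:
    """Empty-path harmonized image: filled band plus double contour.

    The border is defined radially — pixels within border_px/2 of either
    contour radius — which gives clean, sliver-free region boundaries.
    """
    _check_fits(band, dims, margin=border_px)
    rows, cols = dims
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    from .star import pixel_to_polar

    r, phi = pixel_to_polar(rr, cc, band.center)
    f = shape_function(phi, band.shape)
    half = border_px / 2.0
    border = (np.abs(r - band.r_ext * f) <= half) | \
             (np.abs(r - band.r_int * f) <= half)
    bmask = (r > band.r_int * f) & (r < band.r_ext * f) & ~border
    return HarmonizedImage(path_mask=np.zeros(dims, dtype=bool),
                           band_mask=bmask, border_mask=border,
                           source="synthetic")


def _noise_knots(rng: np.random.Generator, sd: float, n_knots: int = 720,
                 clip_sigmas: float = 3.0, smooth_knots: float = 4.0) -> np.ndarray:
    """Circularly smoothed Gaussian tremor with marginal sd ``sd``.

    White noise at the knots is low-passed with a circular Gaussian kernel
    (hand tremor drifts; it does not jump pixel to pixel) and rescaled so the
    marginal standard deviation stays ``sd``; values are clipped at
    ``clip_sigmas`` so noiseless margins bound the excursion.
    """
    if sd <= 0:
        return np.zeros(n_knots)
    knots = rng.normal(0.0, 1.0, size=n_knots)
    if smooth_knots > 0:
        half = int(math.ceil(3 * smooth_knots))
        kern = np.exp(-0.5 * (np.arange(-half, half + 1) / smooth_knots) ** 2)
        kern /= kern.sum()
        knots = np.convolve(np.r_[knots[-half:], knots, knots[:half]], kern,
                            mode="same")[half:-half]
        knots /= math.sqrt(float(np.sum(kern ** 2)))
    knots *= sd
    return np.clip(knots, -clip_sigmas * sd, clip_sigmas * sd)


def _pattern_g(spec: PatternSpec, noise: np.ndarray, error_noise: np.ndarray):
    """Build the realized deviation function g(phi) as a closure."""
    n_knots = len(noise)
    c_rad = math.radians(spec.error_center_deg)
    half_w = math.radians(spec.error_window_deg) / 2.0

    def g(phi):
        phi = np.asarray(phi, dtype=float) % TWO_PI
        if spec.pattern in ("oscillation", "wide_oscillation"):
            base = spec.offset + spec.amplitude * np.sin(spec.frequency * phi)
        elif spec.pattern == "offset_out":
            base = abs(spec.offset) * np.ones_like(phi)
        elif spec.pattern == "offset_in":
            base = -abs(spec.offset) * np.ones_like(phi)
        else:  # ideal, shortcut, corner_error: radially on the midline
            base = np.zeros_like(phi)
        x = phi / TWO_PI * n_knots
        base = base + _interp_periodic(x, noise)
        if spec.pattern == "corner_error":
            d = np.abs((phi - c_rad + math.pi) % TWO_PI - math.pi)
            inside = d < half_w
            if inside.any():
                taper = 0.5 * (1 + np.cos(math.pi * d[inside] / half_w))
                base[inside] = base[inside] + taper * _interp_periodic(
                    x[inside], error_noise)
        return base

    return g


def _interp_periodic(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    n = len(knots)
    i0 = np.floor(x).astype(int) % n
    i1 = (i0 + 1) % n
    frac = x - np.floor(x)
    return knots[i0] * (1 - frac) + knots[i1] * frac


def generate_drawing(spec: PatternSpec, band: StarBand | None = None,
                     dims=None):
    """Render one synthetic drawing.

    Returns ``(HarmonizedImage, g)`` where ``g(phi)`` is the realized
    band-width-fraction deviation actually rendered (pattern plus tremor),
    usable as ground truth for residual-pipeline checks.
    """
    if band is None:
        band = default_band()
    if dims is None:
        size = int(math.ceil(2 * band.r_ext / 0.82))
        dims = (size, size)
    star = generate_star_image(band, dims)

    rng = np.random.default_rng(spec.seed)
    noise = _noise_knots(rng, spec.radial_noise_sd)
    # corner_error: a dense burst of large tremor, rendered as extra retraces
    error_noise = _noise_knots(rng, max(spec.amplitude, 0.6), n_knots=2880,
                               clip_sigmas=1.5)
    g = _pattern_g(spec, noise, error_noise)

    nsamp = max(int(math.ceil(TWO_PI * band.r_ext / 0.25)), 1440)
    phi = np.linspace(0.0, TWO_PI, nsamp, endpoint=False)
    r = ideal_radius(phi, band) + g(phi) * band_width(phi, band)
    row, col = polar_to_pixel(r, phi, band.center)
    pts = np.stack([row, col], axis=1)
    if spec.pattern == "shortcut":
        pts = _apply_shortcuts(pts, phi, spec, band)
    path = _stamp(pts, spec.theta, dims)
    img = HarmonizedImage(path_mask=path, band_mask=star.band_mask,
                          border_mask=star.border_mask, source="synthetic")
    return img, g


def _apply_shortcuts(pts: np.ndarray, phi: np.ndarray, spec: PatternSpec,
                     band: StarBand, half_window_deg: float = 25.0):
    """Replace the path around listed corners by straight chords."""
    out = pts.copy()
    hw = math.radians(half_window_deg)
    for corner_deg in spec.shortcut_corners:
        c = math.radians(corner_deg)
        d = (phi - c + math.pi) % TWO_PI - math.pi
        inside = np.abs(d) < hw
        if not inside.any():
            continue
        p0 = pts[np.argmin(np.abs(d + hw))]
        p1 = pts[np.argmin(np.abs(d - hw))]
        t = (d[inside] + hw) / (2 * hw)
        out[inside] = p0[None, :] * (1 - t[:, None]) + p1[None, :] * t[:, None]
    return out


def generate_cohort(spec: CohortSpec, band: StarBand | None = None,
                    dims=None, compute_metrics: bool = True,
                    bin_width_deg: float = 1.0, keep_images: bool = False):
    """Simulate a twin cohort of drawings with linear age effects.

    One age per pair (twins share birthdays), a latent skill with the stated
    within-pair correlation, and per-drawing oscillation amplitude / radial
    offset that grow linearly with age.  Returns ``(table, images)`` where
    ``images`` is None unless ``keep_images``.
    """
    if band is None:
        band = default_band(384)
    if dims is None:
        size = int(math.ceil(2 * band.r_ext / 0.82))
        dims = (size, size)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    mid = 0.5 * (lo + hi)
    rho = spec.within_pair_correlation
    rows, images = [], []
    drawing_id = 0
    for pair in range(spec.n_pairs):
        age = float(rng.uniform(lo, hi))
        z_pair = rng.normal()
        for member in range(2):
            skill = math.sqrt(rho) * z_pair + math.sqrt(1 - rho) * rng.normal()
            amp = 0.12 + spec.age_effect_on_amplitude * (age - mid) + 0.04 * skill
            amp = float(np.clip(amp, 0.01, 0.45))
            off = spec.age_effect_on_offset * (age - mid) + 0.02 * skill
            off = float(np.clip(off, -0.35, 0.35))
            sex = "F" if rng.random() < spec.sex_ratio else "M"
            time_s = float(np.clip(45 + 0.6 * age + 8 * rng.normal(), 20, None))
            pspec = PatternSpec(pattern="oscillation", amplitude=amp,
                                frequency=25.0, offset=off,
                                radial_noise_sd=0.03, theta=5,
                                seed=int(rng.integers(0, 2**31 - 1)))
            row = {"id": f"d{drawing_id:04d}", "pair_id": f"p{pair:04d}",
                   "age": age, "sex": sex, "time_s": time_s,
                   "true_amplitude": amp, "true_offset": off}
            if compute_metrics or keep_images:
                img, _ = generate_drawing(pspec, band, dims)
                if compute_metrics:
                    from .image import estimate_thickness

                    theta = estimate_thickness(img.path_mask)
                    prof = angular_profile(img, band, theta, bin_width_deg)
                    summ = summarize(prof, count_errors(img), time_s, theta)
                    row.update(errors=summ.errors,
                               mean_density=summ.mean_density,
                               sum_sq_residuals=summ.sum_sq_residuals,
                               theta=theta)
                if keep_images:
                    images.append(img)
            rows.append(row)
            drawing_id += 1
    return pd.DataFrame(rows), (images if keep_images else None)
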