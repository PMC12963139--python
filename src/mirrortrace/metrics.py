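"""Per-drawing metrics: polar residuals, angular density, errors, summaries.

A drawn pixel at polar position (r, phi) gets the harmonized residual

    residual = (r - ideal_radius(phi)) / band_width(phi)

which is 0 on the ideal midline, +0.5 on the external contour and -0.5 on
the internal one, independent of star size or shape.  Density per angular
bin is the drawn pixel count divided by the pixel count of the *expected*
star (the ideal midline dilated to the measured pen thickness) in the same
bin, so a perfect trace has density 1 everywhere and retracing pushes it
above 1, independent of the pen used.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np
from scipy import stats
from skimage.measure import label as cc_label

from .errors import ConfigurationError, SummaryError
from .image import HarmonizedImage
from .star import StarBand, band_width, ideal_radius, pixel_to_polar, render_expected_star

TWO_PI = 2.0 * np.pi

__all__ = [
    "PolarTrace",
    "AngularProfile",
    "DrawingSummary",
    "path_to_polar",
    "residual",
    "density_profile",
    "density_profile_legacy",
    "residual_profile",
    "angular_profile",
    "count_errors",
    "summarize",
    "boxcox_z",
]


@dataclasses.dataclass
class PolarTrace:
    """Per-pixel polar description of the drawn path."""

    r: np.ndarray
    phi: np.ndarray
    residual: np.ndarray

    def __len__(self) -> int:
        return len(self.r)


@dataclasses.dataclass
class AngularProfile:
    """Angle-binned description of one drawing.

    Bins are half-open [d, d + bin_width) degrees, clockwise from the top.
    Residual statistics are NaN for bins containing no drawn pixel.
    """

    bin_width_deg: float
    density: np.ndarray
    mean_residual: np.ndarray
    mean_abs_residual: np.ndarray
    mean_sq_residual: np.ndarray
    n_pixels: np.ndarray
    band_area_px: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.density)

    @property
    def bin_left_deg(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width_deg


@dataclasses.dataclass
class DrawingSummary:
    """Traditional (errors, time) and profile-derived scalars for a drawing."""

    errors: int
    time_s: float | None
    mean_density: float
    sum_sq_residuals: float
    theta: int


def _n_bins(bin_width_deg: float) -> int:
    nb = 360.0 / bin_width_deg
    if abs(nb - round(nb)) > 1e-9:
        raise ConfigurationError(f"bin width {bin_width_deg} does not divide 360")
    return int(round(nb))


def _bin_index(phi: np.ndarray, n_bins: int) -> np.ndarray:
    return np.minimum((phi / TWO_PI * n_bins).astype(int), n_bins - 1)


def residual(phi, r, band: StarBand):
    """Harmonized signed radial deviation from the ideal star."""
    return (np.asarray(r, dtype=float) - ideal_radius(phi, band)) / band_width(phi, band)


def path_to_polar(path_mask: np.ndarray, band: StarBand) -> PolarTrace:
    """Polar coordinates and residual for every drawn pixel."""
    coords = np.argwhere(path_mask)
    if len(coords) == 0:
        return PolarTrace(r=np.empty(0), phi=np.empty(0), residual=np.empty(0))
    r, phi = pixel_to_polar(coords[:, 0], coords[:, 1], band.center)
    return PolarTrace(r=r, phi=phi, residual=residual(phi, r, band))


@lru_cache(maxsize=32)
def _expected_bin_counts(band: StarBand, theta: int, dims: tuple[int, int],
                         n_bins: int) -> np.ndarray:
    mask = render_expected_star(band, theta, dims)
    coords = np.argwhere(mask)
    _, phi = pixel_to_polar(coords[:, 0], coords[:, 1], band.center)
    counts = np.bincount(_bin_index(phi, n_bins), minlength=n_bins)
    if (counts == 0).any():
        raise ConfigurationError(
            "expected star leaves empty angular bins; bin width too narrow "
            "for this raster"
        )
    return counts


def density_profile(path_mask: np.ndarray, band: StarBand, theta: int,
                    bin_width_deg: float = 1.0) -> np.ndarray:
    """Per-bin drawn-pixel count over expected-star pixel count."""
    n_bins = _n_bins(bin_width_deg)
    expected = _expected_bin_counts(band, int(theta), path_mask.shape, n_bins)
    trace = path_to_polar(path_mask, band)
    drawn = np.bincount(_bin_index(trace.phi, n_bins), minlength=n_bins) \
        if len(trace) else np.zeros(n_bins, dtype=int)
    return drawn / expected


def density_profile_legacy(path_mask: np.ndarray, band_mask: np.ndarray,
                           band: StarBand, theta: int,
                           bin_width_deg: float = 1.0) -> np.ndarray:
    """Superseded density: pixels over (band area x thickness) per bin.

    Retained for comparison only; the area normalization over-weights the
    corners, which motivated the expected-star formulation.
    """
    n_bins = _n_bins(bin_width_deg)
    coords = np.argwhere(band_mask)
    _, phi = pixel_to_polar(coords[:, 0], coords[:, 1], band.center)
    area = np.bincount(_bin_index(phi, n_bins), minlength=n_bins)
    if (area == 0).any():
        raise ConfigurationError("zero band area in a bin; bin width too narrow")
    trace = path_to_polar(path_mask, band)
    drawn = np.bincount(_bin_index(trace.phi, n_bins), minlength=n_bins) \
        if len(trace) else np.zeros(n_bins, dtype=int)
    return drawn / (area * theta)


_STATS = {"mean": lambda v: v, "mean_abs": np.abs, "mean_sq": np.square}


def residual_profile(trace: PolarTrace, bin_width_deg: float = 1.0,
                     stat: str = "mean") -> np.ndarray:
    """Per-bin aggregate of pixel residuals; empty bins are NaN."""
    if stat not in _STATS:
        raise ValueError(f"unknown stat {stat!r}; choose from {sorted(_STATS)}")
    n_bins = _n_bins(bin_width_deg)
    out = np.full(n_bins, np.nan)
    if len(trace) == 0:
        return out
    idx = _bin_index(trace.phi, n_bins)
    vals = _STATS[stat](trace.residual)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    good = counts > 0
    out[good] = sums[good] / counts[good]
    return out


def angular_profile(img: HarmonizedImage, band: StarBand, theta: int,
                    bin_width_deg: float = 1.0) -> AngularProfile:
    """Full per-bin profile of one harmonized drawing."""
    n_bins = _n_bins(bin_width_deg)
    trace = path_to_polar(img.path_mask, band)
    dens = density_profile(img.path_mask, band, theta, bin_width_deg)
    coords = np.argwhere(img.band_mask)
    if len(coords):
        _, bphi = pixel_to_polar(coords[:, 0], coords[:, 1], band.center)
        area = np.bincount(_bin_index(bphi, n_bins), minlength=n_bins)
    else:
        area = np.zeros(n_bins, dtype=int)
    n_pix = np.bincount(_bin_index(trace.phi, n_bins), minlength=n_bins) \
        if len(trace) else np.zeros(n_bins, dtype=int)
    return AngularProfile(
        bin_width_deg=bin_width_deg,
        density=dens,
        mean_residual=residual_profile(trace, bin_width_deg, "mean"),
        mean_abs_residual=residual_profile(trace, bin_width_deg, "mean_abs"),
        mean_sq_residual=residual_profile(trace, bin_width_deg, "mean_sq"),
        n_pixels=n_pix,
        band_area_px=area,
    )


def count_errors(img: HarmonizedImage) -> int:
    """Number of excursions of the trace beyond either contour.

    An excursion is a maximal 8-connected component of path pixels outside
    the permitted region (band plus border); touching the border itself is
    not an error.
    """
    outside = img.path_mask & ~(img.band_mask | img.border_mask)
    if not outside.any():
        return 0
    return int(cc_label(outside, connectivity=2).max())


def summarize(profile: AngularProfile, errors: int, time_s: float | None,
              theta: int) -> DrawingSummary:
    """Collapse a profile to scalars: mean density, sum of squared residuals.

    The residual summary sums the squared *per-bin mean* residuals over the
    fixed 360/bin-width bins (missing bins excluded), keeping it independent
    of pixel count; the density summary is the plain mean over bins.
    """
    good = ~np.isnan(profile.mean_residual)
    if not good.any():
        raise SummaryError("no bins contain drawn pixels")
    return DrawingSummary(
        errors=int(errors),
        time_s=time_s,
        mean_density=float(np.mean(profile.density)),
        sum_sq_residuals=float(np.sum(profile.mean_residual[good] ** 2)),
        theta=int(theta),
    )


def boxcox_z(values) -> tuple[np.ndarray, float]:
    """Box-Cox transform (profile-MLE lambda) then z-score.

    Values are shifted by (1e-6 - min) when the minimum is non-positive.
    Returns (z_scores, lambda_hat).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 values for Box-Cox")
    if np.ptp(v) == 0:
        raise ValueError("constant input: Box-Cox standardization undefined")
    if v.min() <= 0:
        v = v + (1e-6 - v.min())
    transformed, lmbda = stats.boxcox(v)
    z = (transformed - transformed.mean()) / transformed.std(ddof=0)
    return z, float(lmbda)
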