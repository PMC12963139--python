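"""Analytic model of the double-contour Mirror Tracing Task star.

The star border is described in polar coordinates by

    r(phi) = r0 * cos((2*asin(k) + pi*m) / (2n))
                / cos((2*asin(k*cos(n*(phi + omega))) + pi*m) / (2n))

where ``r0`` sets the radial scale (the radius at the outer corners), ``k``
in (0, 1] controls corner roundness, ``m`` the side bending/depth, ``n`` the
number of vertices and ``omega`` a phase rotation.  The printed MTT figure is
a *double* contour: an outer and an inner copy of the same shape function
``f(phi)`` scaled by two radii.  The midline between them ("ideal star") is
the target trajectory of a perfect trace.

Angle convention: phi = 0 at the topmost point of the star (the drawing
start) and increases clockwise.  With 0-based (row, col) raster coordinates
(row increasing downward) this is ``phi = atan2(col - c_col, c_row - row)``
taken modulo 2*pi.  Angles are radians internally, degrees in files and
reports.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import yaml
from scipy import optimize
from skimage.morphology import dilation, disk

from .errors import FitError, GeometryError, InvalidBandError, InvalidShapeError

__all__ = [
    "StarShape",
    "StarBand",
    "CornerSet",
    "StarFit",
    "star_radius",
    "shape_function",
    "ideal_radius",
    "band_width",
    "corner_angles",
    "render_ideal_star",
    "render_expected_star",
    "band_mask",
    "pixel_to_polar",
    "polar_to_pixel",
    "fit_star_parameters",
    "band_to_dict",
    "band_from_dict",
    "save_band",
    "load_band",
    "DEFAULT_SHAPE",
]

TWO_PI = 2.0 * math.pi


@dataclasses.dataclass(frozen=True)
class StarShape:
    """Parameters of the star-shape radius function.

    Attributes
    ----------
    r0 : float
        Radial scale in pixels; the radius attained at the outer corners.
    k : float
        Corner roundness, 0 < k <= 1.  k -> 1 gives sharp corners, k -> 0
        degenerates to a circle of radius ``r0``.
    m : float
        Side bending / depth.  m = 3 with k -> 1 reproduces the regular
        pentagram radius ratio cos(72)/cos(36) for n = 5.
    n : int
        Number of vertices, >= 3.
    omega : float
        Phase rotation in radians (clockwise, like phi).
    """

    r0: float = 1.0
    k: float = 0.99
    m: float = 3.0
    n: int = 5
    omega: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.k <= 1.0):
            raise InvalidShapeError(f"k must lie in [0, 1], got {self.k}")
        if int(self.n) != self.n or self.n < 3:
            raise InvalidShapeError(f"n must be an integer >= 3, got {self.n}")
        if self.r0 <= 0:
            raise InvalidShapeError(f"r0 must be positive, got {self.r0}")
        # The cosine argument in the denominator must stay strictly inside
        # (-pi/2, pi/2) for every phi, so r(phi) is finite and positive.
        a = 2.0 * math.asin(self.k)
        hi = (a + math.pi * self.m) / (2.0 * self.n)
        lo = (-a + math.pi * self.m) / (2.0 * self.n)
        if not (-math.pi / 2 < lo and hi < math.pi / 2):
            raise InvalidShapeError(
                f"parameters k={self.k}, m={self.m}, n={self.n} drive the "
                f"denominator argument outside (-pi/2, pi/2): [{lo}, {hi}]"
            )


DEFAULT_SHAPE = StarShape(r0=1.0, k=0.99, m=3.0, n=5, omega=0.0)


@dataclasses.dataclass(frozen=True)
class StarBand:
    """The double contour: one shape function scaled by two radii.

    ``shape.r0`` is ignored; ``r_ext`` and ``r_int`` are the outer/inner
    contour scales.  ``center`` is a sub-pixel (row, col) position.
    """

    shape: StarShape
    r_ext: float
    r_int: float
    center: tuple[float, float]

    def __post_init__(self):
        if not (self.r_ext > self.r_int > 0):
            raise InvalidBandError(
                f"need r_ext > r_int > 0, got r_ext={self.r_ext}, r_int={self.r_int}"
            )

    @property
    def r_mid(self) -> float:
        return 0.5 * (self.r_ext + self.r_int)


@dataclasses.dataclass(frozen=True)
class CornerSet:
    """Corner angles in degrees in [0, 360), sorted ascending."""

    outer: tuple[float, ...]
    inner: tuple[float, ...]


@dataclasses.dataclass(frozen=True)
class StarFit:
    """Result of :func:`fit_star_parameters`."""

    band: StarBand
    rms: float
    n_pixels: int


def shape_function(phi, shape: StarShape):
    """The unit-scale shape function f(k, m, n, omega, phi); f = 1 at outer corners."""
    phi = np.asarray(phi, dtype=float)
    a = 2.0 * math.asin(shape.k) + math.pi * shape.m
    num = math.cos(a / (2.0 * shape.n))
    arg = (2.0 * np.arcsin(shape.k * np.cos(shape.n * (phi + shape.omega)))
           + math.pi * shape.m) / (2.0 * shape.n)
    den = np.cos(arg)
    if np.any(den <= 0):
        raise InvalidShapeError("non-positive denominator in shape function")
    return num / den


def star_radius(phi, shape: StarShape):
    """Radius of the star border at angle(s) ``phi`` (radians)."""
    return shape.r0 * shape_function(phi, shape)


def ideal_radius(phi, band: StarBand):
    """Radius of the ideal (midline) star: the mean of the two contours."""
    return band.r_mid * shape_function(phi, band.shape)


def band_width(phi, band: StarBand):
    """Radial distance between the two contours at angle(s) ``phi``."""
    return (band.r_ext - band.r_int) * shape_function(phi, band.shape)


def corner_angles(shape: StarShape) -> CornerSet:
    """Corner angles of the star, degrees clockwise from the top.

    Outer corners (radius maxima) sit where cos(n*(phi + omega)) = 1, inner
    corners (minima) where it equals -1; consecutive same-type corners are
    360/n degrees apart.
    """
    n = shape.n
    w = math.degrees(shape.omega)
    step = 360.0 / n
    outer = sorted(((-w + j * step) % 360.0) for j in range(n))
    inner = sorted(((-w + step / 2.0 + j * step) % 360.0) for j in range(n))
    # kill float fuzz like 359.99999999999994
    outer = tuple(round(v, 9) % 360.0 for v in outer)
    inner = tuple(round(v, 9) % 360.0 for v in inner)
    return CornerSet(outer=outer, inner=inner)


def pixel_to_polar(rows, cols, center):
    """(row, col) -> (r, phi) under the top/clockwise convention."""
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    dr = center[0] - rows  # positive upward
    dc = cols - center[1]  # positive rightward
    r = np.hypot(dr, dc)
    phi = np.arctan2(dc, dr) % TWO_PI
    return r, phi


def polar_to_pixel(r, phi, center):
    """(r, phi) -> float (row, col)."""
    r = np.asarray(r, dtype=float)
    phi = np.asarray(phi, dtype=float)
    row = center[0] - r * np.cos(phi)
    col = center[1] + r * np.sin(phi)
    return row, col


def _check_fits(band: StarBand, raster_dims, margin: float = 0.0):
    rows, cols = raster_dims
    rmax = band.r_ext + margin
    cr, cc = band.center
    if cr - rmax < 0 or cc - rmax < 0 or cr + rmax > rows - 1 or cc + rmax > cols - 1:
        raise GeometryError(
            f"star of outer radius {band.r_ext:.1f} at center {band.center} "
            f"does not fit a {rows}x{cols} raster"
        )


def _dense_curve_pixels(radius_scale: float, band: StarBand, raster_dims,
                        max_gap: float = 0.02):
    """Integer pixels traversed by r = radius_scale * f(phi), in order.

    Samples the curve densely, subdividing until consecutive samples are at
    most ``max_gap`` px apart, then rounds and removes consecutive duplicates.
    """
    n0 = max(int(math.ceil(TWO_PI * radius_scale / (0.25 * max_gap))), 720)
    phi = np.linspace(0.0, TWO_PI, n0, endpoint=False)
    for _ in range(12):
        f = shape_function(phi, band.shape)
        row, col = polar_to_pixel(radius_scale * f, phi, band.center)
        gaps = np.hypot(np.diff(row, append=row[0]), np.diff(col, append=col[0]))
        bad = gaps > max_gap
        if not bad.any():
            break
        nxt = np.roll(phi, -1)
        nxt[-1] += TWO_PI
        mids = 0.5 * (phi[bad] + nxt[bad])
        phi = np.sort(np.concatenate([phi, mids]))
    ir = np.rint(row).astype(np.int64)
    ic = np.rint(col).astype(np.int64)
    keep = np.ones(len(ir), dtype=bool)
    keep[1:] = (ir[1:] != ir[:-1]) | (ic[1:] != ic[:-1])
    ir, ic = ir[keep], ic[keep]
    if len(ir) > 1 and ir[0] == ir[-1] and ic[0] == ic[-1]:
        ir, ic = ir[:-1], ic[:-1]
    # revisits of earlier pixels (the rounded loop may touch a pixel twice)
    seen = set()
    order = []
    for idx, (a, b) in enumerate(zip(ir.tolist(), ic.tolist())):
        if (a, b) not in seen:
            seen.add((a, b))
            order.append(idx)
    return np.stack([ir[order], ic[order]], axis=1)


def render_ideal_star(band: StarBand, raster_dims) -> np.ndarray:
    """Pixels traversed by the continuous ideal-star curve, as (M, 2) ints.

    The result is a single closed 8-connected loop in traversal order; every
    pixel center lies within half a pixel diagonal (perpendicular distance)
    of the continuous curve.  Sampling is dense enough (consecutive samples
    well under half a pixel apart) that the set converges to all pixels the
    continuous line passes through.
    """
    _check_fits(band, raster_dims)
    return _dense_curve_pixels(band.r_mid, band, raster_dims)


def render_expected_star(band: StarBand, theta: int, raster_dims) -> np.ndarray:
    """Boolean mask of the expected star: ideal pixels dilated to thickness theta.

    The ideal pixel loop is dilated with a disk structuring element of radius
    floor((theta - 1) / 2); theta = 1 leaves the loop unchanged.
    """
    if theta < 1 or int(theta) != theta:
        raise ValueError(f"theta must be an integer >= 1, got {theta}")
    pix = render_ideal_star(band, raster_dims)
    mask = np.zeros(raster_dims, dtype=bool)
    mask[pix[:, 0], pix[:, 1]] = True
    radius = (int(theta) - 1) // 2
    if radius > 0:
        mask = dilation(mask, disk(radius))
    return mask


def band_mask(band: StarBand, raster_dims) -> np.ndarray:
    """Boolean mask of pixels radially strictly between the two contours."""
    _check_fits(band, raster_dims)
    rows, cols = raster_dims
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    r, phi = pixel_to_polar(rr, cc, band.center)
    f = shape_function(phi, band.shape)
    return (r > band.r_int * f) & (r < band.r_ext * f)


# ---------------------------------------------------------------------------
# Parameter fitting from a border mask
# ---------------------------------------------------------------------------

def _estimate_n(phi: np.ndarray, r: np.ndarray, n_max: int = 18) -> int:
    """Dominant harmonic of the angle-binned mean radius."""
    nbins = 360
    idx = np.minimum((phi / TWO_PI * nbins).astype(int), nbins - 1)
    sums = np.bincount(idx, weights=r, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    series = np.full(nbins, np.nan)
    good = counts > 0
    series[good] = sums[good] / counts[good]
    if (~good).any():
        xs = np.arange(nbins)
        series[~good] = np.interp(xs[~good], xs[good], series[good], period=nbins)
    spec = np.abs(np.fft.rfft(series - series.mean()))
    h = np.arange(len(spec))
    cand = (h >= 3) & (h <= n_max)
    return int(h[cand][np.argmax(spec[cand])])


def fit_star_parameters(border_mask: np.ndarray, n_vertices: int | None = None,
                        rms_ceiling: float = 10.0,
                        max_pixels: int = 20000) -> StarFit:
    """Fit a :class:`StarBand` to the binary mask of the two contours.

    Estimates the center from the border-pixel centroid, splits pixels into
    outer/inner contours by the per-angle mid radius, estimates ``n`` as the
    dominant harmonic of the binned mean radius when not supplied, then
    jointly refines (center, r_ext, r_int, k, m, omega) by nonlinear least
    squares of the shape function against both contours.
    """
    coords = np.argwhere(border_mask)
    min_pix = 16 * (n_vertices or 3)
    if len(coords) < min_pix:
        raise FitError(
            "too few border pixels for a star fit",
            {"n_pixels": int(len(coords)), "required": min_pix},
        )
    if len(coords) > max_pixels:
        stride = int(math.ceil(len(coords) / max_pixels))
        coords = coords[::stride]
    center0 = coords.mean(axis=0)
    r, phi = pixel_to_polar(coords[:, 0], coords[:, 1], center0)
    n = int(n_vertices) if n_vertices else _estimate_n(phi, r)

    # split outer/inner by per-angle mid radius
    nbins = 360
    idx = np.minimum((phi / TWO_PI * nbins).astype(int), nbins - 1)
    mins = np.full(nbins, np.inf)
    maxs = np.full(nbins, -np.inf)
    np.minimum.at(mins, idx, r)
    np.maximum.at(maxs, idx, r)
    mid = 0.5 * (mins + maxs)
    is_outer = r > mid[idx]

    # initial shape estimates
    r_ext0 = float(np.quantile(r[is_outer], 0.98)) if is_outer.any() else float(r.max())
    r_int0 = float(np.quantile(r[~is_outer], 0.98)) if (~is_outer).any() else r_ext0 * 0.7
    # phase of the n-th harmonic of the mean radius locates the outer corners
    c = np.sum(r * np.exp(-1j * n * phi))
    omega0 = float(np.angle(c)) / n
    k0, m0 = 0.95, 3.0

    rows_ = coords[:, 0].astype(float)
    cols_ = coords[:, 1].astype(float)

    def resid(p):
        cr, cc, re, ri, k, m, w = p
        rr, pp = pixel_to_polar(rows_, cols_, (cr, cc))
        a = 2.0 * np.arcsin(k) + math.pi * m
        num = math.cos(a / (2.0 * n))
        arg = (2.0 * np.arcsin(k * np.cos(n * (pp + w))) + math.pi * m) / (2.0 * n)
        f = num / np.cos(arg)
        scale = np.where(is_outer, re, ri)
        return rr - scale * f

    # validity of the denominator requires |(+-2asin(k) + pi*m)| < pi*n
    m_hi = n - 1.0 - 1e-3
    p0 = np.array([center0[0], center0[1], r_ext0, r_int0, k0,
                   min(m0, m_hi - 0.1), omega0])
    lo = [center0[0] - 50, center0[1] - 50, 1.0, 0.5, 1e-3, -m_hi, omega0 - math.pi / n]
    hi = [center0[0] + 50, center0[1] + 50, 4 * r_ext0, 4 * r_ext0, 1.0 - 1e-6,
          m_hi, omega0 + math.pi / n]
    sol = optimize.least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                 x_scale=[1, 1, 10, 10, 0.05, 0.5, 0.02])
    cr, cc, re, ri, k, m, w = sol.x
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    if rms > rms_ceiling:
        raise FitError("star fit RMS above ceiling",
                       {"rms": rms, "ceiling": rms_ceiling, "n": n})
    if re < ri:
        re, ri = ri, re
    shape = StarShape(r0=1.0, k=float(k), m=float(m), n=n, omega=float(w % TWO_PI))
    band = StarBand(shape=shape, r_ext=float(re), r_int=float(ri),
                    center=(float(cr), float(cc)))
    return StarFit(band=band, rms=rms, n_pixels=int(len(coords)))


# ---------------------------------------------------------------------------
# Serialization (degrees in files, radians internally)
# ---------------------------------------------------------------------------

def band_to_dict(band: StarBand) -> dict:
    return {
        "r_ext": float(band.r_ext),
        "r_int": float(band.r_int),
        "k": float(band.shape.k),
        "m": float(band.shape.m),
        "n": int(band.shape.n),
        "omega_deg": math.degrees(band.shape.omega),
        "center": [float(band.center[0]), float(band.center[1])],
    }


def band_from_dict(d: dict) -> StarBand:
    shape = StarShape(r0=1.0, k=float(d["k"]), m=float(d["m"]), n=int(d["n"]),
                      omega=math.radians(float(d.get("omega_deg", 0.0))))
    return StarBand(shape=shape, r_ext=float(d["r_ext"]), r_int=float(d["r_int"]),
                    center=(float(d["center"][0]), float(d["center"][1])))


def save_band(band: StarBand, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(band_to_dict(band), fh)


def load_band(path) -> StarBand:
    with open(path) as fh:
        return band_from_dict(yaml.safe_load(fh))
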