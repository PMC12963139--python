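"""Canonical RGB drawing format, scan segmentation, and global measurements.

Harmonized MTT images use one RGB channel per semantic layer: the drawn path
in red, the drawable inner star (the region between the two contours) in
green, and the star border in blue.  Raw scans and screenshots are segmented
into this convention by hue/intensity rules plus a star fit for the band.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.color import rgb2hsv
from skimage.morphology import skeletonize

from . import star as star_mod
from .errors import FormatError, MirrorTraceError
from .star import fit_star_parameters

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizedImage",
    "load_harmonized",
    "save_harmonized",
    "harmonize_scan",
    "estimate_thickness",
    "estimate_center",
]


@dataclasses.dataclass
class HarmonizedImage:
    """Three binary masks on a shared raster plus source metadata."""

    path_mask: np.ndarray
    band_mask: np.ndarray
    border_mask: np.ndarray
    source: str = "synthetic"
    time_s: float | None = None

    def __post_init__(self):
        if not (self.path_mask.shape == self.band_mask.shape == self.border_mask.shape):
            raise FormatError("all masks must share the raster dimensions")
        if (self.band_mask & self.border_mask).any():
            raise FormatError("band and border masks must be disjoint")

    @property
    def dims(self) -> tuple[int, int]:
        return self.path_mask.shape


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def load_harmonized(image_file, threshold: int = 127) -> HarmonizedImage:
    """Read a canonical RGB PNG: R -> path, G -> band, B -> border."""
    path = Path(image_file)
    try:
        with Image.open(path) as im:
            if im.mode not in ("RGB", "RGBA"):
                if im.mode in ("P", "L", "1"):
                    raise FormatError(f"{path}: not an RGB raster (mode {im.mode})")
                im = im.convert("RGB")
            arr = np.asarray(im.convert("RGB"))
    except (OSError, UnidentifiedImageError) as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    source, time_s = "file", None
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        source = meta.get("source", source)
        time_s = meta.get("time_s")
    return HarmonizedImage(
        path_mask=arr[..., 0] > threshold,
        band_mask=arr[..., 1] > threshold,
        border_mask=arr[..., 2] > threshold,
        source=source,
        time_s=time_s,
    )


def save_harmonized(img: HarmonizedImage, path) -> None:
    """Write an 8-bit RGB PNG with masks at value 255; lossless round trip."""
    path = Path(path)
    arr = np.zeros((*img.dims, 3), dtype=np.uint8)
    arr[..., 0] = np.where(img.path_mask, 255, 0)
    arr[..., 1] = np.where(img.band_mask, 255, 0)
    arr[..., 2] = np.where(img.border_mask, 255, 0)
    Image.fromarray(arr, mode="RGB").save(path, format="PNG")
    if img.time_s is not None or img.source not in ("file", "synthetic"):
        _sidecar(path).write_text(
            json.dumps({"source": img.source, "time_s": img.time_s})
        )


def _looks_canonical(arr: np.ndarray, frac: float = 0.99) -> bool:
    """True when nearly all channel values are saturated low or high."""
    extreme = (arr < 32) | (arr > 223)
    return float(extreme.all(axis=-1).mean()) >= frac


def harmonize_scan(rgb_image: np.ndarray, profile: str = "paper",
                   n_vertices: int | None = 5) -> HarmonizedImage:
    """Segment a raw scan/screenshot into the canonical channel convention.

    The printed star outline is isolated by a blue hue window; the pen trace
    by saturated non-blue hues or sufficiently dark strokes (gray/black pens
    included).  The drawable band is reconstructed by fitting the star model
    to the detected border and filling between the fitted contours.  Images
    already in the canonical convention pass through unchanged.
    """
    if profile not in ("paper", "online"):
        raise ValueError(f"unknown profile {profile!r}")
    arr = np.asarray(rgb_image)
    if arr.ndim != 3 or arr.shape[-1] not in (3, 4):
        raise FormatError("harmonize_scan expects an RGB(A) array")
    arr = arr[..., :3].astype(np.uint8)
    if _looks_canonical(arr):
        return HarmonizedImage(
            path_mask=arr[..., 0] > 127,
            band_mask=(arr[..., 1] > 127) & ~(arr[..., 2] > 127),
            border_mask=arr[..., 2] > 127,
            source=profile,
        )

    hsv = rgb2hsv(arr)
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    blue = (hue > 0.5) & (hue < 0.80) & (sat > 0.3) & (val > 0.15)
    saturated_nonblue = (sat > 0.3) & (val > 0.15) & ~((hue > 0.45) & (hue < 0.85))
    dark = (val < 0.35) & (sat < 0.3)
    border = blue
    path = (saturated_nonblue | dark) & ~border
    if not path.any():
        logger.warning("harmonize_scan: no pen trace detected (untraced sheet?)")

    fit = fit_star_parameters(border, n_vertices=n_vertices)
    band = star_mod.band_mask(fit.band, arr.shape[:2]) & ~border
    return HarmonizedImage(path_mask=path, band_mask=band, border_mask=border,
                           source=profile)


def estimate_thickness(path_mask: np.ndarray) -> int:
    """Stroke thickness: drawn area divided by skeleton length, rounded.

    Robust to curvature and needs no stroke model; at least 1.
    """
    if not path_mask.any():
        raise ValueError("cannot estimate thickness of an empty path mask")
    skel = skeletonize(path_mask)
    n_skel = int(skel.sum())
    if n_skel == 0:  # tiny blobs can skeletonize to nothing
        return 1
    return max(1, round(int(path_mask.sum()) / n_skel))


def estimate_center(img: HarmonizedImage, refine: bool = False):
    """Center of the star: border-pixel centroid, optionally fit-refined."""
    coords = np.argwhere(img.border_mask)
    if len(coords) == 0:
        raise ValueError("empty border mask")
    centroid = tuple(coords.mean(axis=0))
    if not refine:
        return centroid
    try:
        fit = fit_star_parameters(img.border_mask)
        return fit.band.center
    except MirrorTraceError:
        logger.warning("center refinement failed; falling back to centroid")
        return centroid
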