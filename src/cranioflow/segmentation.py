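"""Pulsatility-based segmentation (PUBS) of vessel and CSF lumina.

Lumen pixels are identified from the full velocity time-series rather
than from a single image: a seed pixel supplies a reference cardiac
waveform, every pixel is scored by the Pearson correlation of its
velocity-time series with that reference, the correlation map is
thresholded, and the 4-connected component containing the seed is the
lumen. Static background pixels have (near-)zero temporal variance and
are rejected outright; anticorrelated pixels (same waveform shape,
opposite flow direction) are excluded unless ``polarity`` is enabled,
so adjacent arteries and veins do not merge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .core import LumenMask, VelocityCine
from .errors import (BoundsError, DegenerateSeedError, EmptySegmentationError,
                     InvalidSpecError)

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass(frozen=True)
class PubsConfig:
    """Tunable parameters of the segmentation.

    correlation_threshold:
        Minimum Pearson correlation with the reference waveform for a
        pixel to be a lumen candidate (inclusive).
    min_region_px:
        Smallest accepted connected region, in pixels.
    polarity:
        If True, the absolute correlation is thresholded so pixels with
        inverted flow direction are accepted (useful on the low-VENC
        series where bidirectional CSF flow changes sign across the
        lumen over the cycle).
    """

    correlation_threshold: float = 0.85
    min_region_px: int = 2
    polarity: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.correlation_threshold <= 1.0:
            raise InvalidSpecError("correlation_threshold must be in (0, 1]")
        if self.min_region_px < 1:
            raise InvalidSpecError("min_region_px must be >= 1")


def build_reference_waveform(cine: VelocityCine,
                             seed_pixel: Tuple[int, int]) -> np.ndarray:
    """Zero-mean, unit-norm cardiac waveform of the seed pixel.

    Raises DegenerateSeedError if the seed series has no pulsatility
    (zero temporal variance), since correlation against it is undefined.
    """
    series = cine.pixel_series(*seed_pixel).astype(float)
    centered = series - series.mean()
    norm = np.linalg.norm(centered)
    if norm == 0 or not np.isfinite(norm):
        raise DegenerateSeedError(
            f"seed pixel {seed_pixel} has zero temporal variance")
    return centered / norm


def correlation_map(cine: VelocityCine, reference: np.ndarray) -> np.ndarray:
    """Pearson correlation of every pixel's time series with the reference.

    Pixels with zero temporal variance get NaN.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (cine.params.n_phases,):
        raise InvalidSpecError("reference length must equal n_phases")
    v = cine.velocity
    centered = v - v.mean(axis=0, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=0))
    ref = reference - reference.mean()
    ref_norm = np.linalg.norm(ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.tensordot(ref / ref_norm, centered, axes=(0, 0)) / norms
    corr[norms == 0] = np.nan
    return corr


def segment_lumen(cine: VelocityCine, reference: np.ndarray,
                  seed_pixel: Tuple[int, int],
                  config: PubsConfig = PubsConfig()) -> LumenMask:
    """Threshold the correlation map and keep the seed's 4-connected region.

    Pixels at exactly the threshold are included. Raises
    EmptySegmentationError when the seed itself fails the threshold or
    its region is smaller than ``min_region_px``.
    """
    ny, nx = cine.shape
    r, c = seed_pixel
    if not (0 <= r < ny and 0 <= c < nx):
        raise BoundsError(f"seed pixel {seed_pixel} outside {cine.shape} image")
    corr = correlation_map(cine, reference)
    score = np.abs(corr) if config.polarity else corr
    with np.errstate(invalid="ignore"):
        candidates = score >= config.correlation_threshold
    candidates &= np.isfinite(corr)
    if not candidates[r, c]:
        raise EmptySegmentationError(
            f"seed pixel {seed_pixel} below correlation threshold "
            f"{config.correlation_threshold}")
    labels, _ = ndimage.label(candidates, structure=_CROSS)
    region = labels == labels[r, c]
    if int(region.sum()) < config.min_region_px:
        raise EmptySegmentationError(
            f"seed region has {int(region.sum())} px "
            f"< min_region_px={config.min_region_px}")
    return LumenMask(label="", mask=region, source_cine=cine.name)


def segment_from_seed(cine: VelocityCine, seed_pixel: Tuple[int, int],
                      label: str = "",
                      config: PubsConfig = PubsConfig()) -> LumenMask:
    """Convenience wrapper: build the reference at the seed, then segment."""
    reference = build_reference_waveform(cine, seed_pixel)
    mask = segment_lumen(cine, reference, seed_pixel, config)
    mask.label = label
    return mask


def circular_roi(cine: VelocityCine, center: Tuple[float, float],
                 n_pixels: int) -> LumenMask:
    """Circular region of ~``n_pixels`` pixels around ``center``.

    The manual-ROI baseline against which PUBS reproducibility is
    compared: the nearest ``n_pixels`` pixel centres to ``center``.
    """
    ny, nx = cine.shape
    rr, cc = np.mgrid[0:ny, 0:nx]
    dist = np.hypot(rr - center[0], cc - center[1])
    order = np.argsort(dist.ravel(), kind="stable")[:n_pixels]
    mask = np.zeros((ny, nx), dtype=bool)
    mask.ravel()[order] = True
    return LumenMask(label="roi", mask=mask, source_cine=cine.name)


def dice_overlap(a: LumenMask, b: LumenMask) -> float:
    """Dice coefficient between two masks on the same grid."""
    if a.mask.shape != b.mask.shape:
        raise BoundsError("masks are on different grids")
    inter = np.logical_and(a.mask, b.mask).sum()
    return 2.0 * inter / (a.n_pixels + b.n_pixels)
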