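"""DAPI-driven foreground segmentation.

The 3-D quantification is gated on a nuclei-derived foreground mask: the DAPI
channel is smoothed with a deliberately wide in-plane Gaussian (sigma 4 px in
x and y, none across z) so that the mask also captures the perinuclear
cytoplasm where membrane and matrix markers live, then thresholded globally
with Otsu's method.  Intensities at the threshold count as foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stack_io import ImageStack, ValidationError


class DegenerateHistogramError(ValueError):
    """Raised when a threshold is requested for (near-)constant data."""


@dataclass
class ForegroundMask:
    """Binary foreground mask plus the parameters that produced it."""

    mask: np.ndarray  # bool, (Z, Y, X)
    otsu_threshold: float
    sigma_px: tuple[float, float, float]  # (sx, sy, sz)

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold of a 1-D intensity sample.

    Builds an ``n_bins`` histogram spanning the sample's min–max range and
    returns the interior bin edge that maximizes the between-class variance

        sigma_b^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2,

    where class 0 holds values strictly below the edge.  When several edges
    tie (the variance is flat across an empty gap between two classes), the
    middle edge of the maximal plateau is returned, making the result
    deterministic and centered between separated modes.
    """
    values = np.asarray(values).ravel()
    if values.size < 2 or n_bins < 2:
        raise DegenerateHistogramError("need >= 2 values and >= 2 bins")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise DegenerateHistogramError("constant input has no Otsu threshold")
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    # cumulative class-0 weight and mean for every interior edge
    w0 = np.cumsum(counts)[:-1] / total
    w1 = 1.0 - w0
    cum_mass = np.cumsum(counts * centers)[:-1]
    total_mass = float((counts * centers).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = cum_mass / np.cumsum(counts)[:-1]
        mu1 = (total_mass - cum_mass) / (total - np.cumsum(counts)[:-1])
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-np.inf)
    tied = np.flatnonzero(sigma_b == sigma_b.max())
    best = int(tied[len(tied) // 2])  # middle of the maximal plateau
    return float(edges[best + 1])


def segment_dapi(
    stack: ImageStack,
    sigma_px: tuple[float, float, float] = (4.0, 4.0, 0.0),
    n_bins: int = 256,
) -> ForegroundMask:
    """Smooth the DAPI channel and threshold it with Otsu's method.

    ``sigma_px`` is ``(sx, sy, sz)``; the default ``(4, 4, 0)`` smooths each
    z-plane in 2-D only, so no intensity leaks between planes.  A single
    global threshold is computed over the whole smoothed volume with
    ``n_bins`` histogram bins; voxels at or above it are foreground.
    """
    dapi = stack.channel("dapi").astype(np.float64)
    sx, sy, sz = sigma_px
    smoothed = ndimage.gaussian_filter(dapi, sigma=(sz, sy, sx))
    threshold = otsu_threshold(smoothed.ravel(), n_bins=n_bins)
    return ForegroundMask(
        mask=smoothed >= threshold,
        otsu_threshold=threshold,
        sigma_px=(float(sx), float(sy), float(sz)),
    )


def subtract_background(stack: ImageStack, fg: ForegroundMask) -> ImageStack:
    """Subtract each channel's median background intensity, clipping at 0.

    Background is the mask-false voxel set; the median is robust to residual
    foreground contamination.  Every channel, DAPI included, is treated
    identically.  Returns a new float stack; the input is not modified.
    """
    if fg.mask.shape != stack.spatial_shape:
        raise ValidationError("mask shape does not match stack")
    background = ~fg.mask
    if not background.any():
        raise ValidationError("all-foreground mask leaves no background sample")
    out = stack.voxels.astype(np.float64).copy()
    for c in range(out.shape[3]):
        med = float(np.median(out[..., c][background]))
        out[..., c] = np.clip(out[..., c] - med, 0.0, None)
    return stack.with_voxels(out)
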