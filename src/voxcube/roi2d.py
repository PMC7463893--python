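"""2-D monolayer quantification from DAPI/CEA-derived regions of interest.

Monolayer images are split into a cancer and a fibroblast compartment using
only the stated intensity criteria: the DAPI threshold defines where cells
are, the CEA threshold (within the cell area) defines the cancer islets, and
the fibroblast compartment is the remaining cell area minus a small dilation
guard band around the islets to keep edge bleed out.  Morphological criteria
the human analyst also used (islet vs spindle shape) are deliberately not
formalized — this is a documented simplification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .segmentation import DegenerateHistogramError, otsu_threshold
from .stack_io import ImageStack, ValidationError


@dataclass
class RoiSet2D:
    """Compartment masks for one monolayer image."""

    cell_mask: np.ndarray  # bool (Y, X): DAPI-positive cell area
    cancer_mask: np.ndarray  # bool (Y, X): CEA-positive islets within cells
    fibroblast_mask: np.ndarray  # bool (Y, X): cell area minus dilated islets
    dilation_px: int

    def __post_init__(self) -> None:
        if (self.cancer_mask & self.fibroblast_mask).any():
            raise ValidationError("compartments overlap")


def _single_plane(image: ImageStack) -> None:
    if image.spatial_shape[0] != 1:
        raise ValidationError("2-D ROI analysis expects a single z-plane")


def build_rois_2d(
    image: ImageStack,
    dilation_px: int = 2,
    dapi_sigma_px: float = 2.0,
    n_bins: int = 256,
) -> RoiSet2D:
    """Derive cell / cancer / fibroblast masks from DAPI and CEA thresholds.

    ``cell_mask`` is Otsu on the smoothed DAPI plane; ``cancer_mask`` is Otsu
    on the CEA values inside the cell mask (empty when CEA is flat there);
    ``fibroblast_mask`` is the cell mask minus the cancer mask dilated by
    ``dilation_px`` (a guard band against islet-edge bleed; 0 disables it).
    Smoothing and dilation defaults are declared free parameters and are
    echoed in the result.
    """
    _single_plane(image)
    dapi = image.channel("dapi")[0].astype(np.float64)
    cea = image.channel("cea")[0].astype(np.float64)
    smoothed = ndimage.gaussian_filter(dapi, sigma=dapi_sigma_px)
    cell_mask = smoothed >= otsu_threshold(smoothed.ravel(), n_bins=n_bins)
    cea_in_cells = cea[cell_mask]
    if cea_in_cells.size == 0:
        raise DegenerateHistogramError("empty cell mask")
    if cea_in_cells.min() == cea_in_cells.max():
        # flat CEA (e.g. marker absent): no cancer compartment
        cancer_mask = np.zeros_like(cell_mask)
    else:
        t_cea = otsu_threshold(cea_in_cells, n_bins=n_bins)
        cancer_mask = cell_mask & (cea >= t_cea)
    if dilation_px > 0:
        guard = ndimage.binary_dilation(cancer_mask, structure=disk(dilation_px))
    else:
        guard = cancer_mask
    fibroblast_mask = cell_mask & ~guard
    return RoiSet2D(
        cell_mask=cell_mask,
        cancer_mask=cancer_mask,
        fibroblast_mask=fibroblast_mask,
        dilation_px=int(dilation_px),
    )


def quantify_rois(
    image: ImageStack, rois: RoiSet2D, role: str
) -> dict[str, float | None]:
    """Background-subtracted mean marker intensity per compartment.

    Background is the median intensity outside the cell mask.  An empty
    compartment is reported as ``None`` (a labeled missing value), never as a
    silent zero.
    """
    _single_plane(image)
    channel = image.channel(role)[0].astype(np.float64)
    outside = ~rois.cell_mask
    if not outside.any():
        raise ValidationError("no background pixels outside the cell mask")
    background = float(np.median(channel[outside]))
    sub = np.clip(channel - background, 0.0, None)
    out: dict[str, float | None] = {}
    for name, mask in (
        ("cancer", rois.cancer_mask),
        ("fibroblast", rois.fibroblast_mask),
    ):
        out[name] = float(sub[mask].mean()) if mask.any() else None
    return out


def summarize_replicates(
    per_image: list[dict[str, float | None]]
) -> dict[str, dict[str, float | None]]:
    """Mean and SEM across replicate images, per compartment.

    SEM is across replicates (n experiments), not across pixels; with a
    single replicate it is reported as ``None``.  Images where a compartment
    is missing are excluded from that compartment's summary.
    """
    out: dict[str, dict[str, float | None]] = {}
    for name in ("cancer", "fibroblast"):
        values = [d[name] for d in per_image if d.get(name) is not None]
        if not values:
            out[name] = {"mean": None, "sem": None, "n": 0}
            continue
        arr = np.asarray(values, dtype=np.float64)
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None
        out[name] = {"mean": float(arr.mean()), "sem": sem, "n": int(arr.size)}
    return out
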