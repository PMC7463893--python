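"""Cell-type-agnostic fluorescence intensity per µm³.

A deliberately coarser companion to the cube analysis: one number per stack
and channel, the summed foreground intensity divided by the physical volume
of the foreground.  No cube partition and no inclusion rule, so it carries no
skew toward either population — useful when the cube split is suspected of
under-sampling one cell type.  The denominator is the segmented foreground
volume, not the whole imaged volume, so empty cavity space does not dilute
the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import ForegroundMask
from .stack_io import ImageStack, ValidationError


@dataclass
class VolumetricResult:
    role: str
    total_intensity: float
    foreground_volume_um3: float
    intensity_per_um3: float
    stack_id: str = "stack"
    condition: str = "co_culture"


def intensity_per_volume(
    stack: ImageStack,
    fg: ForegroundMask,
    role: str,
    stack_id: str = "stack",
    condition: str = "co_culture",
) -> VolumetricResult:
    """Sum a (background-subtracted) channel over the foreground and divide
    by the foreground's physical volume in µm³."""
    if fg.mask.shape != stack.spatial_shape:
        raise ValidationError("mask shape does not match stack")
    n_fg = fg.n_foreground
    if n_fg == 0:
        raise ValidationError("empty foreground mask: intensity per um^3 undefined")
    dz, dy, dx = stack.voxel_size_um
    total = float(stack.channel(role)[fg.mask].sum())
    volume = n_fg * dz * dy * dx
    return VolumetricResult(
        role=role,
        total_intensity=total,
        foreground_volume_um3=volume,
        intensity_per_um3=total / volume,
        stack_id=stack_id,
        condition=condition,
    )


def pool_volumetric(results: list[VolumetricResult]) -> float:
    """Pooled intensity per µm³ of disjoint foregrounds:
    (sum of totals) / (sum of volumes)."""
    if not results:
        raise ValidationError("nothing to pool")
    total = sum(r.total_intensity for r in results)
    volume = sum(r.foreground_volume_um3 for r in results)
    return total / volume
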