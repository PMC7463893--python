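"""Non-overlapping voxel-cube partition and per-cube foreground quantification.

A stack is tiled from the origin into fixed cubes — 32 x 32 x 16 voxels in
x, y, z by default — trailing margins that do not fit a whole cube are
dropped, so every cube has the same denominator.  A cube enters the analysis
only if *more than* half of its voxels are foreground; for the cubes kept,
each channel's mean is taken over the foreground voxels alone.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .segmentation import ForegroundMask
from .stack_io import CubeRecord, CubeTable, ImageStack, ValidationError

logger = logging.getLogger(__name__)

#: Default cube extents, ordered (x, y, z) voxels.
DEFAULT_CUBE_SHAPE = (32, 32, 16)


def partition_grid(
    spatial_shape: tuple[int, int, int],
    cube_shape: tuple[int, int, int] = DEFAULT_CUBE_SHAPE,
) -> list[tuple[tuple[int, int, int], tuple[int, int, int]]]:
    """Tile a ``(Z, Y, X)`` volume into half-open cube blocks.

    ``cube_shape`` is ``(cx, cy, cz)`` in voxels.  Returns
    ``[(grid_index, origin_voxel), ...]`` with ``grid_index = (ix, iy, iz)``
    and ``origin_voxel = (z0, y0, x0)``, ordered by (iz, iy, ix).  The cube
    count is ``floor(X/cx) * floor(Y/cy) * floor(Z/cz)``.
    """
    cx, cy, cz = cube_shape
    if min(cx, cy, cz) < 1:
        raise ValidationError("cube dimensions must be >= 1")
    nz_, ny_, nx_ = spatial_shape
    nx, ny, nz = nx_ // cx, ny_ // cy, nz_ // cz
    if nx == 0 or ny == 0 or nz == 0:
        logger.warning(
            "volume %s smaller than cube %s in some dimension; empty partition",
            spatial_shape, cube_shape,
        )
        return []
    out = []
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                out.append(((ix, iy, iz), (iz * cz, iy * cy, ix * cx)))
    return out


def quantify_cubes(
    stack: ImageStack,
    fg: ForegroundMask,
    cube_shape: tuple[int, int, int] = DEFAULT_CUBE_SHAPE,
    min_fg_fraction: float = 0.5,
    stack_id: str = "stack",
    condition: str = "co_culture",
) -> CubeTable:
    """Apply the foreground-fraction inclusion rule and average each cube.

    A cube is retained only when its foreground fraction is strictly greater
    than ``min_fg_fraction`` ("more than 50%"); a cube at exactly the
    threshold is excluded.  Channel means are over foreground voxels only —
    background voxels inside a retained cube never contribute.  The caller is
    expected to pass a background-subtracted stack.
    """
    if fg.mask.shape != stack.spatial_shape:
        raise ValidationError("mask shape does not match stack")
    cx, cy, cz = cube_shape
    n_cube_voxels = cx * cy * cz
    records = []
    for grid_index, (z0, y0, x0) in partition_grid(stack.spatial_shape, cube_shape):
        sl = (slice(z0, z0 + cz), slice(y0, y0 + cy), slice(x0, x0 + cx))
        cube_mask = fg.mask[sl]
        n_fg = int(cube_mask.sum())
        fg_fraction = n_fg / n_cube_voxels
        if not fg_fraction > min_fg_fraction:
            continue
        means = {}
        for role in stack.channels:
            means[role] = float(stack.channel(role)[sl][cube_mask].mean())
        records.append(
            CubeRecord(
                grid_index=grid_index,
                origin_voxel=(z0, y0, x0),
                fg_fraction=fg_fraction,
                n_fg_voxels=n_fg,
                mean_fg_intensity=means,
            )
        )
    return CubeTable(
        records=records, stack_id=stack_id, condition=condition, n_cavities_pooled=1
    )


def pool_cavities(tables: Sequence[CubeTable]) -> CubeTable:
    """Concatenate per-cavity cube tables into one composite table.

    All inputs must share their condition and channel roles; per-record stack
    identity is preserved so pooled records remain traceable.
    """
    if not tables:
        raise ValidationError("nothing to pool")
    condition = tables[0].condition
    roles = tables[0].channel_roles
    for t in tables[1:]:
        if t.condition != condition:
            raise ValidationError(
                f"mixed conditions: {condition!r} vs {t.condition!r}"
            )
        if t.records and roles and t.channel_roles != roles:
            raise ValidationError(
                f"mixed channel roles: {roles} vs {t.channel_roles}"
            )
        if t.records and not roles:
            roles = t.channel_roles
    records: list[CubeRecord] = []
    stack_ids: list[str] = []
    for t in tables:
        records.extend(t.records)
        stack_ids.extend(t.stack_ids or [t.stack_id] * len(t.records))
    return CubeTable(
        records=records,
        stack_id=tables[0].stack_id,
        condition=condition,
        n_cavities_pooled=len(tables),
        stack_ids=stack_ids,
    )
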