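"""Image-stack and cube-table I/O.

All volumes are held in a single internal axis convention — ``(Z, Y, X, C)``,
0-based, half-open intervals — and every reader is responsible for transposing
its input dialect to it.  Channel identity is carried by *role* labels
(``dapi``, ``cea``, ``coll4``, ...) rather than positional indices, so that a
quantification request for e.g. the CEA channel always addresses the plane it
was read from.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Channel roles understood by the pipeline.
CHANNEL_ROLES = frozenset(
    {"dapi", "cea", "coll4", "marker", "tracker_green", "tracker_deepred", "tmrm"}
)

#: Culture conditions a cube table may be labeled with.
CONDITIONS = ("mono_cancer", "mono_fibroblast", "co_culture")


class StackFormatError(ValueError):
    """Raised when a TIFF's axes cannot be resolved to Z, Y, X, C."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


@dataclass
class ImageStack:
    """A multichannel 3-D fluorescence volume.

    Parameters
    ----------
    voxels
        4-D array of nonnegative intensities, ordered ``(Z, Y, X, C)``.
    voxel_size_um
        Physical voxel extents ``(dz, dy, dx)`` in micrometres.
    channels
        One role label per channel, drawn from :data:`CHANNEL_ROLES`.
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.channels = tuple(self.channels)
        if self.voxels.ndim != 4:
            raise ValidationError(
                f"voxels must be 4-D (Z, Y, X, C), got ndim={self.voxels.ndim}"
            )
        if len(self.channels) != self.voxels.shape[3]:
            raise ValidationError(
                f"{len(self.channels)} channel roles for "
                f"{self.voxels.shape[3]} channels"
            )
        unknown = set(self.channels) - CHANNEL_ROLES
        if unknown:
            raise ValidationError(f"unknown channel roles: {sorted(unknown)}")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel roles must be unique")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValidationError("voxel_size_um must be three positive lengths")
        if np.issubdtype(self.voxels.dtype, np.floating) and np.any(self.voxels < 0):
            raise ValidationError("intensities must be nonnegative")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    def channel(self, role: str) -> np.ndarray:
        """Return the 3-D ``(Z, Y, X)`` volume for a channel role."""
        if role not in self.channels:
            raise ValidationError(f"stack has no channel with role {role!r}")
        return self.voxels[..., self.channels.index(role)]

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        """Copy of this stack with new voxel data, metadata unchanged."""
        return replace(self, voxels=voxels)


@dataclass
class CubeRecord:
    """Quantification result for one non-overlapping voxel cube."""

    grid_index: tuple[int, int, int]  # (ix, iy, iz)
    origin_voxel: tuple[int, int, int]  # (z0, y0, x0)
    fg_fraction: float
    n_fg_voxels: int
    mean_fg_intensity: dict[str, float]
    compartment: str | None = None  # set by discrimination.classify_cubes


@dataclass
class CubeTable:
    """Cube records pooled over one or more cavities of a single condition."""

    records: list[CubeRecord]
    stack_id: str = "stack"
    condition: str = "co_culture"
    n_cavities_pooled: int = 1
    stack_ids: list[str] | None = None  # per-record origin when pooled

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        idx = [r.grid_index for r in self.records]
        if self.stack_ids is None:
            self.stack_ids = [self.stack_id] * len(self.records)
        if len(self.stack_ids) != len(self.records):
            raise ValidationError("stack_ids length must match records")
        seen = set()
        for sid, gi in zip(self.stack_ids, idx):
            key = (sid, gi)
            if key in seen:
                raise ValidationError(f"duplicate grid index {gi} in stack {sid}")
            seen.add(key)

    @property
    def channel_roles(self) -> tuple[str, ...]:
        if not self.records:
            return ()
        return tuple(self.records[0].mean_fg_intensity.keys())

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        roles = self.channel_roles
        rows = []
        for sid, r in zip(self.stack_ids, self.records):
            row = {
                "stack_id": sid,
                "condition": self.condition,
                "ix": r.grid_index[0],
                "iy": r.grid_index[1],
                "iz": r.grid_index[2],
                "z0": r.origin_voxel[0],
                "y0": r.origin_voxel[1],
                "x0": r.origin_voxel[2],
                "fg_fraction": r.fg_fraction,
                "n_fg_voxels": r.n_fg_voxels,
            }
            for role in roles:
                row[f"mean_{role}"] = r.mean_fg_intensity[role]
            if r.compartment is not None:
                row["compartment"] = r.compartment
            rows.append(row)
        columns = [
            "stack_id", "condition", "ix", "iy", "iz", "z0", "y0", "x0",
            "fg_fraction", "n_fg_voxels",
        ] + [f"mean_{role}" for role in roles]
        if any(r.compartment is not None for r in self.records):
            columns.append("compartment")
        return pd.DataFrame(rows, columns=columns)


def _parse_ome_voxel_size(description: str) -> dict[str, float]:
    """Pull PhysicalSize{X,Y,Z} out of an OME-XML image description.

    Regex-based so it also accepts hand-written or minimal OME headers that a
    strict parser would reject.
    """
    sizes: dict[str, float] = {}
    for axis in "XYZ":
        m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', description)
        if m:
            sizes[axis.lower()] = float(m.group(1))
    return sizes


def _resolve_axes(data: np.ndarray, axes: str, n_channels: int) -> np.ndarray:
    """Transpose a tifffile series to (Z, Y, X, C)."""
    axes = axes.upper().replace("S", "C").replace("I", "Q")
    if (
        len(axes) == data.ndim
        and set(axes) <= set("ZYXC")
        and len(set(axes)) == len(axes)
    ):
        # every axis identified: transpose to Z, Y, X, C and pad missing axes
        order = [axes.index(a) for a in "ZYXC" if a in axes]
        data = np.transpose(data, order)
        if "Z" not in axes:
            data = data[np.newaxis]
        if "C" not in axes:
            data = data[..., np.newaxis]
        return data
    if axes.startswith("Q") and data.ndim == 3:
        # plain multi-page TIFF: pages are Z*C, channel fastest (ImageJ order)
        n_pages = data.shape[0]
        if n_pages % n_channels:
            raise ValidationError(
                f"{n_pages} pages not divisible by {n_channels} channels"
            )
        z = n_pages // n_channels
        data = data.reshape(z, n_channels, *data.shape[1:])
        return np.moveaxis(data, 1, -1)
    if data.ndim == 2:
        return data[np.newaxis, :, :, np.newaxis]
    raise StackFormatError(f"cannot resolve axes {axes!r} with shape {data.shape}")


def read_stack(
    path: str | Path,
    channel_roles: Sequence[str],
    voxel_size_um: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF into an :class:`ImageStack`.

    Voxel size is taken from OME metadata when present; otherwise from the
    ``voxel_size_um`` argument; otherwise defaults to 1 µm isotropic with a
    logged warning.  Integer intensities are preserved losslessly.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        description = tf.pages[0].description or ""
    data = _resolve_axes(data, axes, len(channel_roles))
    if data.shape[3] != len(channel_roles):
        raise ValidationError(
            f"{len(channel_roles)} roles given for {data.shape[3]} channels"
        )
    ome_sizes = _parse_ome_voxel_size(description)
    if ome_sizes:
        base = voxel_size_um or (1.0, 1.0, 1.0)
        vs = (
            ome_sizes.get("z", base[0]),
            ome_sizes.get("y", base[1]),
            ome_sizes.get("x", base[2]),
        )
    elif voxel_size_um is not None:
        vs = tuple(voxel_size_um)
    else:
        logger.warning(
            "%s: no voxel-size metadata; defaulting to 1 um isotropic", path.name
        )
        vs = (1.0, 1.0, 1.0)
    return ImageStack(voxels=data, voxel_size_um=vs, channels=tuple(channel_roles))


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF (axes ZCYX, voxel size in the OME header)."""
    path = Path(path)
    data = np.moveaxis(stack.voxels, -1, 1)  # ZYXC -> ZCYX
    dz, dy, dx = stack.voxel_size_um
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
        },
    )
    return path


def write_cube_table(table: CubeTable, path: str | Path) -> Path:
    """Serialize a cube table to plain CSV (full float precision)."""
    path = Path(path)
    df = table.to_dataframe()
    df.to_csv(path, index=False)
    return path


def read_cube_table(path: str | Path) -> CubeTable:
    """Read a CSV written by :func:`write_cube_table` back to a CubeTable."""
    df = pd.read_csv(Path(path))
    roles = [c[len("mean_"):] for c in df.columns if c.startswith("mean_")]
    records = []
    stack_ids = []
    for _, row in df.iterrows():
        records.append(
            CubeRecord(
                grid_index=(int(row["ix"]), int(row["iy"]), int(row["iz"])),
                origin_voxel=(int(row["z0"]), int(row["y0"]), int(row["x0"])),
                fg_fraction=float(row["fg_fraction"]),
                n_fg_voxels=int(row["n_fg_voxels"]),
                mean_fg_intensity={r: float(row[f"mean_{r}"]) for r in roles},
                compartment=(
                    str(row["compartment"]) if "compartment" in df.columns else None
                ),
            )
        )
        stack_ids.append(str(row["stack_id"]))
    condition = str(df["condition"].iloc[0]) if len(df) else "co_culture"
    n_stacks = len(set(stack_ids)) if stack_ids else 1
    return CubeTable(
        records=records,
        stack_id=stack_ids[0] if stack_ids else "stack",
        condition=condition,
        n_cavities_pooled=n_stacks,
        stack_ids=stack_ids,
    )
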