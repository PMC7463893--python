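"""Mono-culture CEA reference threshold and cube-level population split.

The fibroblast mono-culture defines a CEA brightness range containing 95% of
its voxel cubes; the upper end of that range (a nearest-rank order statistic,
so always an observed cube value) is drawn as the red reference line.  Cubes
of any other table whose CEA mean exceeds the cutoff are called putative
cancer cubes; cubes at or below it — including ties — fall on the fibroblast
side, honouring the "contains 95%" coverage reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .stack_io import CubeRecord, CubeTable, ValidationError

PUTATIVE_CANCER = "putative_cancer"
PUTATIVE_FIBROBLAST = "putative_fibroblast"


@dataclass
class ReferenceThreshold:
    """CEA cutoff bounding a quantile of mono-culture fibroblast cubes."""

    cea_cutoff: float
    coverage: float  # realized fraction of source cubes <= cutoff
    source_condition: str
    n_cubes: int
    quantile_method: str = "nearest_rank_above"
    q: float = 0.95


def compute_reference_threshold(
    mono_fibroblast_table: CubeTable, q: float = 0.95
) -> ReferenceThreshold:
    """Derive the CEA reference cutoff from a fibroblast mono-culture table.

    Uses the inclusive nearest-rank convention: the cutoff is the
    ``ceil(q * n)``-th order statistic of the cube CEA means, so at least
    ``ceil(q * n)`` cubes lie at or below it and the realized coverage is
    always >= q.
    """
    if mono_fibroblast_table.condition != "mono_fibroblast":
        raise ValidationError(
            "reference threshold must come from a mono_fibroblast table, got "
            f"{mono_fibroblast_table.condition!r}"
        )
    values = np.array(
        [r.mean_fg_intensity["cea"] for r in mono_fibroblast_table.records]
    )
    n = values.size
    if n == 0:
        raise ValidationError("empty mono-culture table")
    if n < 20:
        import logging

        logging.getLogger(__name__).warning(
            "only %d mono-culture cubes; the %.0f%% quantile is unstable", n, q * 100
        )
    if not 0 < q <= 1:
        raise ValidationError("q must be in (0, 1]")
    rank = max(1, math.ceil(q * n))  # 1-based order statistic
    cutoff = float(np.sort(values)[rank - 1])
    coverage = float((values <= cutoff).mean())
    return ReferenceThreshold(
        cea_cutoff=cutoff,
        coverage=coverage,
        source_condition=mono_fibroblast_table.condition,
        n_cubes=n,
        q=q,
    )


def classify_cubes(table: CubeTable, ref: ReferenceThreshold) -> CubeTable:
    """Annotate each cube as putative cancer or fibroblast by its CEA mean.

    Strictly above the cutoff -> cancer side; at or below -> fibroblast side.
    Returns a new table; original records are untouched.
    """
    if table.records and "cea" not in table.channel_roles:
        raise ValidationError("table has no cea channel")
    records = [
        replace(
            r,
            compartment=(
                PUTATIVE_CANCER
                if r.mean_fg_intensity["cea"] > ref.cea_cutoff
                else PUTATIVE_FIBROBLAST
            ),
        )
        for r in table.records
    ]
    return CubeTable(
        records=records,
        stack_id=table.stack_id,
        condition=table.condition,
        n_cavities_pooled=table.n_cavities_pooled,
        stack_ids=list(table.stack_ids or []) or None,
    )


def compartment_sizes(table: CubeTable) -> dict[str, int]:
    """Cube counts per compartment label (reported alongside any split so a
    skew toward the cancer side is always visible)."""
    out: dict[str, int] = {}
    for r in table.records:
        if r.compartment is not None:
            out[r.compartment] = out.get(r.compartment, 0) + 1
    return out


def export_scatter(
    table: CubeTable,
    x_role: str = "cea",
    y_role: str = "coll4",
    color_role: str = "dapi",
    ref: ReferenceThreshold | None = None,
    plot_path: str | None = None,
) -> pd.DataFrame:
    """Cube-level scatter export (one row per cube) with optional plot.

    The plot overlays the red reference line at the CEA cutoff when a
    reference threshold is given, mirroring the mono-/co-culture scatter
    figures.
    """
    for role in (x_role, y_role, color_role):
        if table.records and role not in table.channel_roles:
            raise ValidationError(f"unknown channel role {role!r}")
    rows = [
        {
            "stack_id": sid,
            "x": r.mean_fg_intensity[x_role],
            "y": r.mean_fg_intensity[y_role],
            "color": r.mean_fg_intensity[color_role],
            "compartment": r.compartment,
        }
        for sid, r in zip(table.stack_ids or [], table.records)
    ]
    df = pd.DataFrame(rows, columns=["stack_id", "x", "y", "color", "compartment"])
    if plot_path is not None and len(df):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        sc = ax.scatter(df["x"], df["y"], c=df["color"], s=12, cmap="viridis")
        fig.colorbar(sc, ax=ax, label=f"mean {color_role}")
        if ref is not None:
            ax.axvline(ref.cea_cutoff, color="red", lw=1.5)
        ax.set_xlabel(f"mean {x_role}")
        ax.set_ylabel(f"mean {y_role}")
        ax.set_title(f"{table.condition} (n={len(df)} cubes)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df
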