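"""End-to-end orchestration: generate → segment → subtract → quantify →
discriminate → summarize, with config, manifest and reproducibility plumbing.

A run is driven by one :class:`RunConfig` (YAML-serializable); every numeric
setting defaults to the analysis protocol's value (smoothing sigma (4, 4, 0),
32 x 32 x 16 cubes, >50% foreground inclusion, 95% reference quantile, 3 px
randomization blocks, 10 randomizations).  All randomness flows from the
single master seed through documented per-cavity derivation, and the manifest
records parameters plus a SHA-256 of every output file, so reruns with the
same config are bit-identical and every file is traceable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_stacks as synth
from .cube_quant import pool_cavities, quantify_cubes
from .discrimination import (
    ReferenceThreshold,
    classify_cubes,
    compartment_sizes,
    compute_reference_threshold,
    export_scatter,
)
from .segmentation import segment_dapi, subtract_background
from .stack_io import CubeTable, write_cube_table
from .volumetric_intensity import intensity_per_volume

logger = logging.getLogger(__name__)

CONDITIONS = ("mono_cancer", "mono_fibroblast", "co_culture")


class StageError(RuntimeError):
    """Pipeline failure, annotated with the stage and stack it occurred in."""

    def __init__(self, stage: str, stack_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {stack_id!r}: {cause}")
        self.stage = stage
        self.stack_id = stack_id
        self.__cause__ = cause


@dataclass
class RunConfig:
    """All knobs of a full synthetic run, with protocol defaults."""

    seed: int = 0
    out_dir: str = "voxcube_run"
    conditions: tuple[str, ...] = CONDITIONS
    n_cavities: int = 5
    stack_shape: tuple[int, int, int] = synth.DEFAULT_CAVITY_SHAPE
    mixing: str = "interspersed"
    sigma_px: tuple[float, float, float] = (4.0, 4.0, 0.0)
    n_bins: int = 256
    cube_shape: tuple[int, int, int] = (32, 32, 16)
    min_fg_fraction: float = 0.5
    reference_q: float = 0.95
    psf_block_px: int = 3
    n_randomizations: int = 10
    volumetric_role: str = "coll4"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("conditions", "stack_shape", "sigma_px", "cube_shape"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic pipeline and write all artifacts.

    Per condition and cavity: generate, segment on DAPI, subtract
    background, cube-quantify; cavities are pooled per condition.  The
    mono-fibroblast pool defines the CEA reference threshold used to
    classify every condition's cubes.  Volumetric per-µm³ intensities are
    computed per cavity.  Returns the manifest dict (also written to
    ``manifest.yaml``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, CubeTable] = {}
    volumetric_rows: list[dict] = []

    for condition in config.conditions:
        cavity_tables = []
        stacks = synth.generate_condition_set(
            condition,
            n_cavities=config.n_cavities,
            seed=config.seed,
            shape=tuple(config.stack_shape),
            mixing=config.mixing,
        )
        for i, (stack, _truth) in enumerate(stacks):
            stack_id = f"{condition}_cavity{i}"
            try:
                fg = segment_dapi(
                    stack, sigma_px=tuple(config.sigma_px), n_bins=config.n_bins
                )
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise StageError("segmentation", stack_id, exc) from exc
            try:
                sub = subtract_background(stack, fg)
            except Exception as exc:  # noqa: BLE001
                raise StageError("background_subtraction", stack_id, exc) from exc
            try:
                cavity_tables.append(
                    quantify_cubes(
                        sub,
                        fg,
                        cube_shape=tuple(config.cube_shape),
                        min_fg_fraction=config.min_fg_fraction,
                        stack_id=stack_id,
                        condition=condition,
                    )
                )
            except Exception as exc:  # noqa: BLE001
                raise StageError("cube_quantification", stack_id, exc) from exc
            if config.volumetric_role in stack.channels:
                vr = intensity_per_volume(
                    sub, fg, config.volumetric_role,
                    stack_id=stack_id, condition=condition,
                )
                volumetric_rows.append(
                    {
                        "stack_id": vr.stack_id,
                        "condition": vr.condition,
                        "role": vr.role,
                        "total_intensity": vr.total_intensity,
                        "foreground_volume_um3": vr.foreground_volume_um3,
                        "intensity_per_um3": vr.intensity_per_um3,
                    }
                )
        pooled = pool_cavities(cavity_tables)
        tables[condition] = pooled
        write_cube_table(pooled, out_dir / f"cubes_{condition}.csv")

    ref = None
    if "mono_fibroblast" in tables and len(tables["mono_fibroblast"]):
        ref = compute_reference_threshold(
            tables["mono_fibroblast"], q=config.reference_q
        )
        with open(out_dir / "reference_threshold.yaml", "w") as fh:
            yaml.safe_dump(asdict(ref), fh, sort_keys=True)
        for condition, table in tables.items():
            classified = classify_cubes(table, ref)
            tables[condition] = classified
            write_cube_table(
                classified, out_dir / f"cubes_{condition}_classified.csv"
            )
            export_scatter(
                classified,
                ref=ref,
                plot_path=str(out_dir / f"scatter_{condition}.png"),
            ).to_csv(out_dir / f"scatter_{condition}.csv", index=False)

    if volumetric_rows:
        pd.DataFrame(volumetric_rows).to_csv(
            out_dir / "volumetric.csv", index=False
        )

    summary = summarize(tables, volumetric_rows)
    summary.to_csv(out_dir / "summary.csv", index=False)

    manifest = {
        "config": asdict(config),
        "reference_threshold": asdict(ref) if ref else None,
        "compartment_sizes": {c: compartment_sizes(t) for c, t in tables.items()},
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out_dir.iterdir())
            if p.suffix in {".csv", ".yaml"} and p.name != "manifest.yaml"
        },
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def summarize(
    tables: dict[str, CubeTable], volumetric_rows: list[dict] | None = None
) -> pd.DataFrame:
    """Condition-level summary: cube counts, compartment sizes, per-channel
    median cube intensity, and volumetric mean ± SEM across cavities.

    SEM across a single cavity is reported as missing (NaN), never 0; the
    summary is invariant to cavity order.
    """
    if not tables:
        raise ValueError("need at least one condition")
    rows = []
    vol = pd.DataFrame(volumetric_rows or [])
    for condition in sorted(tables):
        table = tables[condition]
        row: dict = {
            "condition": condition,
            "n_cubes": len(table),
            "n_cavities": table.n_cavities_pooled,
        }
        row.update(
            {f"n_{k}": v for k, v in sorted(compartment_sizes(table).items())}
        )
        for role in table.channel_roles:
            vals = [r.mean_fg_intensity[role] for r in table.records]
            row[f"median_{role}"] = float(np.median(vals)) if vals else np.nan
        if len(vol) and condition in set(vol["condition"]):
            v = vol.loc[vol["condition"] == condition, "intensity_per_um3"]
            v = v.sort_values().to_numpy()  # order-free
            row["volumetric_mean"] = float(v.mean())
            row["volumetric_sem"] = (
                float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
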