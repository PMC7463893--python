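"""Standard validation experiments on synthetic condition sets.

These functions bundle the recurring end-to-end experiments — reference
coverage, ground-truth classification accuracy, condition orderings,
determinism — so that the test suite and reproduction scripts run the exact
same computations.  Stack geometries are desk-scale stand-ins for the
1024 x 1024 px acquisitions; classification panels use wider crops so that
the population-zone boundary does not dominate the cube grid the way it
would never do at full acquisition size.
"""

from __future__ import annotations

import numpy as np

from . import synthetic_stacks as synth
from .colocalization import pearson_above_threshold
from .cube_quant import pool_cavities, quantify_cubes
from .discrimination import ReferenceThreshold, compute_reference_threshold
from .segmentation import segment_dapi, subtract_background
from .stack_io import CubeTable, ImageStack
from .volumetric_intensity import intensity_per_volume, pool_volumetric

#: Cancer CEA staining mean held fixed while contrast varies.
_CANCER_CEA = 200.0

#: Stack geometry of the mono-culture reference panels (Z, Y, X).
REFERENCE_SHAPE = (32, 256, 256)

#: Stack geometry of co-culture classification panels; the wider crop keeps
#: the fibroblast-zone boundary from dominating the cube grid.
PANEL_SHAPE = (32, 512, 512)

#: Fibroblast-zone radius used in classification panels: one contiguous zone
#: per crop, as in high-resolution images of chip co-cultures.
PANEL_CLUSTER_RADIUS_PX = 160.0


def derive_seeds(master_seed: int, n: int, stream: int = 0) -> list[int]:
    """n deterministic sub-seeds (< 2**31) for experiment ``stream``."""
    ss = np.random.SeedSequence([int(master_seed), int(stream)])
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def cube_table_for(
    stack: ImageStack, condition: str, stack_id: str = "stack"
) -> CubeTable:
    """The canonical per-stack chain: segment, subtract, cube-quantify."""
    fg = segment_dapi(stack)
    sub = subtract_background(stack, fg)
    return quantify_cubes(sub, fg, stack_id=stack_id, condition=condition)


def _fibroblast_cea(contrast: float) -> dict:
    """Fibroblast override putting the CEA contrast at ``contrast``-fold."""
    mean = _CANCER_CEA / contrast
    return {"channel_levels": {"cea": (mean, 0.2 * mean), "coll4": (80.0, 12.0)}}


def mono_fibroblast_reference(
    seed: int,
    n_cavities: int = 5,
    shape: tuple[int, int, int] = REFERENCE_SHAPE,
    q: float = 0.95,
    contrast: float = 4.0,
) -> tuple[ReferenceThreshold, CubeTable]:
    """Pooled mono-fibroblast cube table and its CEA reference threshold."""
    tables = []
    for i, (stack, _) in enumerate(
        synth.generate_condition_set(
            "mono_fibroblast", n_cavities=n_cavities, seed=seed, shape=shape,
            fibroblast_overrides=_fibroblast_cea(contrast),
        )
    ):
        tables.append(cube_table_for(stack, "mono_fibroblast", f"fibro_cav{i}"))
    pooled = pool_cavities(tables)
    return compute_reference_threshold(pooled, q=q), pooled


def classification_accuracy(
    seeds: list[int],
    ref: ReferenceThreshold,
    contrast: float = 4.0,
    shape: tuple[int, int, int] = PANEL_SHAPE,
    cluster_radius_px: float = PANEL_CLUSTER_RADIUS_PX,
) -> dict:
    """Cube-level classification accuracy vs ground-truth majority labels.

    For each seed, one co-culture stack is generated at the given CEA
    contrast, cube-quantified, and every included cube with labeled truth
    voxels is classified against ``ref``; accuracy is pooled over the panel.
    """
    n_correct = n_total = 0
    per_seed = []
    for seed in seeds:
        stack, truth = synth.generate_stack(
            shape,
            synth.condition_populations(
                "co_culture", shape, fibroblast_overrides=_fibroblast_cea(contrast)
            ),
            seed=seed,
            cluster_radius_px=cluster_radius_px,
        )
        table = cube_table_for(stack, "co_culture")
        majority = synth.majority_label_per_cube(truth)
        correct = total = 0
        for record in table.records:
            label = majority.get(record.grid_index)
            if label is None:
                continue
            predicted = (
                "cancer"
                if record.mean_fg_intensity["cea"] > ref.cea_cutoff
                else "fibroblast"
            )
            total += 1
            correct += predicted == label
        per_seed.append(correct / total if total else float("nan"))
        n_correct += correct
        n_total += total
    return {
        "accuracy": n_correct / n_total if n_total else float("nan"),
        "n_cubes": n_total,
        "per_seed": per_seed,
    }


def volumetric_ordering(
    seed: int,
    n_cavities: int = 5,
    shape: tuple[int, int, int] = synth.DEFAULT_CAVITY_SHAPE,
) -> dict:
    """Autophagy-marker intensity per µm³: co-culture vs fibroblast mono.

    The parameterization encodes the reported biology — the autophagy-marker
    (LC3/P62-like) staining of fibroblasts roughly doubles in co-culture and
    cancer cells contribute at an intermediate level — so a sensitive
    pipeline must find the co-culture value above the mono-culture one.
    """
    marker_mono_fibro = {"marker": (40.0, 8.0)}
    marker_co_fibro = {"marker": (80.0, 12.0)}
    marker_co_cancer = {"marker": (60.0, 10.0)}

    def levels(base: dict, extra: dict) -> dict:
        return {"channel_levels": {**base, **extra}}

    fibro_base = {"cea": (50.0, 10.0), "coll4": (80.0, 12.0)}
    cancer_base = {"cea": (200.0, 30.0), "coll4": (20.0, 5.0)}
    results = {}
    for condition, cancer_extra, fibro_extra, stream in (
        ("mono_fibroblast", None, marker_mono_fibro, 1),
        ("co_culture", marker_co_cancer, marker_co_fibro, 2),
    ):
        per_cavity = []
        cavities = synth.generate_condition_set(
            condition,
            n_cavities=n_cavities,
            seed=derive_seeds(seed, 1, stream=stream)[0],
            shape=shape,
            cancer_overrides=(
                levels(cancer_base, cancer_extra) if cancer_extra else None
            ),
            fibroblast_overrides=levels(fibro_base, fibro_extra),
        )
        for i, (stack, _) in enumerate(cavities):
            fg = segment_dapi(stack)
            sub = subtract_background(stack, fg)
            per_cavity.append(
                intensity_per_volume(sub, fg, "marker",
                                     stack_id=f"cav{i}", condition=condition)
            )
        results[condition] = pool_volumetric(per_cavity)
    results["ratio"] = results["co_culture"] / results["mono_fibroblast"]
    return results


def tracker_tmrm_gaps(
    seeds: list[int], shape: tuple[int, int, int] = (16, 128, 128)
) -> list[float]:
    """Per-seed gap r(trackerA, TMRM) - r(trackerB, TMRM).

    The TMRM-like channel is co-placed with population A's tracker halos
    (cancer cells keep active mitochondria) and absent from population B's,
    so every gap must be positive for a pipeline that preserves channel
    identity.
    """
    gaps = []
    for seed in seeds:
        pops = [
            synth.cancer_spec(
                n_nuclei=40,
                channel_levels={
                    "tracker_green": (150.0, 20.0),
                    "tmrm": (120.0, 30.0),
                    "cea": (200.0, 30.0),
                    "coll4": (20.0, 5.0),
                },
            ),
            synth.fibroblast_spec(
                n_nuclei=20,
                channel_levels={
                    "tracker_deepred": (150.0, 20.0),
                    "cea": (50.0, 10.0),
                    "coll4": (80.0, 12.0),
                },
            ),
        ]
        stack, _ = synth.generate_stack(shape, pops, seed=seed)
        tmrm = stack.channel("tmrm")
        r_a = pearson_above_threshold(stack.channel("tracker_green"), tmrm, (0, 0))
        r_b = pearson_above_threshold(stack.channel("tracker_deepred"), tmrm, (0, 0))
        gaps.append(r_a - r_b)
    return gaps
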