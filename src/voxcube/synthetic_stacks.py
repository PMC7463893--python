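"""Ground-truth-labeled synthetic 3-D co-culture stacks.

Emulates dense scaffold-free cultures of two intermingled cell populations as
seen by a confocal microscope: a cancer-like population with bright, small,
round nuclei, high CEA and low collagen-IV, and a fibroblast-like population
with dim, large, elongated nuclei, low CEA and high collagen-IV.

Geometry.  The imaged volume holds a dense cell mass (a cylinder in XY,
standing in for a microcavity culture) surrounded by empty, cleared medium.
Nuclei are rigid ellipsoids with random in-plane orientation, placed by
rejection sampling; collisions are tested on a slightly shrunk core so nuclei
can pack close enough to touch, as they do in real confluent cultures where
instance segmentation fails.  DAPI intensity is nuclear; membrane/matrix
markers (CEA, Coll4, optional extras) fill a perinuclear cytoplasmic halo.
In co-cultures the two populations occupy contiguous patches of the cell
mass (clusters of one type interspersed in the other), with ``mixing =
"islets"`` confining the second population to fewer, tighter islets.

Image formation.  The clean volume is blurred with a narrow anisotropic
Gaussian PSF surrogate plus a wide-Gaussian scattered-light (haze) component
— dense cleared specimens show substantial out-of-focus light — then offset
by a constant background and corrupted with Poisson shot noise and additive
Gaussian read noise.

All intensity levels and geometric parameters are stand-ins chosen to be
plausible for antibody-stained dense cultures (no numeric intensity
distributions exist for the real specimens); they are plain config, not
constants.  Every draw flows from one integer seed: identical seeds give
bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stack_io import ImageStack

BACKGROUND, CANCER, FIBROBLAST = 0, 1, 2
LABEL_NAMES = {BACKGROUND: "background", CANCER: "cancer", FIBROBLAST: "fibroblast"}
_LABEL_CODE = {"cancer": CANCER, "fibroblast": FIBROBLAST}


class PlacementError(RuntimeError):
    """Raised when nuclei of a population cannot be placed without overlap."""


@dataclass
class PopulationSpec:
    """Geometry and staining statistics of one cell population.

    ``nucleus_radius_um`` and ``elongation`` are (mean, sd) pairs; a nucleus
    gets semi-axes ``(r, r, r * e)`` (z, in-plane minor, in-plane major) with
    a random in-plane orientation.  ``dapi_level`` and each entry of
    ``channel_levels`` are (mean, sd) of per-cell staining intensity.
    """

    label: str
    n_nuclei: int
    nucleus_radius_um: tuple[float, float]
    elongation: tuple[float, float]
    dapi_level: tuple[float, float]
    channel_levels: dict[str, tuple[float, float]]
    cytoplasm_halo_um: float = 2.5

    def __post_init__(self) -> None:
        if self.label not in _LABEL_CODE:
            raise ValueError(f"label must be cancer or fibroblast, got {self.label!r}")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.nucleus_radius_um[0] <= 0 or self.cytoplasm_halo_um <= 0:
            raise ValueError("radii and halo thickness must be positive")
        if self.dapi_level[0] < 0 or any(m < 0 for m, _ in self.channel_levels.values()):
            raise ValueError("intensity means must be nonnegative")


@dataclass
class GroundTruth:
    """Per-voxel cell-type labels accompanying a synthetic stack.

    ``label_volume`` covers nuclei and their cytoplasmic halos;
    ``nucleus_mask`` flags the nuclear (DAPI-bearing) voxels only.
    """

    label_volume: np.ndarray  # uint8 (Z, Y, X), values {0, 1, 2}
    nucleus_centers: list[tuple[int, int, int, str]]  # (z, y, x, label)
    nucleus_mask: np.ndarray | None = None  # bool (Z, Y, X)


# ---------------------------------------------------------------------------
# Default population parameterizations.
#
# DAPI contrast ~3x (bright small cancer nuclei vs dim large fibroblast
# nuclei); CEA cancer-high and Coll4 fibroblast-high, each with ~4x
# separation, chosen so that Otsu segmentation of DAPI is well-posed.

#: Reference nucleus packing (nuclei per voxel of cell-mass volume).  Cancer
#: cells are small and epithelial and pack more per volume.
NUCLEUS_DENSITY = {"cancer": 8.5e-4, "fibroblast": 4.2e-4}


def cancer_spec(n_nuclei: int, **overrides) -> PopulationSpec:
    """HT-29-like population: bright small round nuclei, CEA-high."""
    params = dict(
        label="cancer",
        n_nuclei=n_nuclei,
        nucleus_radius_um=(3.5, 0.4),
        elongation=(1.2, 0.1),
        dapi_level=(300.0, 45.0),
        channel_levels={"cea": (200.0, 30.0), "coll4": (20.0, 5.0)},
        cytoplasm_halo_um=2.5,
    )
    params.update(overrides)
    return PopulationSpec(**params)


def fibroblast_spec(n_nuclei: int, **overrides) -> PopulationSpec:
    """CCD-1137Sk-like population: dim large elongated nuclei, Coll4-high."""
    params = dict(
        label="fibroblast",
        n_nuclei=n_nuclei,
        nucleus_radius_um=(4.5, 0.5),
        elongation=(2.3, 0.3),
        dapi_level=(100.0, 20.0),
        channel_levels={"cea": (50.0, 10.0), "coll4": (80.0, 12.0)},
        cytoplasm_halo_um=2.5,
    )
    params.update(overrides)
    return PopulationSpec(**params)


DEFAULT_NOISE = {"gaussian_sd": 2.0, "poisson_scaling": 1.0}
DEFAULT_BLUR_SIGMA_PX = (1.0, 1.0, 1.5)  # (sx, sy, sz): confocal PSF is longer in z
DEFAULT_BACKGROUND = 10.0
DEFAULT_HAZE_FRACTION = 0.25
DEFAULT_HAZE_SIGMA_PX = (6.0, 6.0, 3.0)  # (sx, sy, sz)
DEFAULT_REGION_RADIUS_FRAC = 0.44  # cell-mass cylinder radius / min(Y, X)
DEFAULT_CORE_SCALE = 0.85  # collision core shrink: nuclei may touch
DEFAULT_CLUSTER_RADIUS_PX = 40.0  # target radius of minority-population clusters


def _ellipsoid_voxels(
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],  # (az, a_minor, a_major), voxels
    theta: float,
    shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel indices inside an in-plane-rotated ellipsoid, clipped to shape."""
    cz, cy, cx = center
    az, amin_, amaj = semi_axes
    r_xy = max(amin_, amaj)
    z0, z1 = max(int(np.floor(cz - az)), 0), min(int(np.ceil(cz + az)) + 1, shape[0])
    y0, y1 = max(int(np.floor(cy - r_xy)), 0), min(int(np.ceil(cy + r_xy)) + 1, shape[1])
    x0, x1 = max(int(np.floor(cx - r_xy)), 0), min(int(np.ceil(cx + r_xy)) + 1, shape[2])
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        empty = np.array([], dtype=np.intp)
        return empty, empty.copy(), empty.copy()
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    dz, dy, dx = zz - cz, yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)  # along the major axis
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    inside = (dz / az) ** 2 + (u / amaj) ** 2 + (v / amin_) ** 2 <= 1.0
    return zz[inside], yy[inside], xx[inside]


def _region_and_patches(
    shape: tuple[int, int, int],
    populations: list[PopulationSpec],
    mixing: str,
    region_radius_frac: float,
    cluster_radius_px: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Per-population 2-D boolean maps of allowed nucleus-center positions.

    The cell mass is a centered XY cylinder.  With two populations, the
    second (conventionally the fibroblasts) is confined to compact circular
    clusters interspersed in the first population's colony, and the first
    gets the complement — the mixing pattern seen in chip co-cultures.
    Cluster area is allocated by *packing-normalized* share
    (``n_nuclei / reference density``), so each population keeps the same
    local density it has in mono-culture.  ``islets`` mode shrinks the
    cluster area to 60% and uses smaller radii: fewer, tighter, denser
    islets, as in spheroid co-cultures.
    """
    _, ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    radius = region_radius_frac * min(ny, nx)
    region = (yy - ny / 2) ** 2 + (xx - nx / 2) ** 2 <= radius**2
    if len(populations) < 2:
        return [region for _ in populations]
    region_area = float(region.sum())
    weights = [p.n_nuclei / NUCLEUS_DENSITY[p.label] for p in populations]
    total_w = sum(weights) or 1.0
    maps: list[np.ndarray | None] = [None] * len(populations)
    carved = np.zeros_like(region)
    for i in range(1, len(populations)):
        share = weights[i] / total_w
        r_target = cluster_radius_px
        if mixing == "islets":
            share *= 0.6
            r_target = cluster_radius_px * 0.6
        cluster_area = share * region_area
        k = max(1, round(cluster_area / (np.pi * r_target**2)))
        r_c = float(np.sqrt(cluster_area / (k * np.pi)))
        allowed = np.zeros_like(region)
        placed: list[tuple[float, float]] = []
        for _ in range(k):
            for _attempt in range(200):
                ang = rng.uniform(0, 2 * np.pi)
                rad = max(0.0, radius - r_c) * np.sqrt(rng.uniform())
                cy = ny / 2 + rad * np.sin(ang)
                cx = nx / 2 + rad * np.cos(ang)
                if all((cy - py) ** 2 + (cx - px) ** 2 > (1.6 * r_c) ** 2
                       for py, px in placed):
                    break
            placed.append((cy, cx))
            allowed |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_c**2
        allowed &= region & ~carved
        carved |= allowed
        maps[i] = allowed
    maps[0] = region & ~carved
    return maps


def _place_population(
    spec: PopulationSpec,
    shape: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float],
    occupied: np.ndarray,
    allowed_xy: np.ndarray,
    rng: np.random.Generator,
    core_scale: float,
    max_attempts_per_nucleus: int = 800,
) -> list[dict]:
    """Rejection-sample non-overlapping nuclei inside an allowed XY map."""
    dz_um, dy_um, dx_um = voxel_size_um
    ys, xs = np.nonzero(allowed_xy)
    if spec.n_nuclei > 0 and ys.size == 0:
        raise PlacementError(f"no allowed region for population {spec.label!r}")
    nuclei = []
    for _ in range(spec.n_nuclei):
        for _attempt in range(max_attempts_per_nucleus):
            r = max(0.5, rng.normal(*spec.nucleus_radius_um))
            e = max(1.0, rng.normal(*spec.elongation))
            theta = rng.uniform(0, np.pi)
            az, amin_, amaj = r / dz_um, r / dy_um, r * e / dx_um
            j = rng.integers(ys.size)
            center = (
                rng.uniform(0, shape[0]),
                ys[j] + rng.uniform(-0.5, 0.5),
                xs[j] + rng.uniform(-0.5, 0.5),
            )
            core = _ellipsoid_voxels(
                center, (az * core_scale, amin_ * core_scale, amaj * core_scale),
                theta, shape,
            )
            if core[0].size == 0 or occupied[core].any():
                continue
            occupied[core] = True
            nuclei.append(
                {
                    "center": center,
                    "semi_axes": (az, amin_, amaj),
                    "theta": theta,
                    "voxels": _ellipsoid_voxels(center, (az, amin_, amaj), theta, shape),
                }
            )
            break
        else:
            raise PlacementError(
                f"could not place all {spec.n_nuclei} {spec.label} nuclei "
                f"without overlap in volume {shape}"
            )
    return nuclei


def generate_stack(
    shape: tuple[int, int, int],
    populations: list[PopulationSpec],
    blur_sigma_px: tuple[float, float, float] = DEFAULT_BLUR_SIGMA_PX,
    noise: dict | None = None,
    background_level: float = DEFAULT_BACKGROUND,
    mixing: str = "interspersed",
    seed: int = 0,
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    haze_fraction: float = DEFAULT_HAZE_FRACTION,
    haze_sigma_px: tuple[float, float, float] = DEFAULT_HAZE_SIGMA_PX,
    region_radius_frac: float = DEFAULT_REGION_RADIUS_FRAC,
    core_scale: float = DEFAULT_CORE_SCALE,
    cluster_radius_px: float = DEFAULT_CLUSTER_RADIUS_PX,
) -> tuple[ImageStack, GroundTruth]:
    """Simulate one multichannel cavity stack with per-voxel truth labels.

    ``shape`` is ``(Z, Y, X)`` in voxels; ``blur_sigma_px`` and
    ``haze_sigma_px`` are ``(sx, sy, sz)``.  ``noise`` holds
    ``poisson_scaling`` (photons per intensity unit; 0 disables shot noise)
    and ``gaussian_sd`` (read noise).  ``haze_fraction`` is the share of
    signal routed through the wide scattered-light kernel (0 disables it).
    Channels are ``[dapi, cea, coll4, ...]`` in first-seen order.
    """
    if noise is None:
        noise = dict(DEFAULT_NOISE)
    if mixing not in ("interspersed", "islets"):
        raise ValueError(f"unknown mixing mode {mixing!r}")

    rng = np.random.default_rng(seed)
    roles: list[str] = ["dapi"]
    for pop in populations:
        for role in pop.channel_levels:
            if role not in roles:
                roles.append(role)
    for required in ("cea", "coll4"):
        if populations and required not in roles:
            roles.append(required)

    clean = np.zeros((*shape, len(roles)), dtype=np.float64)
    labels = np.zeros(shape, dtype=np.uint8)
    occupied = np.zeros(shape, dtype=bool)  # collision cores
    occupied_full = np.zeros(shape, dtype=bool)  # full nuclear ellipsoids
    centers: list[tuple[int, int, int, str]] = []
    allowed_maps = _region_and_patches(
        shape, populations, mixing, region_radius_frac, cluster_radius_px, rng
    )

    for pop, allowed in zip(populations, allowed_maps):
        code = _LABEL_CODE[pop.label]
        nuclei = _place_population(
            pop, shape, voxel_size_um, occupied, allowed, rng, core_scale
        )
        for nuc in nuclei:
            idx = nuc["voxels"]
            clean[(*idx, roles.index("dapi"))] += max(0.0, rng.normal(*pop.dapi_level))
            labels[idx] = code  # nucleus label wins over any earlier halo
            occupied_full[idx] = True
            az, amin_, amaj = nuc["semi_axes"]
            h = pop.cytoplasm_halo_um
            halo_idx = _ellipsoid_voxels(
                nuc["center"], (az + h, amin_ + h, amaj + h), nuc["theta"], shape
            )
            shell = ~np.isin(
                np.ravel_multi_index(halo_idx, shape),
                np.ravel_multi_index(idx, shape),
            )
            shell_idx = tuple(a[shell] for a in halo_idx)
            for role, (mean, sd) in pop.channel_levels.items():
                clean[(*shell_idx, roles.index(role))] += max(0.0, rng.normal(mean, sd))
            unlabeled = labels[shell_idx] == BACKGROUND
            labels[tuple(a[unlabeled] for a in shell_idx)] = code
            cz, cy, cx = (int(round(c)) for c in nuc["center"])
            centers.append((cz, cy, cx, pop.label))

    sx, sy, sz = blur_sigma_px
    out = clean
    if any(s > 0 for s in blur_sigma_px) or haze_fraction > 0:
        hx, hy, hz = haze_sigma_px
        blurred = np.empty_like(out)
        for c in range(out.shape[-1]):
            focal = ndimage.gaussian_filter(out[..., c], sigma=(sz, sy, sx))
            if haze_fraction > 0:
                haze = ndimage.gaussian_filter(out[..., c], sigma=(hz, hy, hx))
                blurred[..., c] = (1 - haze_fraction) * focal + haze_fraction * haze
            else:
                blurred[..., c] = focal
        out = blurred
    out = out + background_level
    scaling = float(noise.get("poisson_scaling", 0.0))
    if scaling > 0:
        out = rng.poisson(out * scaling).astype(np.float64) / scaling
    gaussian_sd = float(noise.get("gaussian_sd", 0.0))
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, size=out.shape)
    out = np.clip(out, 0.0, None)

    stack = ImageStack(voxels=out, voxel_size_um=voxel_size_um, channels=tuple(roles))
    return stack, GroundTruth(
        label_volume=labels, nucleus_centers=centers, nucleus_mask=occupied_full
    )


# ---------------------------------------------------------------------------
# Condition sets

#: Default cavity geometry (Z, Y, X): a scaled-down stand-in for the
#: 1024 x 1024 px acquisitions.  192 px in XY holds a 6 x 6 cube grid;
#: 32 z-planes hold two cube layers.
DEFAULT_CAVITY_SHAPE = (32, 192, 192)


def _default_counts(
    condition: str,
    shape: tuple[int, int, int],
    region_radius_frac: float = DEFAULT_REGION_RADIUS_FRAC,
) -> dict[str, int]:
    """Nucleus counts from the reference packing densities and region volume.

    Mirrors the seeding scheme of the study system: mono-cultures carry the
    full density of one population, the co-culture half of each.
    """
    z, ny, nx = shape
    volume = np.pi * (region_radius_frac * min(ny, nx)) ** 2 * z
    full = {k: int(round(d * volume)) for k, d in NUCLEUS_DENSITY.items()}
    if condition == "mono_cancer":
        return {"cancer": full["cancer"], "fibroblast": 0}
    if condition == "mono_fibroblast":
        return {"cancer": 0, "fibroblast": full["fibroblast"]}
    if condition == "co_culture":
        return {k: v // 2 for k, v in full.items()}
    raise ValueError(f"unknown condition {condition!r}")


def condition_populations(
    condition: str,
    shape: tuple[int, int, int] = DEFAULT_CAVITY_SHAPE,
    cancer_overrides: dict | None = None,
    fibroblast_overrides: dict | None = None,
) -> list[PopulationSpec]:
    """Population specs for a culture condition at the default densities."""
    counts = _default_counts(condition, shape)
    cancer_overrides = cancer_overrides or {}
    fibroblast_overrides = fibroblast_overrides or {}
    pops = []
    if counts["cancer"]:
        pops.append(cancer_spec(n_nuclei=counts["cancer"], **cancer_overrides))
    if counts["fibroblast"]:
        pops.append(fibroblast_spec(n_nuclei=counts["fibroblast"], **fibroblast_overrides))
    return pops


def derive_cavity_seeds(master_seed: int, n_cavities: int) -> list[int]:
    """Deterministic per-cavity seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n_cavities)]


def generate_condition_set(
    condition: str,
    n_cavities: int = 5,
    seed: int = 0,
    shape: tuple[int, int, int] = DEFAULT_CAVITY_SHAPE,
    mixing: str = "interspersed",
    cancer_overrides: dict | None = None,
    fibroblast_overrides: dict | None = None,
    **stack_kwargs,
) -> list[tuple[ImageStack, GroundTruth]]:
    """Generate the per-condition cavity replicates (default 5 cavities).

    Each cavity is an independent placement, reseeded deterministically from
    the master seed.
    """
    if n_cavities < 1:
        raise ValueError("n_cavities must be >= 1")
    populations = condition_populations(
        condition, shape, cancer_overrides, fibroblast_overrides
    )
    return [
        generate_stack(
            shape, populations, mixing=mixing, seed=cavity_seed, **stack_kwargs
        )
        for cavity_seed in derive_cavity_seeds(seed, n_cavities)
    ]


def majority_label_per_cube(
    truth: GroundTruth,
    cube_shape: tuple[int, int, int] = (32, 32, 16),
) -> dict[tuple[int, int, int], str]:
    """Majority cell-type label over each cube's non-background truth voxels.

    Cubes with no labeled voxel are omitted; exact ties go to cancer (a
    deterministic, documented tie-break).
    """
    from .cube_quant import partition_grid

    cx, cy, cz = cube_shape
    out = {}
    for grid_index, (z0, y0, x0) in partition_grid(
        truth.label_volume.shape, cube_shape
    ):
        block = truth.label_volume[z0:z0 + cz, y0:y0 + cy, x0:x0 + cx]
        n_cancer = int((block == CANCER).sum())
        n_fibro = int((block == FIBROBLAST).sum())
        if n_cancer == 0 and n_fibro == 0:
            continue
        out[grid_index] = "cancer" if n_cancer >= n_fibro else "fibroblast"
    return out


def save_synthetic(
    prefix,
    stack: ImageStack,
    truth: GroundTruth,
    params: dict | None = None,
):
    """Write a stack as OME-TIFF with a label-volume TIFF and YAML sidecar.

    The truth TIFF uses the palette 0 = background, 1 = cancer,
    2 = fibroblast.
    """
    from pathlib import Path

    import tifffile
    import yaml

    from .stack_io import write_stack

    prefix = Path(prefix)
    write_stack(stack, prefix.with_suffix(".ome.tif"))
    tifffile.imwrite(prefix.parent / (prefix.name + "_labels.tif"), truth.label_volume)
    sidecar = {
        "label_palette": {int(k): v for k, v in LABEL_NAMES.items()},
        "channels": list(stack.channels),
        "voxel_size_um": list(stack.voxel_size_um),
        "params": params or {},
    }
    with open(prefix.parent / (prefix.name + "_params.yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return prefix
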