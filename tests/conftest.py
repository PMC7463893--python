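"""Shared fixtures: small synthetic stacks built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from voxcube import synthetic_stacks as synth
from voxcube.stack_io import ImageStack


def make_stack(voxels, channels=("dapi",), voxel_size=(1.0, 1.0, 1.0)):
    """Wrap a (Z, Y, X[, C]) array into an ImageStack."""
    voxels = np.asarray(voxels, dtype=np.float64)
    if voxels.ndim == 3:
        voxels = voxels[..., np.newaxis]
    return ImageStack(voxels=voxels, voxel_size_um=voxel_size, channels=channels)


CLEAN = dict(
    blur_sigma_px=(0, 0, 0),
    haze_fraction=0.0,
    noise={"gaussian_sd": 0.0, "poisson_scaling": 0.0},
    background_level=0.0,
)


@pytest.fixture(scope="session")
def default_cavity():
    """One default-parameter fibroblast mono-culture cavity (full noise model)."""
    stacks = synth.generate_condition_set("mono_fibroblast", n_cavities=1, seed=42)
    return stacks[0]


@pytest.fixture(scope="session")
def default_co_cavity():
    """One default-parameter co-culture cavity (full noise model)."""
    stacks = synth.generate_condition_set("co_culture", n_cavities=1, seed=43)
    return stacks[0]


@pytest.fixture(scope="session")
def clean_single_nucleus():
    """One cancer nucleus, no blur, no haze, no noise, zero background."""
    pop = synth.cancer_spec(n_nuclei=1)
    return synth.generate_stack((24, 48, 48), [pop], seed=7, **CLEAN)
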