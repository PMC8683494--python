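"""Shared fixtures: small phantoms and electrode layouts built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ieegcoverage.grid import VolumeGrid
from ieegcoverage.synthetic import CohortConfig, PhantomSpec, generate_phantom
from ieegcoverage.volumes import TissueProbabilityVolumes


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    """Gyrified phantom at 2 mm voxels, the cohort-analysis resolution."""
    return PhantomSpec(voxel_mm=2.0)


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    return generate_phantom(phantom_spec)


@pytest.fixture(scope="session")
def cohort_config(phantom_spec) -> CohortConfig:
    return CohortConfig(phantom=phantom_spec)


@pytest.fixture
def slab_spec() -> PhantomSpec:
    """Hard-boundary flat slab: closed-form tissue volumes."""
    return PhantomSpec(
        extent_mm=(100.0, 100.0, 60.0),
        voxel_mm=1.0,
        cortical_thickness_mm=3.0,
        gyral_amplitude_mm=0.0,
        csf_thickness_mm=15.0,
        interhemispheric_gap_mm=0.0,
        softness_mm=0.0,
        include_deep_structures=False,
    )


def homogeneous_tissue(extent_mm: float, tissue: str = "gm") -> TissueProbabilityVolumes:
    """Uniform single-tissue block (probability 1 everywhere) on a coarse
    carrier grid; used by FEM and sphere-oracle tests."""
    grid = VolumeGrid.from_spacing((8, 8, 8), extent_mm / 8, (extent_mm / 16,) * 3)
    one = np.ones(grid.shape)
    zero = np.zeros(grid.shape)
    maps = {"gm": zero, "wm": zero, "csf": zero}
    maps[tissue] = one
    return TissueProbabilityVolumes(grid, maps["gm"], maps["wm"], maps["csf"])


@pytest.fixture
def fine_grid() -> VolumeGrid:
    """1 mm isotropic grid, 40 mm cube, voxel centers on half-integers."""
    return VolumeGrid.from_spacing((40, 40, 40), 1.0, (0.5, 0.5, 0.5))
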