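import numpy as np
import pytest

from octamorph.containers import BinaryVesselMask
from octamorph.synth import (CohortSpec, PhantomSpec, generate_cohort,
                             generate_vessel_phantom)


@pytest.fixture(scope="session")
def full_phantom():
    """Default 304-px phantom with trees, capillary mesh and FAZ ring."""
    spec = PhantomSpec(seed=1)
    image, truth = generate_vessel_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def trees_phantom():
    """Arteriole/venule trees only (no mesh): clean Strahler topology."""
    spec = PhantomSpec(seed=3, capillary_density_target=0.0)
    image, truth = generate_vessel_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def small_phantom():
    """Down-scaled phantom where brute-force pixel oracles are affordable."""
    spec = PhantomSpec(grid_size=(96, 96), field_mm=0.95, n_trees=2,
                       branch_depth=3, faz_axes=(0.12, 0.09), seed=7)
    image, truth = generate_vessel_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def truth_mask(full_phantom):
    _, image, truth = full_phantom
    return BinaryVesselMask(truth.vessel_mask(), truth.pixel_size_mm)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(seed=11))
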