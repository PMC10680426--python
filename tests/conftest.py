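import numpy as np
import pytest

from rectdvh.cohort import CohortConfig, generate_cohort
from rectdvh.grids import DoseGrid, StructureMask


def make_mask(occ, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), name="m"):
    return StructureMask(np.asarray(origin, float), np.asarray(spacing, float),
                         np.asarray(occ, bool), name)


def column_mask(z_slices, nz, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), name="m"):
    """1x1xnz mask occupied on the given slice indices."""
    occ = np.zeros((1, 1, nz), dtype=bool)
    occ[0, 0, list(z_slices)] = True
    return make_mask(occ, spacing, origin, name)


def uniform_dose(mask, value):
    return DoseGrid(mask.origin.copy(), mask.spacing.copy(),
                    np.full(mask.array_shape, float(value)))


@pytest.fixture(scope="session")
def cohort200():
    """A 200-patient synthetic cohort under the default study conditions."""
    return generate_cohort(CohortConfig(n_patients=200, seed=20))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_patients=40, seed=7))
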