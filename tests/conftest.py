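import numpy as np
import pytest

import macroflim as mf


@pytest.fixture(scope="session")
def acq():
    """Standard TCSPC timing on a small test field."""
    return mf.AcquisitionParams(image_size=64)


@pytest.fixture(scope="session")
def gt_params():
    return mf.GroundTruthParams(
        I0=1.0, alpha1=0.3, alpha2=0.7, tau1=2.5, tau2=0.4, C=0.0
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for fast structural tests (not the study conditions)."""
    return mf.CohortConfig(
        seed=11,
        n_donors=2,
        fields_per_condition=1,
        cells_per_field=6,
        cell_radius=4,
        photons_per_cell=8000.0,
        treatments=("FCCP",),
        acq=mf.AcquisitionParams(image_size=64),
    )


@pytest.fixture(scope="session")
def fccp_field(small_cohort):
    return mf.generate_field(small_cohort, mf.Condition("A", "M2", "FCCP", 0))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
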