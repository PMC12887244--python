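import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spineprint as sp

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def spine_c4c6():
    return sp.build_spinal_parcellation(["C4", "C5", "C6"])


@pytest.fixture(scope="session")
def tiny_spine():
    """One-level spinal parcellation (14 ROIs) for cheap cohort tests."""
    return sp.build_spinal_parcellation(["C4"])


@pytest.fixture(scope="session")
def combined_parcellation():
    """Two spinal levels plus a reduced 20-ROI brain block."""
    return (sp.build_spinal_parcellation(["C4", "C5"])
            + sp.build_brain_parcellation(n_cortical=16, n_subcortical=4))


@pytest.fixture(scope="session")
def default_cohort(spine_c4c6):
    """The default study-condition cohort: 15 subjects, 42 ROIs, T=300."""
    spec = sp.CohortSpec(n_subjects=15, parcellation=spine_c4c6, seed=7)
    return sp.generate_cohort(spec)


def make_run(data, parcellation, subject="sub-x", run=1):
    return sp.ParcelledRun(subject, run, np.asarray(data, float), parcellation)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
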