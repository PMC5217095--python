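import numpy as np
import pytest

from motionqc.synthetic_data import (
    GeneratorConfig,
    ThicknessParams,
    generate_cohort,
    write_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale synthetic cohort shared across read-only tests."""
    cfg = GeneratorConfig(
        n_participants=150,
        per_decade_min=12,
        seed=42,
        thickness=ThicknessParams(n_vertices=300, n_parcels=30),
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    """The small cohort written out in every on-disk input format."""
    out = tmp_path_factory.mktemp("cohort")
    paths = write_cohort(small_cohort, out)
    return paths
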