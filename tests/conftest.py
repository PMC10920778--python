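import numpy as np
import pytest

from gliohab import SyntheticCohortSpec, generate_cohort
from gliohab.pipeline import run_pipeline


@pytest.fixture(scope="session")
def small_spec() -> SyntheticCohortSpec:
    """A desk-scale cohort: same structure as the study-scale defaults,
    smaller grids and fewer frames so the suite stays fast."""
    return SyntheticCohortSpec(
        n_subjects=8,
        grid_shape=(32, 32, 32),
        tumour_size_range=(250, 700),
        bold_length=120,
        n_missing_post=2,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec, seed=7)


@pytest.fixture(scope="session")
def pipeline_result(small_cohort):
    return run_pipeline(small_cohort, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
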