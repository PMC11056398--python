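import numpy as np
import pytest

from bonetex.imaging import SliceImage
from bonetex.phantom import PhantomSpec, SyntheticCohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_roi(rng):
    """A 16x16 HU patch with trabecular-like bimodal values."""
    base = np.where(rng.random((16, 16)) < 0.5, 100.0, 300.0)
    return SliceImage(base + rng.normal(0, 5, (16, 16)), source_id="random_roi")


@pytest.fixture
def phantom_image():
    return PhantomSpec(density=0.5, seed=11)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 12-case synthetic cohort on disk, shared across pipeline tests."""
    out = tmp_path_factory.mktemp("cohort")
    spec = SyntheticCohortSpec(n_cases=12, seed=21)
    csv_path, table = generate_cohort(spec, out)
    return csv_path, table
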