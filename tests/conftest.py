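import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small imaging cohort shared by extraction-heavy tests."""
    from radhet.synthetic import CohortSpec, generate_cohort

    spec = CohortSpec(n_patients=3, lesions_per_patient=(3, 5),
                      heterogeneity_level=0.6, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_tables(small_cohort):
    from radhet.pipeline import extract_cohort_tables

    orig, eroded, dilated, _ = extract_cohort_tables(small_cohort)
    return orig, eroded, dilated


def random_roi(rng, max_side=4, n_levels=4):
    """Random small discretized ROI (levels grid + mask) for oracle tests."""
    shape = tuple(rng.integers(1, max_side + 1, size=3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return levels, mask
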