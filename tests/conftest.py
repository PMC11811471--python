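import numpy as np
import pytest

from rtfpipe import CohortConfig, PhantomSpec, generate_cohort, generate_map


@pytest.fixture(scope="session")
def small_spec():
    """A small annulus phantom that keeps per-test extraction cheap."""
    return PhantomSpec(grid_shape=(48, 48), ring_radii=(6.0, 14.0))


@pytest.fixture(scope="session")
def small_map(small_spec):
    return generate_map(small_spec, subject_effect=12.0, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """4 subjects x 1 slice x 2 fields on the small grid."""
    config = CohortConfig(n_subjects=4, slices_per_subject=1, master_seed=5)
    return generate_cohort(config, small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_discretized_roi(rng, shape=(8, 8), n_levels=4, p_mask=0.7):
    """A random small discretized ROI for oracle-equivalence checks."""
    from rtfpipe import discretize_roi

    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    values = rng.integers(0, n_levels, size=shape).astype(float) * 10.0
    values += rng.random(shape)  # sub-bin jitter: exercises the floor rule
    return discretize_roi(values, mask, bin_width=10.0)
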