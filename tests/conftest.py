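import numpy as np
import pytest

import capdyn as cd


@pytest.fixture(scope="session")
def small_cohort():
    """6-subject cohort (3 AD / 3 NC), small grid, for fast integration tests."""
    cfg = cd.default_cohort_config(42, n_per_group=3, n_voxels=300, n_frames=60, k_true=4)
    return cd.generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_run_with_variances(variances, n_voxels=50, subject_id="s1", seed=0):
    """Run whose frame-wise spatial variances equal ``variances`` exactly.

    Frame t is sqrt(v_t) times a fixed unit-variance spatial pattern.
    """
    rng = np.random.default_rng(seed)
    base = rng.standard_normal(n_voxels)
    base = (base - base.mean()) / base.std(ddof=1)
    v = np.asarray(variances, dtype=float)
    data = np.sqrt(v)[None, :] * base[:, None]
    return cd.BoldRun(data=data, tr=3.0, subject_id=subject_id)
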