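import numpy as np
import pytest

from gfconn.synthetic import GroundTruth, generate_cohort, generate_trait_connectomes


def make_ground_truth(n_regions=10, shares=(0.25, 0.05, 0.06, 0.64), total=1.0,
                      mean=0.0, session_noise_sd=0.0, offsets=None):
    """Uniform-edge ground truth for unit tests."""
    e = n_regions * (n_regions - 1) // 2
    a, c, t, u = (s * total for s in shares)
    return GroundTruth(
        n_regions=n_regions,
        mean_profile=np.full(e, mean),
        var_a=np.full(e, a),
        var_c=np.full(e, c),
        var_t=np.full(e, t),
        var_e=np.full(e, u),
        state_offsets=offsets or {},
        session_noise_sd=session_noise_sd,
    )


@pytest.fixture(scope="session")
def twin_cohort():
    """Mid-sized cohort with all three family types."""
    return generate_cohort(120, 80, 100, extra_sib_prob=0.3, age_range=(25, 35), seed=7)


@pytest.fixture(scope="session")
def twin_traits(twin_cohort):
    gt = make_ground_truth()
    return generate_trait_connectomes(twin_cohort, gt, seed=8)
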