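import numpy as np
import pytest

from stridekit import SynthConfig, generate_cohort
from stridekit.templates import StrideTemplate


def random_template(rng, m: int, d: int, side: str = "right") -> StrideTemplate:
    """Random well-conditioned template for kernel tests."""
    means = rng.normal(0.0, 1.0, (m, d))
    covs = np.empty((m, d, d))
    for i in range(m):
        a = rng.normal(0.0, 1.0, (d, d))
        covs[i] = a @ a.T + 0.5 * np.eye(d)
    return StrideTemplate(side, means, covs, toe_off_index=m // 2)


def identity_template(means, side: str = "right", toe_off: int | None = None):
    """Template with identity covariances (ML cost = squared Euclidean)."""
    means = np.asarray(means, dtype=float)
    m, d = means.shape
    covs = np.broadcast_to(np.eye(d), (m, d, d)).copy()
    return StrideTemplate(side, means, covs,
                          toe_off_index=m // 2 if toe_off is None else toe_off)


@pytest.fixture(scope="session")
def ideal_cohort():
    """Fully deterministic gait: no noise, no timing jitter, grid-aligned."""
    cfg = SynthConfig(n_subjects=3, joint_noise_sd=0.0,
                      within_subject_period_cv=0.0,
                      snap_period_to_frames=True, seed=5)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default study conditions at a small cohort size."""
    cfg = SynthConfig(n_subjects=4, seed=3)
    return cfg, generate_cohort(cfg)
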