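import numpy as np
import pytest

from pdtraj import CohortConfig, TruthDynamics, generate_cohort
from pdtraj.synthetic import ABETA, ASYN, MOCA


def single_marker_config(**overrides):
    """A one-marker exponential-approach cohort; overrides applied on top."""
    dyn = {ABETA: TruthDynamics("exponential_approach", k=0.1, plateau=600.0,
                                onset_level=1000.0)}
    ctrl = {ABETA: TruthDynamics("constant", onset_level=1000.0)}
    base = dict(n_pd=30, n_control=10, dynamics=dyn, control_dynamics=ctrl,
                noise_sd={ABETA: 0.0}, onset_level_sd={ABETA: 0.0},
                dropout_prob=0.0, high_hemoglobin_fraction=0.0,
                outlier_fraction=0.0, seed=7)
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture
def zero_noise_cohort():
    cfg = single_marker_config()
    visits, covariates, truth = generate_cohort(cfg)
    return cfg, visits, covariates, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
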