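import numpy as np
import pytest

from burstloco.simulate import (CohortSimParams, TrialSimParams,
                                simulate_cohort, simulate_trial,
                                simulate_level_trial as level_trial)


@pytest.fixture(scope="session")
def clean_trial():
    """Noiseless constant-acceleration half-bound: a=4 m/s^2, M=1 kg, v0=0."""
    params = TrialSimParams(accel_mean_m_s2=4.0, body_mass_kg=1.0,
                            v0_m_s=0.0, seed=1)
    return simulate_trial(params)


@pytest.fixture(scope="session")
def noisy_trial():
    """Half-sine trial with 1 mm marker noise and 0.5 N force noise."""
    params = TrialSimParams(accel_mean_m_s2=5.0, body_mass_kg=0.8,
                            v0_m_s=0.3, accel_profile="half-sine",
                            marker_noise_sd_m=1e-3, force_noise_sd_n=0.5,
                            seed=11)
    return simulate_trial(params)




@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortSimParams(seed=21))


@pytest.fixture(scope="session")
def flat_cohort():
    """Cohort with a negligible mass trend: variance components dominate."""
    params = CohortSimParams(seed=22, n_individuals=100,
                             trials_per_individual=10, curvature=-1e-6,
                             between_sd=float(np.sqrt(0.359)),
                             within_sd=float(np.sqrt(0.641)))
    return simulate_cohort(params)
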