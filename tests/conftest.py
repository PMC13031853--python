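import numpy as np
import pytest

from tractage.simulate import CohortConfig, ModeSpec, simulate_cohort


def quiet_cohort_config(**overrides):
    """A config with all noise sources off and zero couplings (exact checks)."""
    defaults = dict(
        n_subjects=50,
        n_sites=1,
        deviation_sd=0.0,
        tract_jitter_sd=0.0,
        noise_sd=0.0,
        tract_noise_sd=0.0,
        site_location_sd=0.0,
        site_scale_sd=0.0,
        modes=[
            ModeSpec("association", ("dorsal-association",), "cognition", 0.0),
            ModeSpec("subcortical-limbic", ("limbic",), "psychopathology", 0.0),
        ],
        seed=0,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-condition cohort shared across tests."""
    cc = CohortConfig(n_subjects=200, seed=7)
    cohort, profiles, behavior, diagnoses = simulate_cohort(cc)
    return {
        "config": cc,
        "cohort": cohort,
        "profiles": profiles,
        "behavior": behavior,
        "diagnoses": diagnoses,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
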