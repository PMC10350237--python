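import numpy as np
import pandas as pd
import pytest

from drckit.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def noiseless_config() -> CohortConfig:
    """Two pairs, noise and background off: every invariant holds exactly."""
    return CohortConfig(
        n_pairs=2, noise_sigma=0.0, control_drift=0.0, case_effect=0.4, seed=7
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    return generate_cohort(noiseless_config, return_latent=True)


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """Four pairs at default (study-condition) noise levels."""
    donors, points = generate_cohort(CohortConfig(n_pairs=4, seed=11))
    return donors, points


def planted_feature_table(
    n: int = 200, n_noise: int = 5, seed: int = 0, sigma: float = 0.1
) -> tuple[pd.DataFrame, np.ndarray]:
    """One informative feature (label + noise) plus pure-noise features."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame(
        {"planted": y + rng.normal(0.0, sigma, size=y.size)}
        | {
            f"noise_{j}": rng.normal(size=y.size)
            for j in range(n_noise)
        }
    )
    return X, y
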