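import numpy as np
import pandas as pd
import pytest

from hemoclock import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 1000-subject default-panel cohort shared across read-only tests."""
    return generate_cohort(GeneratorConfig(n_subjects=1000, seed=3))


def make_frame(n: int = 2000, seed: int = 0, slope: float = 0.1, noise: float = 0.0,
               n_noise_markers: int = 1) -> pd.DataFrame:
    """Hand-built complete cohort: m1 linear in age, m2.. pure noise."""
    rng = np.random.default_rng(seed)
    age = rng.integers(18, 93, n)
    frame = pd.DataFrame(
        {
            "id": [f"s{i:05d}" for i in range(n)],
            "age": age,
            "sex": rng.integers(0, 2, n),
            "smoking": rng.integers(0, 2, n),
            "m1": 3.0 + slope * age + rng.normal(0.0, noise, n) if noise else 3.0 + slope * age,
        }
    )
    for j in range(n_noise_markers):
        frame[f"noise{j + 1}"] = rng.normal(0.0, 1.0, n)
    return frame


@pytest.fixture()
def linear_frame() -> pd.DataFrame:
    return make_frame()
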