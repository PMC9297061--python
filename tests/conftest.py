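import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from metacate import io_data
from metacate.synthetic import SyntheticConfig, generate_cohort


def make_raw_frame(n=8, seed=0):
    """A small schema-complete raw table (pre-validation)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "Age": rng.uniform(16, 50, n).round(1),
        "Gender": rng.choice(["Female", "Male"], n),
        "Height": rng.uniform(1.5, 1.9, n).round(2),
        "Weight": rng.uniform(50, 120, n).round(1),
        "FHWO": rng.choice(["Yes", "No"], n),
        "FAVC": rng.choice(["Yes", "No"], n),
        "FCVC": rng.uniform(1, 3, n).round(2),
        "NCP": rng.uniform(1, 4, n).round(2),
        "CAEC": rng.choice(["No", "Sometimes", "Frequently", "Always"], n),
        "SMOKE": rng.choice(["Yes", "No"], n),
        "CH2O": rng.uniform(1, 3, n).round(2),
        "SCC": rng.choice(["Yes", "No"], n),
        "FAF": rng.uniform(0, 3, n).round(2),
        "TUE": rng.uniform(0, 2, n).round(2),
        "CALC": rng.choice(["No", "Sometimes", "Frequently"], n),
        "MTRANS": rng.choice(["Automobile", "Walking", "Public_Transportation"], n),
    })


@pytest.fixture
def raw_frame():
    return make_raw_frame(n=12, seed=42)


@pytest.fixture
def cohort(raw_frame):
    return io_data.validate_cohort(raw_frame)


@pytest.fixture(scope="session")
def linear_cohort():
    """Moderate-noise linear-CATE cohort with random 50/50 assignment."""
    return generate_cohort(
        SyntheticConfig(n=1200, cate="linear", noise_sd=1.0, assignment=0.5, seed=11))


def linear_dgp(n=240, p=4, heterogeneous=True, seed=0):
    """Noiseless linear potential-outcome data for exact-recovery checks."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    t = rng.integers(0, 2, n)
    beta1 = rng.normal(size=p)
    beta3 = rng.normal(size=p) if heterogeneous else np.zeros(p)
    tau = 1.5 + X @ beta3
    y = 3.0 + X @ beta1 + t * tau
    return X, y, t, tau
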