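import numpy as np
import pandas as pd
import pytest

from pmhm import schema
from pmhm.features import build_feature_table
from pmhm.synthetic import SubjectSpec, simulate_subject


@pytest.fixture(scope="session")
def complete_spec() -> SubjectSpec:
    """A fully-compliant subject: every scheduled EMA answered."""
    return SubjectSpec(seed=42, completion_prob=1.0)


@pytest.fixture(scope="session")
def complete_subject(complete_spec):
    return simulate_subject(complete_spec)


@pytest.fixture(scope="session")
def feature_table(complete_subject) -> pd.DataFrame:
    return build_feature_table(complete_subject)


def make_linear_table(
    n: int = 60,
    p: int = 5,
    betas=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Small generic regression table with a Likert-like positive target."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, size=(n, p))
    if betas is None:
        betas = np.zeros(p)
        betas[0] = 1.0
    y = 4.0 + X @ np.asarray(betas, dtype=float) + rng.normal(0, noise_sd, n)
    y = np.clip(y, 1.0, 7.0)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    df[schema.TARGET] = y
    return df
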