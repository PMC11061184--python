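import numpy as np
import pandas as pd
import pytest

from affectmed import CONDITIONS, SCALES, StudyConfig, generate_study
from affectmed.pipeline import study_analysis_frame


def null_paths() -> dict:
    return {(c, s): 0.0 for c in CONDITIONS for s in SCALES}


def single_mediator_config(a: float, b: float, n: int, seed: int,
                           mediator=("neutral", "disgust"), **kwargs) -> StudyConfig:
    """Study where only one condition x scale cell carries the effects."""
    a_paths = null_paths()
    b_paths = null_paths()
    a_paths[mediator] = a
    b_paths[mediator] = b
    return StudyConfig(
        n_participants=n, seed=seed, a_paths=a_paths, b_paths=b_paths,
        covariate_effects=(0.0,) * 6, **kwargs,
    )


@pytest.fixture(scope="session")
def small_study():
    """Clean defaults study, small enough for fast unit tests."""
    return generate_study(StudyConfig(n_participants=160, seed=11))


@pytest.fixture(scope="session")
def small_frame(small_study):
    return study_analysis_frame(small_study)


@pytest.fixture(scope="session")
def random_regression_data():
    """Factory for small random regression frames with a binary exposure,
    mediators and covariates (used for algebraic-identity tests)."""

    def make(seed: int, n: int = 80, n_mediators: int = 2) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        d = {"diagnosed": (rng.random(n) < 0.3).astype(float)}
        for j in range(n_mediators):
            d[f"m{j}"] = 0.3 * d["diagnosed"] + rng.standard_normal(n)
        d["cov1"] = rng.standard_normal(n) * 2 + 1
        d["cov2"] = (rng.random(n) < 0.5).astype(float)
        d["disruption"] = (
            0.2 * d["diagnosed"]
            + sum(0.25 * d[f"m{j}"] for j in range(n_mediators))
            + 0.1 * d["cov1"]
            + rng.standard_normal(n)
        )
        return pd.DataFrame(d)

    return make
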