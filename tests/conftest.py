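import numpy as np
import pytest

from fermopt import DesignSpec, FactorSpec, QuadraticModel, generate_ccfd, study_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return study_fixtures()


@pytest.fixture(scope="session")
def ccfd50(fixtures):
    """The study's 50-run, five-factor face-centered CCD in canonical order."""
    return generate_ccfd(fixtures["design_spec"])


@pytest.fixture()
def time_factor():
    return FactorSpec("time_days", 10.0, 11.0, 12.0)


def random_quadratic(rng: np.random.Generator, n: int) -> QuadraticModel:
    """A random full-quadratic model on n coded factors."""
    npair = n * (n - 1) // 2
    return QuadraticModel(
        intercept=float(rng.normal(20, 2)),
        linear=rng.normal(0, 0.5, n),
        interaction=rng.normal(0, 0.1, npair),
        quadratic=rng.normal(-0.8, 0.3, n),
    )


def small_design(n: int, n_c: int = 6):
    factors = tuple(FactorSpec(f"f{i}", -1.0, 0.0, 1.0) for i in range(n))
    return generate_ccfd(DesignSpec(factors=factors, n_center=n_c))
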