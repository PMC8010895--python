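import numpy as np
import pytest

from crtbaseline import CorrelationParams, DesignSpec, TimeEffectSpec


@pytest.fixture
def worked_example_template():
    """24-month trial, m=172, 9-month transition (6 closure + 3 implementation),
    transition data excluded from both arms; cross-over set per test."""

    def make(crossover_months: float) -> DesignSpec:
        return DesignSpec(
            m=172,
            crossover=crossover_months / 24.0,
            closure=6.0 / 24.0,
            implementation=3.0 / 24.0,
        )

    return make


@pytest.fixture
def worked_example_no_baseline():
    return DesignSpec.without_baseline(m=172, implementation=3.0 / 24.0)


def brute_force_gls_variance(Z: np.ndarray, V: np.ndarray, index: int) -> float:
    """Independent oracle: explicit (Z' V^-1 Z)^-1 on the joint matrices."""
    info = Z.T @ np.linalg.inv(V) @ Z
    return float(np.linalg.inv(info)[index, index])


def random_design(
    rng: np.random.Generator, max_m: int = 12, symmetric: bool = False
) -> DesignSpec:
    """A random admissible small design for property tests.

    ``symmetric=True`` forces both arms to share the retained grid
    (transition excluded in both arms), the regime in which the time-effect
    invariance theorem applies.
    """
    m = int(rng.integers(4, max_m + 1))
    closure = float(rng.uniform(0.0, 0.25))
    implementation = float(rng.uniform(0.0, 0.2))
    crossover = float(rng.uniform(closure + implementation, 1.0))
    return DesignSpec(
        m=m,
        crossover=crossover,
        closure=closure,
        implementation=implementation,
        control_recruits_in_transition=(
            False if symmetric else bool(rng.integers(0, 2))
        ),
    )


def random_corr(rng: np.random.Generator) -> CorrelationParams:
    return CorrelationParams(
        rho=float(rng.uniform(0.0, 0.3)), tau=float(rng.uniform(0.1, 1.0))
    )
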