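import numpy as np
import pytest

from doxorigami import (
    BindingParameters,
    DonDesign,
    FreeDoxReference,
    GeneratorConfig,
    default_registry,
)

#: Averaged fitted binding constants used throughout as planted truth.
K11, K12 = 2.0e5, 2.6e5
PHI_D11, PHI_D12 = -0.48, -0.933


@pytest.fixture
def triangle() -> DonDesign:
    return default_registry()["triangle"]


@pytest.fixture
def planted_params() -> BindingParameters:
    return BindingParameters(
        k11=K11,
        k12=K12,
        phi_delta_11={494.0: PHI_D11},
        phi_delta_12={494.0: PHI_D12},
    )


@pytest.fixture
def free_dox_reference() -> FreeDoxReference:
    return FreeDoxReference(c_dox=3e-6, phi0_proxy=1.0)


@pytest.fixture
def noiseless_config() -> GeneratorConfig:
    return GeneratorConfig(seed=7, noise_phi=0.0, noise_a=0.0)


def two_step_equilibrium_speciation(c_dox0, c_bp0, k11, k12):
    """Independent brute-force oracle for the two-step binding equilibrium.

    Solves the coupled mass balances for free DOX ``d`` and free bp ``c``
    (complexes c11 = K11*d*c, c12 = K11*K12*d*c^2) with a damped fixed-point
    iteration, no shared code with the package's cubic solver.
    Returns (free_dox, free_bp).
    """
    d, c = c_dox0, c_bp0
    for _ in range(200000):
        d_new = c_dox0 / (1.0 + k11 * c + k11 * k12 * c * c)
        c_new = _free_bp_given_dox(c_bp0, d_new, k11, k12)
        if abs(d_new - d) <= 1e-15 * max(d_new, 1e-300) and abs(c_new - c) <= 1e-15 * max(
            c_new, 1e-300
        ):
            d, c = d_new, c_new
            break
        d = 0.5 * d + 0.5 * d_new
        c = 0.5 * c + 0.5 * c_new
    return d, c


def _free_bp_given_dox(c_bp0, d, k11, k12):
    # bp balance: c + d*(k11*c + 2*k11*k12*c^2) = c_bp0, solved for c >= 0
    a = 2.0 * k11 * k12 * d
    b = 1.0 + k11 * d
    if a == 0:
        return c_bp0 / b
    disc = b * b + 4.0 * a * c_bp0
    return (-b + np.sqrt(disc)) / (2.0 * a)
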