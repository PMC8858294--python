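import numpy as np
import pytest

from prolylkin.datasets import load_binding_activity_table
from prolylkin.lineshape import ExchangeParameters
from prolylkin.synthetic import FixtureConfig


@pytest.fixture(scope="session")
def variant_table():
    return load_binding_activity_table()


@pytest.fixture()
def default_config():
    return FixtureConfig(seed=1234)


@pytest.fixture()
def exchange_params():
    return ExchangeParameters(
        p_cis=0.3, nu_cis=10.0, nu_trans=-10.0, r2_cis=10.0, r2_trans=10.0, k_ex=50.0
    )


@pytest.fixture()
def wide_axis():
    return np.linspace(-400.0, 400.0, 4001)


def matrix_inversion_oracle(params, axis):
    """Independent lineshape oracle: per-frequency 2x2 complex solve."""
    L = params.evolution_matrix()
    m0 = np.array([params.p_cis, params.p_trans], dtype=complex)
    ones = np.ones(2, dtype=complex)
    out = np.empty(len(axis))
    for i, nu in enumerate(axis):
        out[i] = (ones @ np.linalg.solve(2j * np.pi * nu * np.eye(2) - L, m0)).real
    return out
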