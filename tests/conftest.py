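import numpy as np
import pytest

from penosome.synth import (CompartmentModelParams, NetworkLayout,
                            PopulationSpec, simulate_compartment_network)
from penosome.traces import KineticTrace


@pytest.fixture(scope="session")
def params():
    return CompartmentModelParams()


def make_logistic(L=1.0, k=-0.1, x0=60.0, t=None, noise_sd=0.0, seed=0,
                  normalized=None):
    """Sample the printed logistic form A(x) = L/(1 + exp(k(x - x0)))."""
    if t is None:
        t = np.linspace(0.0, 150.0, 151)
    A = L / (1.0 + np.exp(k * (t - x0)))
    if noise_sd > 0:
        A = A + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    if normalized is None:
        normalized = abs(L - 1.0) < 1e-12
    return KineticTrace(t=t, A=A, normalized=normalized)


@pytest.fixture(scope="session")
def autocat_traceset(params):
    """One small compartmentalised autocatalytic run shared across tests."""
    layout = NetworkLayout(
        (PopulationSpec("autocatalytic", n_compartments=3),),
        volume_fraction=0.005)
    return simulate_compartment_network(params, layout, 1.0, 480.0, 2.0, seed=7)
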