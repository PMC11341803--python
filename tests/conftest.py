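"""Shared fixtures: small synthetic systems exercised across the suite."""

import numpy as np
import pytest

from molcond.bath import BathSpec
from molcond.electronic import ElectronicStructure, solve_eigensystem
from molcond.synthetic import ModelSpec, make_model


@pytest.fixture
def rng():
    return np.random.default_rng(20240823)


@pytest.fixture
def two_level_es():
    """Symmetric dimer with a 1 eV gap, μ at midgap."""
    raw = make_model(ModelSpec(kind="two_level", gap=1.0))
    return ElectronicStructure.from_raw(raw, 2)


@pytest.fixture
def chain_es():
    """Half-filled 8-site uniform chain."""
    raw = make_model(ModelSpec(kind="uniform_chain", n_sites=8, hopping=0.5))
    return ElectronicStructure.from_raw(raw, 8)


@pytest.fixture
def dba_es():
    """5-site donor-bridge-acceptor wire, frontier levels on the ends."""
    raw = make_model(ModelSpec(kind="dba_wire", n_sites=5, barrier=2.0, hopping=0.4))
    return ElectronicStructure.from_raw(raw, 6)


@pytest.fixture
def warm_bath():
    """Room-temperature bath with a cutoff comparable to toy level spacings.

    The protein default cutoff (0.0185 eV) freezes out transitions across
    eV-scale toy gaps, so the relaxation-driven tests use a larger cutoff.
    """
    return BathSpec(temperature_K=300.0, cutoff_ev=0.5)


def random_es(rng, n, mu=None, spread=1.0):
    """Electronic structure of a random symmetric Hamiltonian."""
    h = rng.normal(scale=spread, size=(n, n))
    h = 0.5 * (h + h.T)
    energies, psi = solve_eigensystem(h)
    homo = n // 2 - 1
    if mu is None:
        mu = 0.5 * (energies[homo] + energies[homo + 1])
    return ElectronicStructure(energies=energies, psi=psi, mu=float(mu),
                               homo_index=homo, lumo_index=homo + 1)
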