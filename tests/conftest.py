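import numpy as np
import pytest

from gccsd.hamiltonian_io import load_fixture, to_spin_orbitals
from gccsd.cc_ground import solve_cc


_so_cache = {}


def get_so(name):
    """Session-cached spin-orbital integrals for a packaged fixture."""
    if name not in _so_cache:
        _so_cache[name] = to_spin_orbitals(load_fixture(name).load())
    return _so_cache[name]


_cc_cache = {}


def get_cc(name, tol=1e-11):
    if (name, tol) not in _cc_cache:
        res = solve_cc(get_so(name), tol=tol, max_iter=400)
        assert res.converged, f"CCSD failed to converge on {name}"
        _cc_cache[(name, tol)] = res
    return _cc_cache[(name, tol)]


@pytest.fixture(scope="session")
def so_h2():
    return get_so("h2_sto3g")


@pytest.fixture(scope="session")
def so_h2_631g():
    return get_so("h2_631g")


@pytest.fixture(scope="session")
def so_h4_center():
    return get_so("h4_center")


@pytest.fixture(scope="session")
def cc_h2():
    return get_cc("h2_sto3g")


@pytest.fixture(scope="session")
def cc_h4_center():
    return get_cc("h4_center")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)
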