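"""Shared fixtures: synthetic networks, baths, and reusable heavy runs."""

import numpy as np
import pytest

import fcpexciton as fx


@pytest.fixture(scope="session")
def toy_network():
    """Deterministic 9-site FCP-like network (7 Chl-a + 2 Chl-c)."""
    pigments, H = fx.make_network(seed=3)
    return pigments, H


@pytest.fixture(scope="session")
def site_sds():
    """Default Chl-a / Chl-c spectral densities."""
    return fx.default_site_sds()


@pytest.fixture(scope="session")
def toy_absorption(toy_network, site_sds):
    """Full pool-decomposed spectrum and its 800 cm^-1-truncated variant."""
    _, H = toy_network
    full = fx.pool_decomposition(H, site_sds, 300.0)
    truncated_sds = {k: fx.truncate_sd(v, 800.0) for k, v in site_sds.items()}
    truncated = fx.absorption_cumulant(H, truncated_sds, 300.0)
    return full, truncated


@pytest.fixture(scope="session")
def toy_2des(toy_network, site_sds):
    """2DES of the toy network at waiting times 0 and 50 fs."""
    _, H = toy_network
    n_t = 96
    need = 2 * n_t + 27
    ensemble = fx.make_ensemble(H, site_sds, 300.0, 6, need, dt=2.0, seed=11)
    grid = np.arange(13800.0, 17200.0, 20.0)
    return fx.response_2d(
        ensemble, n_t1=n_t, n_t3=n_t, t2_list=[0.0, 50.0], w1_grid=grid, w3_grid=grid
    )


@pytest.fixture(scope="session")
def toy_pool_transfer(toy_network, site_sds):
    """Pool-transfer run of the toy network over 2 ps."""
    _, H = toy_network
    ensemble = fx.make_ensemble(H, site_sds, 300.0, 30, 1001, dt=2.0, seed=21)
    return fx.pool_transfer(ensemble, 2000.0)


@pytest.fixture()
def square_ring_pigment():
    """Planar pigment with NA on +y, ND on +x (canonical orientation)."""
    atoms = {
        "MG": np.zeros(3),
        "NA": np.array([0.0, 2.0, 0.0]),
        "NB": np.array([-2.0, 0.0, 0.0]),
        "NC": np.array([0.0, -2.0, 0.0]),
        "ND": np.array([2.0, 0.0, 0.0]),
    }
    return fx.Pigment("CLC403", fx.PigmentType.chl_c2, atoms, mu=[0.0, 2.4, 0.0])


def static_hamiltonian(sh_energies, J, mu=None, pools=None, n_steps=400, dt=2.0):
    """Helper: StochasticHamiltonian with zero fluctuations."""
    n = len(sh_energies)
    labels = [f"CLA{401 + i}" for i in range(n)]
    if pools is not None:
        label_pools = dict(zip(labels, pools))
    else:
        label_pools = {lab: "a" for lab in labels}
    if mu is None:
        mu = np.tile([4.0, 0.0, 0.0], (n, 1))
    H = fx.ExcitonHamiltonian(
        labels=labels, E=np.asarray(sh_energies, float), J=np.asarray(J, float),
        mu=np.asarray(mu, float), pools=label_pools,
    )
    traj = fx.Trajectory(dt=dt, delta=np.zeros((n, n_steps)))
    return fx.StochasticHamiltonian(H, traj)
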