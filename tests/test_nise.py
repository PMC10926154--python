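"""NISE propagation, population dynamics, linear response, 2DES."""

import numpy as np
import pytest
from scipy.linalg import expm

import fcpexciton as fx
from fcpexciton.constants import C_CM_FS, TWO_PI_C

from conftest import static_hamiltonian

GRID = np.arange(0.5, 2000.0, 0.5)


class TestPropagate:
    def test_static_diagonal_populations_constant(self):
        sh = static_hamiltonian([100.0, 300.0, 700.0], np.zeros((3, 3)))
        psi0 = np.array([0.6, 0.0, 0.8], dtype=complex)
        out = fx.propagate(sh, psi0, 100)
        assert np.max(np.abs(np.abs(out) ** 2 - np.abs(psi0) ** 2)) < 1e-12
        # phases evolve as exp(-i 2 pi c E t)
        t = 100 * sh.dt
        expected = psi0 * np.exp(-1j * TWO_PI_C * np.array([100.0, 300.0, 700.0]) * t)
        np.testing.assert_allclose(out[-1], expected, atol=1e-10)

    def test_resonant_dimer_transfer_time(self):
        J = 100.0
        sh = static_hamiltonian([0.0, 0.0], [[0.0, J], [J, 0.0]], dt=0.5, n_steps=400)
        out = fx.propagate(sh, np.array([1.0, 0.0], dtype=complex), 300)
        p2 = np.abs(out[:, 1]) ** 2
        t = np.arange(301) * 0.5
        t_transfer = t[np.argmax(p2)]
        assert abs(t_transfer - 1.0 / (4.0 * C_CM_FS * J)) <= 0.5  # one time step
        assert p2.max() > 0.999

    def test_matches_time_ordered_exponential_oracle(self):
        # random fluctuating 3-site system against scipy expm per step
        rng = np.random.default_rng(12)
        J = rng.normal(scale=30, size=(3, 3))
        J = 0.5 * (J + J.T)
        np.fill_diagonal(J, 0.0)
        E = rng.normal(15000, 100, size=3)
        delta = rng.normal(scale=80, size=(3, 120))
        H = fx.ExcitonHamiltonian(
            labels=["CLA401", "CLA402", "CLA403"], E=E, J=J, mu=np.zeros((3, 3)),
        )
        sh = fx.StochasticHamiltonian(H, fx.Trajectory(dt=2.0, delta=delta))
        psi0 = np.array([1.0, 0.0, 0.0], dtype=complex)
        ours = fx.propagate(sh, psi0, 100)
        psi = psi0.copy()
        for i in range(100):
            psi = expm(-1j * TWO_PI_C * sh.h_at(i) * sh.dt) @ psi
        assert np.max(np.abs(ours[-1] - psi)) < 1e-6

    def test_norm_conserved_under_fluctuations(self, toy_network, site_sds):
        _, H = toy_network
        ens = fx.make_ensemble(H, site_sds, 300.0, 1, 600, seed=2)
        out = fx.propagate(ens[0], np.eye(9, dtype=complex)[:, :3], 500)
        norms = np.linalg.norm(out[-1], axis=0)
        assert np.max(np.abs(norms - 1.0)) < 1e-10


class TestPoolTransfer:
    def test_uncoupled_pools_never_mix(self):
        sh = static_hamiltonian(
            [15000.0, 14600.0], np.zeros((2, 2)), pools=["a", "c"], n_steps=200
        )
        pops = fx.pool_transfer([sh], 200.0)
        np.testing.assert_allclose(pops.p_stay_a, 1.0, atol=1e-12)
        np.testing.assert_allclose(pops.p_c, 0.0, atol=1e-12)

    def test_fluctuating_dimer_equilibrates_to_half(self):
        H = fx.ExcitonHamiltonian(
            labels=["CLA401", "CLC402"], E=[15000.0, 15000.0],
            J=[[0.0, 30.0], [30.0, 0.0]],
            mu=np.array([[4.0, 0, 0], [2.4, 0, 0]]),
            pools={"CLA401": "a", "CLC402": "c"},
        )
        sd = fx.drude_sd(40.0, 40.0, GRID)
        ens = fx.make_ensemble(H, {"a": sd, "c": sd}, 300.0, 40, 2001, seed=9)
        pops = fx.pool_transfer(ens, 4000.0)
        tail = pops.p_c[pops.t > 3000.0].mean()
        assert tail == pytest.approx(0.5, abs=0.02)

    def test_population_conservation_every_step(self, toy_pool_transfer):
        total = toy_pool_transfer.p_site.sum(axis=1)
        assert np.max(np.abs(total - 1.0)) < 1e-8
        assert toy_pool_transfer.p_stay_a[0] == pytest.approx(1.0, abs=1e-12)

    def test_interpool_transfer_is_picosecond_scale(self, toy_pool_transfer):
        pops = toy_pool_transfer
        i100 = np.searchsorted(pops.t, 100.0)
        assert pops.p_c[i100] < 0.1
        k = 51
        smooth = np.convolve(pops.p_c, np.ones(k) / k, mode="valid")
        assert np.all(np.diff(smooth) > -1e-4)
        assert smooth[-1] > smooth[0]

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fx.pool_transfer([], 100.0)


class TestLinearResponse:
    def test_single_static_site_peaks_at_site_energy(self):
        sh = static_hamiltonian([15000.0], np.zeros((1, 1)), n_steps=1100)
        spec = fx.linear_response([sh], n_t=1024, apodization_fs=100.0)
        assert spec.omega[np.argmax(spec.intensity)] == pytest.approx(15000.0, abs=3.0)

    def test_peak_agrees_with_cumulant_route(self):
        # motional-narrowing Drude dimer: the two independent absorption
        # engines must place the bright exciton peak at the same position
        H = fx.ExcitonHamiltonian(
            labels=["CLA401", "CLA402"], E=[15000.0, 15000.0],
            J=[[0.0, 100.0], [100.0, 0.0]],
            mu=np.array([[4.0, 0, 0], [4.0, 0, 0]]),
            pools={"CLA401": "a", "CLA402": "a"},
        )
        sd = fx.drude_sd(10.0, 100.0, GRID)
        cum = fx.absorption_cumulant(H, [sd, sd], 300.0)
        ens = fx.make_ensemble(H, {"a": sd}, 300.0, 200, 1600, dt=1.0, seed=5)
        nise = fx.linear_response(ens, n_t=1024)
        peak_c = cum.omega[np.argmax(cum.intensity)]
        peak_n = nise.omega[np.argmax(nise.intensity)]
        assert abs(peak_c - peak_n) < 20.0

    def test_same_seed_deterministic(self, toy_network, site_sds):
        _, H = toy_network
        a = fx.linear_response(
            fx.make_ensemble(H, site_sds, 300.0, 2, 300, seed=4), n_t=256
        )
        b = fx.linear_response(
            fx.make_ensemble(H, site_sds, 300.0, 2, 300, seed=4), n_t=256
        )
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestResponse2D:
    def test_single_site_positive_diagonal_no_esa(self):
        sh = static_hamiltonian([15000.0], np.zeros((1, 1)), n_steps=200)
        s = fx.response_2d([sh], n_t1=64, n_t3=64, t2_list=[0.0])
        sig = s.signal[0]
        i3, i1 = np.unravel_index(np.argmax(np.abs(sig)), sig.shape)
        assert sig[i3, i1] > 0
        assert abs(s.w1[i1] - 15000.0) < 60.0 and abs(s.w3[i3] - 15000.0) < 60.0
        assert np.all(s.components[0]["esa"] == 0.0)

    def test_uncoupled_sites_reduce_to_sum_of_singles(self):
        # with J = 0 the GSB/SE cross terms cancel the ESA exactly, leaving
        # the sum of isolated single-site responses
        grids = dict(
            w1_grid=np.arange(14300.0, 16200.0, 25.0),
            w3_grid=np.arange(14300.0, 16200.0, 25.0),
        )
        sh = static_hamiltonian(
            [14800.0, 15600.0], np.zeros((2, 2)),
            mu=[[4.0, 0, 0], [2.0, 1.0, 0]], n_steps=250,
        )
        pair = fx.response_2d([sh], n_t1=96, n_t3=96, t2_list=[0.0], **grids)
        acc = np.zeros_like(pair.signal[0])
        for i in range(2):
            shi = static_hamiltonian(
                [sh.base.E[i]], np.zeros((1, 1)), mu=[sh.base.mu[i]], n_steps=250
            )
            acc += fx.response_2d([shi], n_t1=96, n_t3=96, t2_list=[0.0], **grids).signal[0]
        residual = np.max(np.abs(pair.signal[0] - acc))
        assert residual < 1e-8 * np.max(np.abs(pair.signal[0]))

    def test_coupled_dimer_cross_peaks_and_esa_shift(self):
        # eigenbasis stick oracle: excitons at E+-sqrt(d^2/4+J^2) about the
        # mean; the ESA detection peak from the lower exciton appears at
        # E2f - E1 (two-exciton state minus exciton), displaced by the
        # coupling-induced shift
        E1, E2, J = 14800.0, 15400.0, 150.0
        sh = static_hamiltonian(
            [E1, E2], [[0.0, J], [J, 0.0]], mu=[[4.0, 0, 0], [3.0, 1.0, 0]],
            n_steps=300,
        )
        grids = dict(
            w1_grid=np.arange(14200.0, 16200.0, 10.0),
            w3_grid=np.arange(14200.0, 16200.0, 10.0),
        )
        s = fx.response_2d([sh], n_t1=128, n_t3=128, t2_list=[0.0], **grids)
        evals = np.linalg.eigvalsh(sh.base.matrix())
        e_f = E1 + E2  # hard-core pair state (J only couples shared-site pairs)
        sig = s.signal[0]
        m1_low = np.abs(s.w1 - evals[0]) < 40.0
        m3_high = np.abs(s.w3 - evals[1]) < 40.0
        cross = np.abs(sig[np.ix_(m3_high, m1_low)]).max()
        assert cross > 0.02 * np.abs(sig).max()  # cross peak present
        esa = s.components[0]["esa"]
        # ESA from the lower exciton detects at e_f - evals[0]
        m3_esa = np.abs(s.w3 - (e_f - evals[0])) < 40.0
        band = np.abs(esa[np.ix_(m3_esa, m1_low)]).max()
        assert band > 0.5 * np.abs(esa[:, m1_low]).max()

    def test_same_seed_bit_identical(self, toy_network, site_sds):
        _, H = toy_network
        runs = []
        for _ in range(2):
            ens = fx.make_ensemble(H, site_sds, 300.0, 2, 100, seed=13)
            runs.append(
                fx.response_2d(
                    ens, n_t1=32, n_t3=32, t2_list=[0.0],
                    w1_grid=np.arange(14000.0, 16000.0, 50.0),
                    w3_grid=np.arange(14000.0, 16000.0, 50.0),
                ).signal[0]
            )
        np.testing.assert_array_equal(runs[0], runs[1])


class TestDiagonalTrace:
    def test_normalized_to_one_at_t2_zero(self, toy_2des):
        trace = fx.diagonal_trace(toy_2des, (14800.0, 15000.0))
        assert trace[0] == 1.0

    def test_region_outside_grid_rejected(self, toy_2des):
        with pytest.raises(ValueError, match="region"):
            fx.diagonal_trace(toy_2des, (30000.0, 31000.0))

    def test_vibronic_region_decays_much_faster_than_main(self, toy_2des):
        main = fx.diagonal_trace(toy_2des, (14800.0, 15000.0))
        vib = fx.diagonal_trace(toy_2des, (16100.0, 16400.0))
        # strong high-frequency Chl-a modes dephase the vibronic diagonal
        # feature within tens of fs while the main peak barely moves
        assert vib[1] < 0.6
        assert main[1] > 0.8
        assert vib[1] < main[1] - 0.2


class TestForster:
    def _lorentzian(self, center, fwhm, grid):
        gamma = fwhm / 2.0
        lor = gamma / np.pi / ((grid - center) ** 2 + gamma**2)
        return fx.Spectrum(omega=grid, intensity=lor / np.trapezoid(lor, grid))

    def test_zero_overlap_gives_infinite_time(self):
        grid = np.arange(12000.0, 18000.0, 1.0)
        d = self._lorentzian(13000.0, 100.0, grid[:2000])
        a = self._lorentzian(17500.0, 100.0, grid[-2000:])
        t, rate = fx.forster_transfer_time(25.0, d, a)
        assert np.isinf(t) and rate == 0.0

    def test_identical_lorentzians_closed_form(self):
        # overlap of two identical unit-area Lorentzians of FWHM G is
        # 1/(pi G); the wide grid keeps tail-truncation renormalization
        # below the 2% comparison level
        grid = np.arange(0.0, 60000.0, 0.5)
        fwhm, J = 300.0, 25.0
        d = self._lorentzian(30000.0, fwhm, grid)
        t_ps, rate = fx.forster_transfer_time(J, d, d)
        expected_rate = 2.0 * np.pi * TWO_PI_C * J**2 / (np.pi * fwhm)
        assert rate == pytest.approx(expected_rate, rel=0.02)
        assert t_ps == pytest.approx(1.0 / expected_rate / 1000.0, rel=0.02)

    def test_doubling_coupling_quarters_time(self):
        grid = np.arange(10000.0, 20000.0, 0.5)
        d = self._lorentzian(15000.0, 300.0, grid)
        t1, _ = fx.forster_transfer_time(25.0, d, d)
        t2, _ = fx.forster_transfer_time(50.0, d, d)
        assert t1 / t2 == pytest.approx(4.0, rel=1e-9)

    def test_unnormalized_lineshape_rejected(self):
        grid = np.arange(10000.0, 20000.0, 0.5)
        d = self._lorentzian(15000.0, 300.0, grid)
        bad = fx.Spectrum(omega=grid, intensity=2.0 * d.intensity)
        with pytest.raises(ValueError, match="normalized"):
            fx.forster_transfer_time(25.0, d, bad)
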