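"""Pigment loading, couplings, ladders, and exciton manifolds."""

import numpy as np
import pytest
import scipy.constants as sc
from hypothesis import given, settings
from hypothesis import strategies as st

import fcpexciton as fx
from fcpexciton.constants import DIPOLE_COUPLING_CM
from fcpexciton.pigments import Pigment, PigmentType


def _pig(center, mu, label="CLA401", ptype=PigmentType.chl_a):
    return Pigment(label, ptype, {"MG": np.asarray(center, float)}, mu=mu)


class TestLoadPigments:
    def test_single_residue_roundtrip(self, tmp_path, square_ring_pigment):
        path = tmp_path / "one.pdb"
        fx.write_network_pdb([square_ring_pigment], path)
        pigments = fx.load_pigments(path)
        assert len(pigments) == 1
        assert pigments[0].ptype is PigmentType.chl_c2
        assert pigments[0].has_ring_atoms()
        np.testing.assert_allclose(pigments[0].atoms["NA"], [0.0, 2.0, 0.0], atol=1e-3)

    def test_nine_pigment_network_pools(self, tmp_path, toy_network):
        pigments, _ = toy_network
        path = tmp_path / "net.pdb"
        fx.write_network_pdb(pigments, path)
        loaded = fx.load_pigments(path, ptype_overrides={408: PigmentType.chl_c1})
        assert len(loaded) == 9
        pools = [p.ptype.pool for p in loaded]
        assert pools.count("a") == 7 and pools.count("c") == 2
        assert any(p.ptype is PigmentType.chl_c1 for p in loaded)

    def test_zero_matches_is_error(self, tmp_path, square_ring_pigment):
        path = tmp_path / "one.pdb"
        fx.write_network_pdb([square_ring_pigment], path)
        with pytest.raises(ValueError, match="zero matches"):
            fx.load_pigments(path, resname_map={"XYZ": PigmentType.chl_a})


class TestPointDipoleCoupling:
    def test_orthogonal_orientation_factor_vanishes(self):
        p1 = _pig([0, 0, 0], [0, 1, 0])
        p2 = _pig([10, 0, 0], [0, 0, 1], "CLA402")
        assert fx.point_dipole_coupling(p1, p2) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_head_to_tail_kappa(self):
        p1 = _pig([0, 0, 0], [1, 0, 0])
        p2 = _pig([10, 0, 0], [1, 0, 0], "CLA402")
        v = fx.point_dipole_coupling(p1, p2)
        assert v == pytest.approx(-2.0 * DIPOLE_COUPLING_CM / 1000.0, rel=1e-12)

    def test_prefactor_against_codata_oracle(self):
        # independent derivation of f from scipy.constants
        debye = 1e-21 / sc.c  # C m
        joule = debye**2 / (4 * np.pi * sc.epsilon_0 * (1e-10) ** 3)
        f = joule / (sc.h * sc.c * 100.0)
        p1 = _pig([0, 0, 0], [0, 1, 0])
        p2 = _pig([10, 0, 0], [0, 1, 0], "CLA402")
        assert fx.point_dipole_coupling(p1, p2) == pytest.approx(f / 1000.0, rel=1e-6)
        assert f == pytest.approx(5034.1, rel=1e-3)

    def test_symmetry_and_r3_decay(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            c1, c2 = rng.normal(size=3) * 5, rng.normal(size=3) * 5 + 15
            m1, m2 = rng.normal(size=3), rng.normal(size=3)
            p1, p2 = _pig(c1, m1), _pig(c2, m2, "CLA402")
            v12 = fx.point_dipole_coupling(p1, p2)
            assert v12 == pytest.approx(fx.point_dipole_coupling(p2, p1), rel=1e-12)
            # doubling the separation about the midpoint divides V by 8
            mid = (c1 + c2) / 2
            p1b, p2b = _pig(mid + 2 * (c1 - mid), m1), _pig(mid + 2 * (c2 - mid), m2, "CLA402")
            assert fx.point_dipole_coupling(p1b, p2b) == pytest.approx(v12 / 8.0, rel=1e-9)

    def test_zero_separation_is_error(self):
        p1 = _pig([0, 0, 0], [0, 1, 0])
        p2 = _pig([0, 0, 0], [0, 1, 0], "CLA402")
        with pytest.raises(ValueError):
            fx.point_dipole_coupling(p1, p2)


class TestEnergyLadder:
    def test_reference_gas_phase_ordering(self):
        # high-level gas-phase energies put Chl-a lowest, then c2, then c1
        ladder = fx.energy_ladder([1.910, 2.023, 1.987], ["chl_a", "chl_c1", "chl_c2"])
        assert [lab for lab, _, _ in ladder] == ["chl_a", "chl_c2", "chl_c1"]
        assert [r for _, _, r in ladder] == [1, 2, 3]

    def test_tie_break_by_label(self):
        ladder = fx.energy_ladder([1.0, 1.0, 1.0], ["b", "a", "c"])
        assert [lab for lab, _, _ in ladder] == ["a", "b", "c"]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-1e4, max_value=1e4, allow_nan=False),
            min_size=1,
            max_size=12,
        )
    )
    def test_ladder_preserves_energy_multiset(self, energies):
        labels = [f"P{i:02d}" for i in range(len(energies))]
        ladder = fx.energy_ladder(energies, labels)
        assert sorted(v for _, v, _ in ladder) == sorted(energies)
        assert sorted(lab for lab, _, _ in ladder) == labels
        assert [r for _, _, r in ladder] == list(range(1, len(energies) + 1))
        values = [v for _, v, _ in ladder]
        assert values == sorted(values)

    def test_matches_sort_oracle_and_is_permutation(self):
        rng = np.random.default_rng(11)
        e = rng.normal(15000, 200, size=12)
        labels = [f"P{i:02d}" for i in range(12)]
        ladder = fx.energy_ladder(e, labels)
        assert [v for _, v, _ in ladder] == sorted(e)
        assert sorted(lab for lab, _, _ in ladder) == sorted(labels)


class TestDiagonalize:
    def test_uncoupled_sorted(self):
        H = fx.ExcitonHamiltonian(
            labels=["CLA401", "CLA402"], E=[200.0, 100.0], J=np.zeros((2, 2)),
            mu=np.array([[1, 0, 0], [0, 1, 0.0]]),
        )
        st = fx.diagonalize(H)
        np.testing.assert_allclose(st.energies, [100.0, 200.0])
        assert np.allclose(np.abs(st.coeffs), np.eye(2)[:, ::-1])

    def test_resonant_dimer_splitting(self):
        H = fx.ExcitonHamiltonian(
            labels=["CLA401", "CLA402"], E=[0.0, 0.0],
            J=[[0.0, 100.0], [100.0, 0.0]], mu=np.array([[1, 0, 0], [1, 0, 0.0]]),
        )
        st = fx.diagonalize(H)
        np.testing.assert_allclose(st.energies, [-100.0, 100.0], atol=1e-10)

    def test_random_network_reconstruction_and_dipoles(self, toy_network):
        _, H = toy_network
        st = fx.diagonalize(H)
        # reconstruction H = C diag(E) C^T
        rebuilt = st.coeffs @ np.diag(st.energies) @ st.coeffs.T
        assert np.max(np.abs(rebuilt - H.matrix())) < 1e-6
        np.testing.assert_allclose(st.dipoles, st.coeffs.T @ H.mu)
        # independent eigen-oracle
        ref = np.sort(np.linalg.eigvalsh(H.matrix()))
        np.testing.assert_allclose(st.energies, ref, atol=1e-8)


class TestMaxInterpoolCoupling:
    def test_zero_couplings(self):
        H = fx.ExcitonHamiltonian(
            labels=["CLA401", "CLC402"], E=[0.0, 0.0], J=np.zeros((2, 2)),
            mu=np.zeros((2, 3)),
        )
        v, _ = fx.max_interpool_coupling(H)
        assert v == 0.0

    def test_hand_built_pair(self):
        J = np.zeros((3, 3))
        J[0, 2] = J[2, 0] = -25.0
        H = fx.ExcitonHamiltonian(
            labels=["CLA401", "CLA402", "CLC403"], E=np.zeros(3), J=J, mu=np.zeros((3, 3)),
        )
        v, pair = fx.max_interpool_coupling(H)
        assert v == 25.0 and pair == ("CLA401", "CLC403")

    def test_matches_exhaustive_scan(self, toy_network):
        _, H = toy_network
        v, pair = fx.max_interpool_coupling(H)
        a = H.pool_sites("a")
        c = H.pool_sites("c")
        brute = max(abs(H.J[i, j]) for i in a for j in c)
        assert v == pytest.approx(brute, rel=1e-12)

    def test_overlapping_pools_rejected(self, toy_network):
        _, H = toy_network
        with pytest.raises(ValueError, match="overlap"):
            fx.max_interpool_coupling(H, ["CLA401"], ["CLA401", "CLC403"])


class TestTwoExcitonExpand:
    def test_two_sites_single_pair(self):
        H = fx.ExcitonHamiltonian(
            labels=["CLA401", "CLA402"], E=[100.0, 250.0],
            J=[[0.0, 30.0], [30.0, 0.0]], mu=np.array([[1, 0, 0], [0, 1, 0.0]]),
        )
        man = fx.two_exciton_expand(H)
        assert man.pairs == [(0, 1)]
        np.testing.assert_allclose(man.H2, [[350.0]])

    def test_uncoupled_triple_is_diagonal_pairwise_sums(self):
        E = np.array([10.0, 20.0, 40.0])
        H = fx.ExcitonHamiltonian(
            labels=["CLA401", "CLA402", "CLA403"], E=E, J=np.zeros((3, 3)),
            mu=np.zeros((3, 3)),
        )
        man = fx.two_exciton_expand(H)
        expected = np.diag([30.0, 50.0, 60.0])
        np.testing.assert_allclose(man.H2, expected)
        # J = 0: eigenvalues are exactly the pairwise sums
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(man.H2)), [30, 50, 60])

    def test_matches_index_loop_oracle(self):
        rng = np.random.default_rng(5)
        n = 4
        J = rng.normal(scale=20, size=(n, n))
        J = 0.5 * (J + J.T)
        np.fill_diagonal(J, 0.0)
        E = rng.normal(15000, 100, size=n)
        H = fx.ExcitonHamiltonian(
            labels=[f"CLA{401 + i}" for i in range(n)], E=E, J=J,
            mu=rng.normal(size=(n, 3)),
        )
        man = fx.two_exciton_expand(H)
        for p, (i, j) in enumerate(man.pairs):
            for q, (k, l) in enumerate(man.pairs):
                if p == q:
                    expected = E[i] + E[j]
                elif len({i, j} & {k, l}) == 1:
                    (s,) = {i, j} & {k, l}
                    a = i if j == s else j
                    b = k if l == s else l
                    expected = J[a, b]
                else:
                    expected = 0.0
                assert man.H2[p, q] == pytest.approx(expected, abs=1e-12)
        # one->two dipole nonzero only when the site belongs to the pair
        for p, (i, j) in enumerate(man.pairs):
            for s in range(n):
                if s == i:
                    np.testing.assert_allclose(man.mu_up[p, s], H.mu[j])
                elif s == j:
                    np.testing.assert_allclose(man.mu_up[p, s], H.mu[i])
                else:
                    np.testing.assert_allclose(man.mu_up[p, s], 0.0)

    def test_single_site_rejected(self):
        H = fx.ExcitonHamiltonian(
            labels=["CLA401"], E=[0.0], J=[[0.0]], mu=np.zeros((1, 3)),
        )
        with pytest.raises(ValueError):
            fx.two_exciton_expand(H)


def test_asymmetric_coupling_rejected():
    with pytest.raises(ValueError, match="symmetric"):
        fx.ExcitonHamiltonian(
            labels=["CLA401", "CLA402"], E=[0.0, 0.0],
            J=[[0.0, 10.0], [10.1, 0.0]], mu=np.zeros((2, 3)),
        )
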