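"""Synthetic FCP-like inputs: networks, charge shells, trajectory ensembles.

The study conditions this package targets — nine chlorophylls (seven Chl-a,
two Chl-c) with inter-pool couplings of at most ~25 cm^-1, Chl-c dipoles
weaker than Chl-a, Drude-plus-intramolecular-mode baths with the
high-frequency modes much stronger for Chl-a — are encoded here as
generator defaults, so every downstream module can be exercised without
structure downloads or electronic-structure input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bath import SpectralDensity, Trajectory, drude_sd, sample_trajectory, underdamped_sd
from .constants import BOHR_ANG, TWO_PI_C
from .fields import ChargeEnvironment, coulomb_field
from .nise import StochasticHamiltonian
from .pigments import (
    ExcitonHamiltonian,
    Pigment,
    PigmentType,
    point_dipole_coupling,
)

__all__ = [
    "NetworkSpec",
    "make_network",
    "make_environment",
    "make_ensemble",
    "dimer_fixture",
    "default_site_sds",
    "write_network_pdb",
    "DEFAULT_LABELS",
]

#: residue-style labels of the nine-chlorophyll FCP monomer network
#: (CLC403 is the Chl-c2 site, CLC408 the Chl-c1 site)
DEFAULT_LABELS = [
    "CLA401",
    "CLA402",
    "CLC403",
    "CLA404",
    "CLA405",
    "CLA407",
    "CLC408",
    "CLA409",
    "CLA410",
]


@dataclass
class NetworkSpec:
    """Parameters of a synthetic chlorophyll network.

    Defaults emulate the FCP monomer: 7 Chl-a sites around 14950 cm^-1 and
    2 red-shifted Chl-c sites around 14600 cm^-1 (the Chl-c2 site lowest,
    as in the protein energy ladder), Chl-c dipoles 0.6x the Chl-a ones,
    couplings of at most tens of cm^-1 with the largest a-c coupling
    clamped to 25 cm^-1.
    """

    n_a: int = 7
    n_c: int = 2
    e_mean_a: float = 14950.0
    e_spread_a: float = 80.0
    e_mean_c: float = 14600.0
    e_spread_c: float = 80.0
    coupling_scale: float = 60.0
    interpool_max: float = 25.0
    dipole_a: float = 4.0
    dipole_c: float = 2.4
    min_distance: float = 8.0
    box: float = 35.0

    def __post_init__(self) -> None:
        if self.n_a < 0 or self.n_c < 0:
            raise ValueError("pigment counts must be nonnegative")
        if self.coupling_scale < 0 or self.interpool_max < 0:
            raise ValueError("coupling scales must be nonnegative")


def _labels_for(spec: NetworkSpec) -> list[tuple[str, PigmentType]]:
    if spec.n_a == 7 and spec.n_c == 2:
        out = []
        for lab in DEFAULT_LABELS:
            if lab == "CLC403":
                out.append((lab, PigmentType.chl_c2))
            elif lab == "CLC408":
                out.append((lab, PigmentType.chl_c1))
            else:
                out.append((lab, PigmentType.chl_a))
        return out
    out = [(f"CLA{401 + i}", PigmentType.chl_a) for i in range(spec.n_a)]
    out += [
        (f"CLC{401 + spec.n_a + i}", PigmentType.chl_c2) for i in range(spec.n_c)
    ]
    return out


def _place_centers(rng: np.random.Generator, count: int, spec: NetworkSpec) -> np.ndarray:
    centers: list[np.ndarray] = []
    for _ in range(count):
        for _attempt in range(4000):
            cand = rng.uniform(0.0, spec.box, size=3)
            if all(np.linalg.norm(cand - c) >= spec.min_distance for c in centers):
                centers.append(cand)
                break
        else:
            raise RuntimeError(
                f"impossible packing: cannot place {count} pigments with "
                f"{spec.min_distance} A spacing in a {spec.box} A box"
            )
    return np.array(centers)


def _ring_atoms(center: np.ndarray, y_axis: np.ndarray, normal: np.ndarray) -> dict:
    """Planar MG/NA..ND arrangement with NA on +y and ND->NA->NB... CCW."""
    x_axis = np.cross(y_axis, normal)
    r = 2.05  # Mg-N distance scale, Angstrom
    return {
        "MG": center.copy(),
        "NA": center + r * y_axis,
        "NB": center - r * x_axis,
        "NC": center - r * y_axis,
        "ND": center + r * x_axis,
    }


def make_network(
    spec: NetworkSpec | None = None, seed: int = 0
) -> tuple[list[Pigment], ExcitonHamiltonian]:
    """Generate a random pigment network and its exciton Hamiltonian.

    Centers are placed with a minimum spacing, dipole orientations are
    random, couplings come from the point-dipole formula, and the inter-pool
    block is rescaled so its largest coupling equals ``spec.interpool_max``
    exactly (intra-pool couplings are rescaled if they exceed
    ``spec.coupling_scale``).  Deterministic per seed.
    """
    spec = spec or NetworkSpec()
    rng = np.random.default_rng(seed)
    named = _labels_for(spec)
    count = len(named)
    if count == 0:
        raise ValueError("network must contain at least one pigment")
    centers = _place_centers(rng, count, spec)
    pigments: list[Pigment] = []
    energies = np.empty(count)
    for i, (label, ptype) in enumerate(named):
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        helper = rng.normal(size=3)
        y_axis = helper - (helper @ normal) * normal
        y_axis /= np.linalg.norm(y_axis)
        mag = spec.dipole_a if ptype is PigmentType.chl_a else spec.dipole_c
        atoms = _ring_atoms(centers[i], y_axis, normal)
        pigments.append(
            Pigment(label=label, ptype=ptype, atoms=atoms, mu=mag * y_axis)
        )
        if ptype is PigmentType.chl_a:
            energies[i] = rng.normal(spec.e_mean_a, spec.e_spread_a)
        else:
            energies[i] = rng.normal(spec.e_mean_c, spec.e_spread_c)
    # make the c2 site the red-most pigment, as in the protein energy ladder
    c2 = [i for i, (_, t) in enumerate(named) if t is PigmentType.chl_c2]
    if c2 and count > 1:
        lowest = int(np.argmin(energies))
        if lowest not in c2:
            energies[c2[0]], energies[lowest] = energies[lowest], energies[c2[0]]

    J = np.zeros((count, count))
    for i in range(count):
        for j in range(i + 1, count):
            J[i, j] = J[j, i] = point_dipole_coupling(pigments[i], pigments[j])
    pools = np.array([t.pool for _, t in named])
    inter = (pools[:, None] == "a") & (pools[None, :] == "c")
    inter = inter | inter.T
    intra = ~inter
    np.fill_diagonal(intra, False)
    if np.any(intra) and np.max(np.abs(J[intra])) > spec.coupling_scale > 0:
        J[intra] *= spec.coupling_scale / np.max(np.abs(J[intra]))
    if np.any(inter) and np.max(np.abs(J[inter])) > 0 and spec.interpool_max > 0:
        J[inter] *= spec.interpool_max / np.max(np.abs(J[inter]))

    H = ExcitonHamiltonian(
        labels=[lab for lab, _ in named],
        E=energies,
        J=J,
        mu=np.array([p.mu for p in pigments]),
        pools={lab: t.pool for lab, t in named},
    )
    return pigments, H


def write_network_pdb(pigments: list[Pigment], path) -> None:
    """Write the ring atoms of a synthetic network as a standard PDB file."""
    resname = {
        PigmentType.chl_a: "CLA",
        PigmentType.chl_c1: "CLC",
        PigmentType.chl_c2: "CLC",
    }
    lines = []
    serial = 1
    for res_i, p in enumerate(pigments, start=1):
        rn = resname[p.ptype]
        num = "".join(ch for ch in p.label if ch.isdigit()) or str(400 + res_i)
        for name, xyz in p.atoms.items():
            element = "MG" if name == "MG" else name[0]
            lines.append(
                f"HETATM{serial:5d} {name:<4s} {rn:<3s} A{int(num):4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def make_environment(
    target: np.ndarray,
    probe: np.ndarray,
    seed: int = 0,
    n_decoys: int = 12,
    corrector_distance: float = 6.0,
) -> ChargeEnvironment:
    """Charge shell producing a prescribed field at a probe point.

    Decoy charges are scattered around the probe (seeded); one corrector
    charge placed along the residual-field direction cancels their
    contribution and supplies the target field exactly (verified against
    :func:`coulomb_field` to well under 1e-6 au).
    """
    target = np.asarray(target, dtype=float)
    probe = np.asarray(probe, dtype=float)
    if np.linalg.norm(target) <= 0.0:
        raise ValueError("target field must be nonzero")
    rng = np.random.default_rng(seed)
    positions = []
    charges = []
    for _ in range(n_decoys):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        positions.append(probe + direction * rng.uniform(8.0, 20.0))
        charges.append(rng.uniform(-0.5, 0.5))
    env = ChargeEnvironment(np.array(charges), np.array(positions))
    residual = target - coulomb_field(env, probe[None, :])[0]
    direction = residual / np.linalg.norm(residual)
    s_bohr = corrector_distance / BOHR_ANG
    q = float(np.linalg.norm(residual) * s_bohr**2)
    positions.append(probe - direction * corrector_distance)
    charges.append(q)
    return ChargeEnvironment(np.array(charges), np.array(positions))


def default_site_sds(
    grid: np.ndarray | None = None,
    drude_lambda: float = 40.0,
    drude_gamma: float = 40.0,
    modes: tuple = ((750.0, 30.0, 20.0), (1150.0, 45.0, 20.0), (1520.0, 35.0, 20.0)),
    c_mode_factor: float = 0.3,
) -> dict[str, SpectralDensity]:
    """Default Chl-a / Chl-c spectral densities of the synthetic network.

    Both pools share a Drude background (lambda = gamma = 40 cm^-1); the
    underdamped intramolecular modes ``(omega0, lambda, gamma)`` are at full
    strength for Chl-a and scaled by ``c_mode_factor`` for Chl-c, so the
    vibronic sideband of the absorption spectrum is carried by the Chl-a
    pool.  Returns ``{"a": sd, "c": sd}``.
    """
    if grid is None:
        grid = np.arange(0.5, 2200.0, 0.5)
    sd_a = drude_sd(drude_lambda, drude_gamma, grid)
    sd_c = drude_sd(drude_lambda, drude_gamma, grid)
    for omega0, lam, gamma in modes:
        sd_a = sd_a + underdamped_sd(lam, omega0, gamma, grid)
        sd_c = sd_c + underdamped_sd(lam * c_mode_factor, omega0, gamma, grid)
    return {"a": sd_a, "c": sd_c}


def make_ensemble(
    H: ExcitonHamiltonian,
    sds: dict[str, SpectralDensity],
    temperature: float,
    n_real: int,
    n_steps: int,
    dt: float = 2.0,
    seed: int = 0,
) -> list[StochasticHamiltonian]:
    """Seeded ensemble of stochastic Hamiltonians for NISE averaging.

    Each realization draws independent per-site gap trajectories from the
    pool-resolved spectral densities; all randomness derives from one
    master seed.
    """
    if n_real < 0:
        raise ValueError("n_real must be nonnegative")
    children = np.random.SeedSequence(seed).spawn(max(n_real, 1))
    ensemble = []
    for r in range(n_real):
        rng = np.random.default_rng(children[r])
        delta = np.empty((H.n, n_steps))
        for i, lab in enumerate(H.labels):
            sd = sds[H.pools[lab]]
            traj = sample_trajectory(sd, temperature, dt, n_steps, 1, rng)
            delta[i] = traj.delta[0]
        ensemble.append(
            StochasticHamiltonian(
                base=H,
                fluctuations=Trajectory(dt=dt, delta=delta, mean_energies=H.E.copy()),
            )
        )
    return ensemble


def dimer_fixture(delta: float, coupling: float) -> dict:
    """Analytic two-site oracle bundle.

    For site energies ``+-delta/2`` about the mean and coupling J the
    eigenvalues are ``+-sqrt(delta^2/4 + J^2)`` about the mean, the Rabi
    (full population-return) angular frequency is
    ``2 * 2 pi c * sqrt(delta^2/4 + J^2)``, and the transfer probability is

        P2(t) = J^2/(J^2 + delta^2/4) * sin^2(2 pi c sqrt(J^2+delta^2/4) t).

    The bundle self-verifies its eigenvalues against direct
    diagonalization at construction.
    """
    omega_r = np.sqrt(coupling**2 + delta**2 / 4.0)
    amp = coupling**2 / (coupling**2 + delta**2 / 4.0) if omega_r > 0 else 0.0
    h = np.array([[+delta / 2.0, coupling], [coupling, -delta / 2.0]])
    vals = np.linalg.eigvalsh(h)
    if not np.allclose(sorted(vals), [-omega_r, +omega_r], atol=1e-9):
        raise AssertionError("dimer fixture eigenvalue self-check failed")

    def population(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if omega_r == 0.0:
            return np.zeros_like(t)
        return amp * np.sin(TWO_PI_C * omega_r * t) ** 2

    period = np.inf if omega_r == 0.0 else 2.0 * np.pi / (TWO_PI_C * 2.0 * omega_r)
    return {
        "eigenvalues": (-omega_r, +omega_r),
        "splitting": 2.0 * omega_r,
        "transfer_amplitude": amp,
        "rabi_period_fs": period,
        "first_full_transfer_fs": (
            np.inf
            if (omega_r == 0.0 or amp < 1.0)
            else np.pi / (2.0 * TWO_PI_C * omega_r)
        ),
        "population": population,
    }
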