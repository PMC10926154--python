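"""Pigments and Frenkel exciton Hamiltonians for chlorophyll networks.

The FCP antenna of diatoms binds a small network of chlorophylls (seven
Chl-a and two Chl-c in the monomer studied here).  This module provides the
tight-binding ("exciton") description of such a network: per-pigment site
energies on the diagonal, excitonic couplings off the diagonal, transition
dipoles for the optical response, and the one- and two-exciton manifolds
needed for linear and third-order spectroscopy.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import DIPOLE_COUPLING_CM

__all__ = [
    "PigmentType",
    "Pigment",
    "ExcitonHamiltonian",
    "ExcitonStates",
    "TwoExcitonManifold",
    "load_pigments",
    "point_dipole_coupling",
    "energy_ladder",
    "diagonalize",
    "max_interpool_coupling",
    "two_exciton_expand",
]

#: ring atoms expected for frame construction
RING_ATOMS = ("MG", "NA", "NB", "NC", "ND")


class PigmentType(enum.Enum):
    """Chemical identity of a chlorophyll pigment."""

    chl_a = "chl_a"
    chl_c1 = "chl_c1"
    chl_c2 = "chl_c2"

    @property
    def pool(self) -> str:
        """Spectroscopic pool: ``"a"`` for Chl-a, ``"c"`` for Chl-c1/c2."""
        return "a" if self is PigmentType.chl_a else "c"


@dataclass
class Pigment:
    """One chromophore: labelled atoms, transition dipole, geometric center.

    Parameters
    ----------
    label
        Residue-style label, e.g. ``"CLA409"`` or ``"CLC403"``.
    ptype
        Chemical identity (`PigmentType`).
    atoms
        Map atom name -> coordinate (Angstrom).  ``MG`` and the four ring
        nitrogens ``NA``..``ND`` must be present for frame construction.
    mu
        Transition-dipole vector in Debye.
    center
        Optional explicit center (Angstrom); defaults to the MG position.
    """

    label: str
    ptype: PigmentType
    atoms: dict[str, np.ndarray]
    mu: np.ndarray
    center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}
        self.mu = np.asarray(self.mu, dtype=float)
        for name, xyz in self.atoms.items():
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"{self.label}: non-finite coordinate for {name}")
        if self.center is None and "MG" in self.atoms:
            self.center = self.atoms["MG"].copy()
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=float)

    def has_ring_atoms(self) -> bool:
        return all(a in self.atoms for a in RING_ATOMS)

    def ring_coords(self) -> np.ndarray:
        """Coordinates of MG, NA..ND (5 x 3), in that order."""
        if not self.has_ring_atoms():
            missing = [a for a in RING_ATOMS if a not in self.atoms]
            raise ValueError(f"{self.label}: missing ring atoms {missing}")
        return np.array([self.atoms[a] for a in RING_ATOMS])


@dataclass
class ExcitonHamiltonian:
    """Site energies, couplings, dipoles and pool assignment of a network.

    ``E`` holds the diagonal (site energies, cm^-1), ``J`` the symmetric
    coupling matrix with exact zero diagonal (cm^-1), ``mu`` the n x 3
    transition dipoles (Debye) and ``pools`` maps each label onto the
    ``"a"`` / ``"c"`` pigment pool.
    """

    labels: list[str]
    E: np.ndarray
    J: np.ndarray
    mu: np.ndarray
    pools: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        n = len(self.labels)
        if self.E.shape != (n,) or self.J.shape != (n, n) or self.mu.shape != (n, 3):
            raise ValueError("inconsistent Hamiltonian dimensions")
        if not np.all(np.isfinite(self.E)) or not np.all(np.isfinite(self.J)):
            raise ValueError("non-finite Hamiltonian entries")
        if np.max(np.abs(self.J - self.J.T)) > 1e-9:
            raise ValueError("coupling matrix not symmetric within 1e-9 cm^-1")
        self.J = 0.5 * (self.J + self.J.T)
        np.fill_diagonal(self.J, 0.0)
        if not self.pools:
            self.pools = {
                lab: ("a" if lab.startswith("CLA") else "c") for lab in self.labels
            }

    @property
    def n(self) -> int:
        return len(self.labels)

    def matrix(self) -> np.ndarray:
        """Full Hamiltonian matrix diag(E) + J (cm^-1)."""
        return np.diag(self.E) + self.J

    def pool_sites(self, pool: str) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if self.pools[lab] == pool]

    def subsystem(self, sites: list[int]) -> "ExcitonHamiltonian":
        """Restriction of the network to the given site indices."""
        idx = np.asarray(sites, dtype=int)
        labels = [self.labels[i] for i in idx]
        return ExcitonHamiltonian(
            labels=labels,
            E=self.E[idx],
            J=self.J[np.ix_(idx, idx)],
            mu=self.mu[idx],
            pools={lab: self.pools[lab] for lab in labels},
        )


@dataclass
class ExcitonStates:
    """One-exciton eigenstates: energies ascending, coefficient columns."""

    energies: np.ndarray
    coeffs: np.ndarray  # column k = exciton k in the site basis
    dipoles: np.ndarray  # n x 3 exciton transition dipoles

    def __post_init__(self) -> None:
        gram = self.coeffs.T @ self.coeffs
        if np.max(np.abs(gram - np.eye(gram.shape[0]))) > 1e-8:
            raise ValueError("exciton coefficients not orthonormal")


@dataclass
class TwoExcitonManifold:
    """Hard-core two-exciton space spanned by site pairs (i < j).

    ``H2[(i,j),(i,j)] = E_i + E_j`` and pairs sharing one site couple through
    the one-exciton coupling of the differing sites.  No intra-site double
    excitation and no anharmonic shift — the standard hard-core boson model
    for chlorophyll Q_y manifolds.
    """

    pairs: list[tuple[int, int]]
    H2: np.ndarray
    mu_up: np.ndarray  # m x n x 3: <pair| mu |site>

    @property
    def m(self) -> int:
        return len(self.pairs)

    def raising_operator(self, mu_comp: np.ndarray) -> np.ndarray:
        """One- to two-exciton transition operator for site amplitudes.

        ``mu_comp`` is a length-n vector of dipole components (one Cartesian
        direction).  Returns the m x n matrix ``T`` with
        ``(T v)_(jk) = mu_j v_k + mu_k v_j``.
        """
        n = mu_comp.shape[0]
        T = np.zeros((self.m, n))
        for p, (j, k) in enumerate(self.pairs):
            T[p, k] += mu_comp[j]
            T[p, j] += mu_comp[k]
        return T


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

#: default transition-dipole magnitude per pigment type (Debye)
DEFAULT_DIPOLE_D = {
    PigmentType.chl_a: 4.0,
    PigmentType.chl_c1: 2.4,
    PigmentType.chl_c2: 2.4,
}


def load_pigments(
    structure_path,
    resname_map: dict[str, PigmentType] | None = None,
    ptype_overrides: dict[int, PigmentType] | None = None,
    dipole_magnitudes: dict[PigmentType, float] | None = None,
) -> list[Pigment]:
    """Read chlorophyll pigments from a PDB file.

    Residues are selected by name through ``resname_map`` (default:
    ``CLA -> chl_a``, ``CLC -> chl_c2``; PDB residue names do not distinguish
    c1 from c2, so specific residues can be re-typed through
    ``ptype_overrides`` keyed by residue number).  The Q_y transition dipole
    is placed along the NC->NA axis with a per-type default magnitude.

    Raises ``ValueError`` on an unparseable file or when no residue matches.
    Pigments lacking ring atoms are loaded with a warning; frame construction
    for them fails later.
    """
    import gemmi

    resname_map = resname_map or {
        "CLA": PigmentType.chl_a,
        "CLC": PigmentType.chl_c2,
    }
    ptype_overrides = ptype_overrides or {}
    mags = dict(DEFAULT_DIPOLE_D)
    if dipole_magnitudes:
        mags.update(dipole_magnitudes)

    try:
        structure = gemmi.read_pdb(str(structure_path))
    except Exception as exc:  # pragma: no cover - gemmi error text varies
        raise ValueError(f"cannot parse PDB file {structure_path}: {exc}") from exc

    pigments: list[Pigment] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                if residue.name not in resname_map:
                    continue
                ptype = ptype_overrides.get(
                    residue.seqid.num, resname_map[residue.name]
                )
                atoms = {
                    at.name: np.array([at.pos.x, at.pos.y, at.pos.z])
                    for at in residue
                }
                label = f"{residue.name}{residue.seqid.num}"
                missing = [a for a in RING_ATOMS if a not in atoms]
                if missing:
                    warnings.warn(
                        f"pigment {label} lacks atoms {missing}; "
                        "ring-frame construction will not be possible",
                        stacklevel=2,
                    )
                    axis = np.array([0.0, 1.0, 0.0])
                else:
                    axis = atoms["NA"] - atoms["NC"]
                    axis = axis / np.linalg.norm(axis)
                mu = mags[ptype] * axis
                pigments.append(Pigment(label=label, ptype=ptype, atoms=atoms, mu=mu))
        break  # first model only
    if not pigments:
        raise ValueError("zero matches: no residue in the file matches the selection")
    return pigments


def point_dipole_coupling(p1: Pigment, p2: Pigment) -> float:
    """Excitonic coupling in the point-dipole approximation (cm^-1).

    ``V = f * kappa * |mu1||mu2| / R^3`` with
    ``kappa = mu1.mu2 - 3 (mu1.R)(mu2.R)`` for unit vectors and ``f`` the
    CODATA-derived dipole-dipole constant.  Symmetric in its arguments and
    decaying as R^-3.
    """
    r = np.asarray(p2.center, dtype=float) - np.asarray(p1.center, dtype=float)
    dist = np.linalg.norm(r)
    if dist < 1e-9:
        raise ValueError("pigment centers coincide; point-dipole coupling undefined")
    m1, m2 = np.linalg.norm(p1.mu), np.linalg.norm(p2.mu)
    if m1 == 0.0 or m2 == 0.0:
        return 0.0
    u1, u2, ur = p1.mu / m1, p2.mu / m2, r / dist
    kappa = u1 @ u2 - 3.0 * (u1 @ ur) * (u2 @ ur)
    return DIPOLE_COUPLING_CM * kappa * m1 * m2 / dist**3


def energy_ladder(E, labels) -> list[tuple[str, float, int]]:
    """Rank site energies ascending; ties broken by label.

    ``E`` may be a vector of energies or per-site trajectory samples (rows),
    in which case per-site means are ranked.  Returns ``(label, energy,
    rank)`` triples with rank starting at 1.
    """
    E = np.asarray(E, dtype=float)
    if E.ndim == 2:
        E = E.mean(axis=1)
    if not np.all(np.isfinite(E)):
        raise ValueError("non-finite energies")
    order = sorted(range(len(labels)), key=lambda i: (E[i], labels[i]))
    return [(labels[i], float(E[i]), rank + 1) for rank, i in enumerate(order)]


def diagonalize(H: ExcitonHamiltonian) -> ExcitonStates:
    """One-exciton eigenstates of the network (ascending energies)."""
    mat = H.matrix()
    if np.max(np.abs(mat - mat.T)) > 1e-9:
        raise ValueError("Hamiltonian not symmetric")
    energies, coeffs = np.linalg.eigh(mat)
    dipoles = coeffs.T @ H.mu
    return ExcitonStates(energies=energies, coeffs=coeffs, dipoles=dipoles)


def max_interpool_coupling(
    H: ExcitonHamiltonian,
    pool_a: list[str] | None = None,
    pool_b: list[str] | None = None,
) -> tuple[float, tuple[str, str]]:
    """Largest |J| between two disjoint pigment pools and the site pair.

    Defaults to the Chl-a vs Chl-c pools recorded in the Hamiltonian.
    """
    if pool_a is None or pool_b is None:
        pool_a = [lab for lab in H.labels if H.pools[lab] == "a"]
        pool_b = [lab for lab in H.labels if H.pools[lab] == "c"]
    if not pool_a or not pool_b:
        raise ValueError("both pools must be nonempty")
    if set(pool_a) & set(pool_b):
        raise ValueError("pools overlap")
    index = {lab: i for i, lab in enumerate(H.labels)}
    best, pair = 0.0, (pool_a[0], pool_b[0])
    for la in pool_a:
        for lb in pool_b:
            v = abs(H.J[index[la], index[lb]])
            if v > best:
                best, pair = v, (la, lb)
    return best, pair


def two_exciton_expand(H: ExcitonHamiltonian) -> TwoExcitonManifold:
    """Hard-core two-exciton manifold of the network.

    One-to-two transition dipoles are nonzero only when the one-exciton site
    belongs to the pair, and then equal the dipole of the added site.
    """
    n = H.n
    if n < 2:
        raise ValueError("two-exciton manifold requires at least 2 sites")
    pairs = list(itertools.combinations(range(n), 2))
    m = len(pairs)
    H2 = np.zeros((m, m))
    for p, (i, j) in enumerate(pairs):
        H2[p, p] = H.E[i] + H.E[j]
        for q in range(p + 1, m):
            k, l = pairs[q]
            shared = set((i, j)) & set((k, l))
            if len(shared) == 1:
                (s,) = shared
                a = i if j == s else j  # member of pair p besides the shared site
                b = k if l == s else l
                H2[p, q] = H2[q, p] = H.J[a, b]
    mu_up = np.zeros((m, n, 3))
    for p, (i, j) in enumerate(pairs):
        mu_up[p, i] = H.mu[j]
        mu_up[p, j] = H.mu[i]
    return TwoExcitonManifold(pairs=pairs, H2=H2, mu_up=mu_up)
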