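"""Electric fields at pigment atoms and Stark-response analysis.

The protein matrix of FCP creates directed electric fields at the bound
chlorophylls; Chl-c pigments respond to those fields far more strongly than
Chl-a.  This module covers the geometric and electrostatic side of that
analysis: rigid alignment of a pigment into a canonical ring frame, Coulomb
fields of a point-charge environment evaluated at the Mg/N probe atoms,
and the arithmetic on energy-vs-field scans (shifts, susceptibility ratios,
and a linear difference-dipole fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import BOHR_ANG
from .pigments import Pigment, RING_ATOMS

__all__ = [
    "ChargeEnvironment",
    "FieldReport",
    "FieldScan",
    "kabsch_align",
    "ring_frame",
    "coulomb_field",
    "field_report",
    "scan_shifts",
    "susceptibility_ratio",
    "difference_dipole_fit",
]

SCAN_DIRECTIONS = ("none", "+x", "-x", "+y", "-y", "+z", "-z")
_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass
class ChargeEnvironment:
    """Point charges (e) at positions (Angstrom)."""

    charges: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape != (self.charges.shape[0], 3):
            raise ValueError("positions must be k x 3 matching charges")
        if not (np.all(np.isfinite(self.charges)) and np.all(np.isfinite(self.positions))):
            raise ValueError("non-finite charge environment")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChargeEnvironment":
        """Environment after the rigid map ``r -> R r + t``."""
        return ChargeEnvironment(
            charges=self.charges.copy(),
            positions=self.positions @ np.asarray(rotation).T + np.asarray(translation),
        )


@dataclass
class FieldReport:
    """Per-probe-atom field components in atomic units, +y rows flagged."""

    atoms: list[str]
    fields: np.ndarray  # q x 3, e/a0^2
    flags: np.ndarray  # True where F_y > 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fields, columns=["Fx_au", "Fy_au", "Fz_au"])
        df.insert(0, "atom", self.atoms)
        df["positive_y"] = self.flags
        return df


@dataclass
class FieldScan:
    """Excitation energies (eV) per pigment and field direction.

    ``energies`` is a DataFrame indexed by direction (``none``, ``+x``, ...,
    ``-z``) with one column per pigment; ``field`` is the homogeneous field
    magnitude in atomic units.
    """

    energies: pd.DataFrame
    field: float

    def __post_init__(self) -> None:
        if "none" not in self.energies.index:
            raise ValueError("scan must contain the zero-field 'none' row")
        if not self.field > 0:
            raise ValueError("field magnitude must be positive")
        unknown = set(self.energies.index) - set(SCAN_DIRECTIONS)
        if unknown:
            raise ValueError(f"unknown scan directions: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# rigid alignment
# ---------------------------------------------------------------------------

def kabsch_align(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of paired point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to
    ``reference``; the rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching N x 3 arrays")
    if mobile.shape[0] < 3:
        raise ValueError("at least 3 paired points required")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    x, y = mobile - cm, reference - cr
    if np.linalg.matrix_rank(x, tol=1e-9) < 2:
        raise ValueError("collinear point set; rotation ill-defined")
    u, _, vt = np.linalg.svd(x.T @ y)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    rotation = (u @ diag @ vt).T
    translation = cr - rotation @ cm
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


def ring_frame(p: Pigment):
    """Rigid transform taking a pigment into its canonical ring frame.

    After the map ``r -> R (r - centroid_N)``, the best-fit plane of the
    ring nitrogens NA..ND has normal +z (sign fixed so NA->NB->NC->ND
    circulate counterclockwise seen from +z), the nitrogen centroid sits at
    the origin, and the in-plane y axis points along the NC->NA direction
    projected into the plane (the Q_y axis convention).  Returns
    ``(rotation, translation)`` for the map ``r -> R r + t``.
    """
    coords = p.ring_coords()
    nitro = coords[1:]  # NA, NB, NC, ND
    centroid = nitro.mean(axis=0)
    centered = nitro - centroid
    _, svals, vt = np.linalg.svd(centered)
    if svals[1] < 1e-8:
        raise ValueError(f"{p.label}: degenerate (collinear) ring nitrogens")
    normal = vt[2]
    # counterclockwise circulation of NA->NB->NC->ND seen from +normal
    circ = np.zeros(3)
    for i in range(4):
        circ += np.cross(centered[i], centered[(i + 1) % 4])
    if circ @ normal < 0:
        normal = -normal
    y_axis = centered[0] - centered[2]  # NC -> NA
    y_axis = y_axis - (y_axis @ normal) * normal
    norm = np.linalg.norm(y_axis)
    if norm < 1e-8:
        raise ValueError(f"{p.label}: NA-NC axis perpendicular to ring plane")
    y_axis /= norm
    x_axis = np.cross(y_axis, normal)
    rotation = np.vstack([x_axis, y_axis, normal])
    translation = -rotation @ centroid
    return rotation, translation


# ---------------------------------------------------------------------------
# Coulomb fields
# ---------------------------------------------------------------------------

def coulomb_field(env: ChargeEnvironment, points: np.ndarray) -> np.ndarray:
    """Electric field of the point charges at given points, atomic units.

    ``F(r) = sum_i q_i (r - r_i) / |r - r_i|^3`` with coordinates converted
    from Angstrom to bohr; superposition is exact.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rp = points[:, None, :] / BOHR_ANG
    rq = env.positions[None, :, :] / BOHR_ANG
    diff = rp - rq
    dist = np.linalg.norm(diff, axis=2)
    if np.any(dist * BOHR_ANG < 1e-6):
        raise ValueError("evaluation point coincides with a charge")
    return np.einsum("j,ijk->ik", env.charges, diff / dist[:, :, None] ** 3)


def field_report(pigment: Pigment, env: ChargeEnvironment) -> FieldReport:
    """Coulomb field at the MG and NA..ND atoms of a frame-aligned pigment.

    Both the pigment and the environment are expected in the canonical ring
    frame (apply :func:`ring_frame` and ``ChargeEnvironment.transformed``
    with the same transform first).  Rows with a positive y component are
    flagged — the direction the Chl-c excitation energy is most sensitive to.
    """
    probes = pigment.ring_coords()
    if len(env.charges) == 0 or np.all(env.charges == 0.0):
        fields = np.zeros((len(RING_ATOMS), 3))
    else:
        fields = coulomb_field(env, probes)
    flags = fields[:, 1] > 0.0
    return FieldReport(atoms=list(RING_ATOMS), fields=fields, flags=flags)


# ---------------------------------------------------------------------------
# homogeneous-field scan analysis
# ---------------------------------------------------------------------------

def scan_shifts(scan: FieldScan) -> tuple[pd.DataFrame, dict[str, str]]:
    """Field-induced excitation-energy shifts and the dominant direction.

    Returns ``(shifts, max_direction)`` where ``shifts`` holds
    ``E(direction) - E(none)`` in eV for every non-baseline direction and
    ``max_direction`` maps each pigment onto the direction of its largest
    absolute shift.
    """
    baseline = scan.energies.loc["none"]
    directions = [d for d in scan.energies.index if d != "none"]
    shifts = scan.energies.loc[directions] - baseline
    max_direction = {
        col: shifts[col].abs().idxmax() for col in shifts.columns
    }
    return shifts, max_direction


def susceptibility_ratio(
    scan: FieldScan, group_a: list[str], group_b: list[str]
) -> tuple[float, int]:
    """Fold difference in field susceptibility between two pigment groups.

    The susceptibility of a group is the largest absolute field-induced
    shift over its pigments and directions; the ratio is group B over
    group A, returned together with its nearest-integer rounding.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    shifts, _ = scan_shifts(scan)
    max_a = shifts[group_a].abs().to_numpy().max()
    max_b = shifts[group_b].abs().to_numpy().max()
    if max_a == 0.0:
        raise ValueError("zero susceptibility in the reference group")
    ratio = float(max_b / max_a)
    return ratio, int(round(ratio))


def difference_dipole_fit(scan: FieldScan, pigment: str):
    """Linear Stark model for one pigment from a +/- field scan.

    The first-order Stark shift is ``dE = -dmu . F``; from paired scans
    along each axis ``dmu_alpha = -(E(+alpha) - E(-alpha)) / (2F)`` in
    eV per atomic unit of field.  Residuals (observed - predicted, eV) over
    the six scan points quantify how non-linear the actual response is.

    Returns ``(dmu, residuals)`` with ``dmu`` a 3-vector and ``residuals``
    a Series indexed by direction.
    """
    energies = scan.energies[pigment]
    dmu = np.zeros(3)
    for axis, idx in _AXIS.items():
        plus, minus = f"+{axis}", f"-{axis}"
        if plus not in energies.index or minus not in energies.index:
            raise ValueError(f"scan lacks the +/-{axis} pair")
        dmu[idx] = -(energies[plus] - energies[minus]) / (2.0 * scan.field)
    baseline = energies["none"]
    residuals = {}
    for direction in energies.index:
        if direction == "none":
            continue
        sign = 1.0 if direction[0] == "+" else -1.0
        fvec = np.zeros(3)
        fvec[_AXIS[direction[1]]] = sign * scan.field
        predicted = -dmu @ fvec
        residuals[direction] = float((energies[direction] - baseline) - predicted)
    return dmu, pd.Series(residuals)
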