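"""Physical constants and unit conversions.

Internal conventions used throughout the package:

* energies and frequencies in wavenumbers (cm^-1),
* time in femtoseconds,
* phase evolution ``exp(-1j * TWO_PI_C * E * t)`` with ``E`` in cm^-1 and
  ``t`` in fs,
* transition dipoles in Debye, coordinates in Angstrom,
* electric fields and point charges in atomic units (e / a0^2 and e).

All conversion factors derive from CODATA values; nothing is transcribed
from secondary sources.
"""

from __future__ import annotations

import math

# --- CODATA primaries -----------------------------------------------------
_E_CHARGE = 1.602176634e-19          # C
_EPS0 = 8.8541878128e-12             # F/m
_H_PLANCK = 6.62607015e-34           # J s
_C_M_S = 2.99792458e8                # m/s
_DEBYE_CM = 3.33564095e-30           # C m per Debye
_BOHR_M = 5.29177210903e-11          # m

# --- derived, in package units -------------------------------------------
#: speed of light in cm/fs
C_CM_FS = _C_M_S * 100.0 * 1e-15
#: 2*pi*c in rad / (cm^-1 fs); phase factor exp(-i * TWO_PI_C * E * t)
TWO_PI_C = 2.0 * math.pi * C_CM_FS
#: cm^-1 per eV
CM_PER_EV = _E_CHARGE / (_H_PLANCK * _C_M_S * 100.0)
#: Boltzmann constant in cm^-1 / K
KB_CM = 1.380649e-23 / (_H_PLANCK * _C_M_S * 100.0)
#: Angstrom per bohr
BOHR_ANG = _BOHR_M * 1e10
#: one atomic unit of electric field, in V/Angstrom
AU_FIELD_V_ANG = 27.211386245988 / BOHR_ANG / 1.0  # Hartree/(e*bohr) -> V/A


def _dipole_coupling_prefactor() -> float:
    """Point-dipole prefactor f in cm^-1 Angstrom^3 / Debye^2.

    V = f * kappa * |mu1||mu2| / R^3 for dipoles in Debye and R in Angstrom.
    """
    joule = _DEBYE_CM**2 / (4.0 * math.pi * _EPS0 * (1e-10) ** 3)
    return joule / (_H_PLANCK * _C_M_S * 100.0)


#: dipole-dipole coupling constant, ~5.034e3 cm^-1 A^3 / D^2
DIPOLE_COUPLING_CM = _dipole_coupling_prefactor()
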