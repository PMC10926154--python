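"""Packaged reference tables for gas-phase and in-protein chlorophylls.

Three small published data sets ship with the package:

* ``qy_reference_energies.csv`` — Q_y excitation energies (eV) of isolated
  Chl-a/c1/c2 from several electronic-structure levels and from solvent
  experiments; input to the energy-ladder and pairwise-difference analysis.
* ``qy_field_scan.csv`` — Q_y energies (eV) of the gas-phase-optimized
  pigments without a field and under homogeneous 0.01 au fields along
  +-x, +-y, +-z; input to the Stark shift / susceptibility analysis.
* ``protein_fields_chlc.csv`` — electric-field components (atomic units)
  at the Mg and ring-nitrogen atoms of the two Chl-c pigments inside the
  protein, in the pigment frame; +y components are the physiologically
  decisive ones.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .fields import FieldScan

__all__ = [
    "load_reference_energies",
    "load_field_scan",
    "load_protein_fields",
    "FIELD_SCAN_AU",
]

#: homogeneous field strength used for the reference scan (atomic units)
FIELD_SCAN_AU = 0.01


def _read(name: str) -> pd.DataFrame:
    # keep_default_na: the ring nitrogen "NA" is a literal atom name
    with resources.files("fcpexciton.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, keep_default_na=False, na_values=[])


def load_reference_energies() -> pd.DataFrame:
    """Gas-phase/solvent Q_y energies (eV), indexed by method."""
    return _read("qy_reference_energies.csv").set_index("method")


def load_field_scan() -> FieldScan:
    """Homogeneous-field Q_y scan of Chl-a/c1/c2 as a `FieldScan` (0.01 au)."""
    df = _read("qy_field_scan.csv").set_index("direction")
    return FieldScan(energies=df, field=FIELD_SCAN_AU)


def load_protein_fields() -> pd.DataFrame:
    """In-protein fields (au) at the Mg/N probe atoms of Chl-c1 and Chl-c2."""
    return _read("protein_fields_chlc.csv")
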