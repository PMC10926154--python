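#!/usr/bin/env python
"""Stark response of the chlorophylls and fields inside the protein.

Part 1 analyzes the packaged homogeneous-field scan (0.01 au): per-pigment
shifts, the dominant +y direction for Chl-c, the ~5-fold susceptibility
ratio, and a linear difference-dipole fit whose residuals show how
asymmetric the Chl-c response is.  Part 2 reproduces the geometry/field
machinery on a synthetic charge shell: a pigment is aligned into its ring
frame and the Coulomb field at its Mg/N atoms is tabulated with the +y
components flagged, mirroring the packaged in-protein field table.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import fcpexciton as fx
from fcpexciton.io import _aligned_copy
from fcpexciton.reference_data import load_field_scan, load_protein_fields

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    scan = load_field_scan()
    shifts, max_dir = fx.scan_shifts(scan)
    shifts.to_csv(OUT / "stark_shifts.csv", float_format="%.3f")
    ratio, rounded = fx.susceptibility_ratio(scan, ["chl_a"], ["chl_c1", "chl_c2"])

    print("Stark shifts E(direction) - E(none), eV:")
    print(shifts.round(3).to_string())
    print(f"\nDominant direction per pigment: {max_dir}")
    print(
        f"Chl-c susceptibility is {ratio:.2f}-fold that of Chl-a "
        f"(~{rounded}-fold): the +y response of Chl-c dwarfs everything else."
    )

    rows = {}
    for pigment in scan.energies.columns:
        dmu, res = fx.difference_dipole_fit(scan, pigment)
        rows[pigment] = {
            "dmu_x": dmu[0], "dmu_y": dmu[1], "dmu_z": dmu[2],
            "max_residual_ev": float(res.abs().max()),
        }
    fit = pd.DataFrame(rows).T
    fit.to_csv(OUT / "difference_dipoles.csv", float_format="%.4g")
    print("\nLinear difference-dipole fit (eV per au field) and residuals:")
    print(fit.round(3).to_string())
    print(
        "Large +y residuals for Chl-c1/c2 mean the response is strongly "
        "one-sided, beyond a first-order Stark model."
    )

    # part 2: ring frame + synthetic charge shell
    pigments, _ = fx.make_network(seed=1)
    pig = next(p for p in pigments if p.label == "CLC403")
    rot, trans = fx.ring_frame(pig)
    aligned = _aligned_copy(pig, rot, trans)
    env = fx.make_environment(
        np.array([0.0, 0.022, 0.0]), aligned.atoms["NA"], seed=1
    )
    report = fx.field_report(aligned, env)
    df = report.to_dataframe()
    df.to_csv(OUT / "synthetic_field_report.csv", index=False, float_format="%.4g")
    print("\nSynthetic charge shell, fields at the ring atoms (au):")
    print(df.round(4).to_string(index=False))

    protein = load_protein_fields()
    pos_y = protein[protein["Fy_au"] > 0]["atom"].unique()
    print(
        f"\nIn the packaged in-protein table the +y components sit on "
        f"{sorted(pos_y)} — the atoms facing the charged residues that "
        "red-shift Chl-c."
    )


if __name__ == "__main__":
    main()
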