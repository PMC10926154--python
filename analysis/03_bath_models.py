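#!/usr/bin/env python
"""Spectral densities: models, reorganization energies, and the round trip.

Builds the default Chl-a / Chl-c baths (Drude background plus intramolecular
modes at 750/1150/1520 cm^-1, much weaker for Chl-c), reports reorganization
energies before and after the 800 cm^-1 truncation, and demonstrates that
synthesizing Gaussian gap trajectories from a bath and re-extracting the
spectral density returns the input within a few percent RMS.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import fcpexciton as fx
from fcpexciton.io import write_sd

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    sds = fx.default_site_sds()
    rows = []
    for name, sd in sds.items():
        cut = fx.truncate_sd(sd, 800.0)
        rows.append(
            {
                "pool": name,
                "lambda_cm1": fx.reorganization_energy(sd),
                "lambda_below_800_cm1": fx.reorganization_energy(cut),
            }
        )
        write_sd(sd, OUT / f"sd_{name}.txt")
    table = pd.DataFrame(rows).set_index("pool")
    table.to_csv(OUT / "reorganization_energies.csv", float_format="%.2f")
    print("Reorganization energies (cm^-1):")
    print(table.round(1).to_string())
    print(
        "Truncating above 800 cm^-1 removes most of the Chl-a mode "
        "reorganization — exactly the content that builds the vibronic "
        "sideband in absorption."
    )

    sd = sds["a"]
    acc = None
    n_real = 20
    for r in range(n_real):
        traj = fx.sample_trajectory(sd, 300.0, 2.0, 16384, 1, seed=100 + r)
        ext = fx.sd_from_trajectory(traj, 300.0)
        if acc is None:
            acc, grid = np.zeros_like(ext.j), ext.omega
        acc += ext.j
    acc /= n_real
    target = sd.interp(grid)
    mask = target > 0.05 * target.max()
    rms = np.sqrt(np.mean((acc[mask] - target[mask]) ** 2) / np.mean(target[mask] ** 2))
    pd.DataFrame({"omega_cm1": grid, "J_extracted": acc, "J_input": target}).to_csv(
        OUT / "sd_round_trip.csv", index=False, float_format="%.6g"
    )
    print(
        f"\nSynthesis -> extraction round trip over {n_real} realizations: "
        f"{100 * rms:.1f}% RMS deviation on the support (J > 5% of max)."
    )


if __name__ == "__main__":
    main()
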