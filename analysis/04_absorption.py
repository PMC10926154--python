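#!/usr/bin/env python
"""Linear absorption of the synthetic network: pools, truncation, alignment.

Computes the cumulant absorption spectrum of the 9-site network at 300 K,
decomposes it into the Chl-a and Chl-c pools, repeats the calculation with
the baths truncated above 800 cm^-1, and exercises the rigid peak-alignment
shift against a mock reference curve.  Findings mirror the study logic: the
Chl-a pool carries ~90% of the intensity, and the high-frequency sideband
vanishes when the intramolecular modes are removed — it is vibronic Chl-a
structure, not Chl-c absorption.
"""

from pathlib import Path

import numpy as np

import fcpexciton as fx
from fcpexciton.io import write_spectrum_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    _, H = fx.make_network(seed=1)
    sds = fx.default_site_sds()

    full = fx.pool_decomposition(H, sds, 300.0)
    write_spectrum_csv(full, OUT / "absorption_pools.csv")
    truncated = fx.absorption_cumulant(
        H, {k: fx.truncate_sd(v, 800.0) for k, v in sds.items()}, 300.0
    )
    write_spectrum_csv(truncated, OUT / "absorption_truncated.csv")

    main_peak = full.omega[int(np.argmax(full.intensity))]
    win = (full.omega >= main_peak + 900.0) & (full.omega <= main_peak + 1700.0)
    w_full = np.trapezoid(full.intensity[win], full.omega[win])
    w_cut = np.trapezoid(truncated.intensity[win], truncated.omega[win])
    w_a = np.trapezoid(full.components["a"], full.omega)
    w_c = np.trapezoid(full.components["c"], full.omega)

    print(f"Main absorption peak at {main_peak:.0f} cm^-1.")
    print(
        f"Chl-a pool carries {100 * w_a / (w_a + w_c):.1f}% of the integrated "
        "intensity; the Chl-c pool is nearly invisible."
    )
    print(
        f"Truncating the baths above 800 cm^-1 removes "
        f"{100 * (w_full - w_cut) / w_full:.1f}% of the sideband-window weight "
        "(the sideband disappears)."
    )

    # rigid alignment against a reference curve peaking 1049 cm^-1 higher
    ref = fx.Spectrum(omega=full.omega + 1049.0, intensity=full.intensity.copy())
    shift = fx.align_shift(ref, full)
    print(
        f"Aligning a curve peaking 1049 cm^-1 higher onto the computed "
        f"spectrum requires a {shift:+.0f} cm^-1 shift — the mechanics used "
        "to overlay computed and measured spectra."
    )


if __name__ == "__main__":
    main()
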