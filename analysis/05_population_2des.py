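#!/usr/bin/env python
"""NISE dynamics: pool transfer, 2DES waiting-time traces, Forster estimate.

Propagates the 9-site network under fluctuating site energies: (i) the
Chl-a -> Chl-c population transfer over 2 ps, (ii) a small absorptive 2DES
at waiting times 0 and 50 fs with diagonal traces of the main and vibronic
regions, (iii) a Forster-theory transfer time for the largest inter-pool
coupling.  Findings: inter-pool transfer is picosecond-scale (sub-percent
Chl-c population at 100 fs), while the vibronic diagonal feature changes on
tens of femtoseconds — fast vibrational dynamics of Chl-a, not Chl-c
exciton transfer.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import fcpexciton as fx
from fcpexciton.io import write_spectrum2d

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    _, H = fx.make_network(seed=SEED)
    sds = fx.default_site_sds()
    jmax, pair = fx.max_interpool_coupling(H)
    print(f"Largest Chl-a/Chl-c coupling: {jmax:.1f} cm^-1 between {pair}.")

    # (i) population transfer
    ensemble = fx.make_ensemble(H, sds, 300.0, 30, 1001, dt=2.0, seed=SEED + 11)
    pops = fx.pool_transfer(ensemble, 2000.0)
    pd.DataFrame({"t_fs": pops.t, "p_stay_a": pops.p_stay_a, "p_c": pops.p_c}).to_csv(
        OUT / "pool_populations.csv", index=False, float_format="%.6g"
    )
    i100 = int(np.searchsorted(pops.t, 100.0))
    print(
        f"P(Chl-c) = {pops.p_c[i100]:.4f} at 100 fs and "
        f"{pops.p_c[-1]:.4f} at 2 ps: transfer is picosecond-scale, as the "
        "~25 cm^-1 couplings dictate."
    )

    # (ii) 2DES + diagonal traces
    n_t = 96
    ens2d = fx.make_ensemble(H, sds, 300.0, 10, 2 * n_t + 27, dt=2.0, seed=SEED + 7)
    grid = np.arange(13800.0, 17400.0, 20.0)
    s2d = fx.response_2d(
        ens2d, n_t1=n_t, n_t3=n_t, t2_list=[0.0, 50.0], w1_grid=grid, w3_grid=grid
    )
    write_spectrum2d(s2d, OUT, stem="twodes")
    spec = fx.absorption_cumulant(H, sds, 300.0)
    main_peak = float(spec.omega[int(np.argmax(spec.intensity))])
    diag = np.array([s2d.signal[0][i, i] for i in range(len(grid))])
    band = (grid >= main_peak + 900.0) & (grid <= main_peak + 1700.0)
    vib_peak = float(grid[band][int(np.argmax(diag[band]))])
    main = fx.diagonal_trace(s2d, (main_peak - 100.0, main_peak + 100.0))
    vib = fx.diagonal_trace(s2d, (vib_peak - 150.0, vib_peak + 150.0))
    print(
        f"Diagonal traces at t2 = 50 fs (normalized to t2 = 0): main peak "
        f"{main[1]:.2f}, vibronic region {vib[1]:.2f}.  The main band barely "
        "moves while the vibronic feature changes completely within 50 fs — "
        "with this sparse three-mode bath it beats coherently rather than "
        "damping away, so its trace can overshoot or invert."
    )

    # (iii) Forster estimate from cumulant single-site lineshapes
    lineshapes = {}
    for key, e0, mu in (("a", 14950.0, 4.0), ("c", 14600.0, 2.4)):
        h1 = fx.ExcitonHamiltonian(
            labels=[f"CL{key.upper()}0"], E=[e0], J=[[0.0]],
            mu=np.array([[mu, 0, 0]]), pools={f"CL{key.upper()}0": key},
        )
        s = fx.absorption_cumulant(h1, {key: sds[key]}, 300.0,
                                   grid=np.arange(10000.0, 20000.0, 1.0))
        line = s.intensity / s.omega
        lineshapes[key] = fx.Spectrum(
            omega=s.omega, intensity=line / np.trapezoid(line, s.omega)
        )
    t_ps, rate = fx.forster_transfer_time(jmax, lineshapes["a"], lineshapes["c"])
    print(
        f"Forster transfer time for J = {jmax:.0f} cm^-1 with these "
        f"lineshapes: {t_ps:.2f} ps (rate {rate * 1e3:.3f} / ps) — "
        "consistent with the picosecond-scale NISE transfer."
    )


if __name__ == "__main__":
    main()
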