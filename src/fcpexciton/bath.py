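"""Spectral densities and Gaussian site-energy fluctuation trajectories.

The coupling of each pigment's excitation energy to its environment is
summarized by a spectral density J(omega).  Chlorophyll baths combine an
overdamped (Drude) low-frequency part from protein/solvent motion with
sharp underdamped intramolecular modes above ~800 cm^-1, which are the
origin of the vibronic sideband in absorption.  This module constructs
model spectral densities, extracts them from energy-gap trajectories, and
synthesizes stationary Gaussian trajectories consistent with a target
spectral density (the stand-in for QM/MM excitation-energy time series).

Conventions.  J is in cm^-1 on a wavenumber grid (cm^-1).  The classical
energy-gap autocorrelation corresponding to J at temperature T is

    C(t) = (2 kB T / pi) * Int dw J(w)/w cos(2 pi c w t),

so the variance is 2 kB T lambda with the reorganization energy
lambda = (1/pi) Int J(w)/w dw.  Extraction inverts this with the harmonic
prefactor beta*w, making synthesis -> extraction an identity in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import C_CM_FS, KB_CM, TWO_PI_C

__all__ = [
    "SpectralDensity",
    "Trajectory",
    "model_sd",
    "drude_sd",
    "underdamped_sd",
    "reorganization_energy",
    "truncate_sd",
    "sd_from_trajectory",
    "sample_trajectory",
]


@dataclass
class SpectralDensity:
    """J(omega) >= 0 on an ascending positive wavenumber grid (cm^-1)."""

    omega: np.ndarray
    j: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.j = np.asarray(self.j, dtype=float)
        if self.omega.ndim != 1 or self.omega.shape != self.j.shape:
            raise ValueError("omega and J must be matching 1-D arrays")
        if np.any(self.omega <= 0) or np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega grid must be positive and strictly ascending")
        if np.any(self.j < 0):
            raise ValueError("J must be nonnegative")

    def __add__(self, other: "SpectralDensity") -> "SpectralDensity":
        if not np.array_equal(self.omega, other.omega):
            raise ValueError("spectral densities live on different grids")
        return SpectralDensity(self.omega.copy(), self.j + other.j)

    def interp(self, omega: np.ndarray) -> np.ndarray:
        """J interpolated onto another grid, zero outside the support."""
        return np.interp(omega, self.omega, self.j, left=0.0, right=0.0)


@dataclass
class Trajectory:
    """Per-site energy-gap fluctuation series delta E_n(t_i) (cm^-1).

    ``delta`` has shape (n_sites, n_steps); ``mean_energies`` holds the mean
    site energies the fluctuations ride on (cm^-1).
    """

    dt: float
    delta: np.ndarray
    mean_energies: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta = np.atleast_2d(np.asarray(self.delta, dtype=float))
        if not np.all(np.isfinite(self.delta)):
            raise ValueError("non-finite trajectory")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.mean_energies is not None:
            self.mean_energies = np.asarray(self.mean_energies, dtype=float)

    @property
    def n_sites(self) -> int:
        return self.delta.shape[0]

    @property
    def n_steps(self) -> int:
        return self.delta.shape[1]


def drude_sd(lam: float, gamma: float, grid: np.ndarray) -> SpectralDensity:
    """Overdamped Drude spectral density 2*lam*w*gamma/(w^2+gamma^2)."""
    if lam <= 0 or gamma <= 0:
        raise ValueError("Drude parameters must be positive")
    w = np.asarray(grid, dtype=float)
    return SpectralDensity(w, 2.0 * lam * w * gamma / (w**2 + gamma**2))


def underdamped_sd(lam: float, omega0: float, gamma: float, grid: np.ndarray) -> SpectralDensity:
    """Underdamped Brownian-oscillator mode (antisymmetrized Lorentzian pair).

    ``J(w) = 2*lam*omega0^2*gamma*w / ((w^2-omega0^2)^2 + gamma^2 w^2)``;
    for gamma << omega0 the peak sits at ~omega0 and carries reorganization
    energy ~lam.
    """
    if lam <= 0 or omega0 <= 0 or gamma <= 0:
        raise ValueError("mode parameters must be positive")
    w = np.asarray(grid, dtype=float)
    j = 2.0 * lam * omega0**2 * gamma * w / ((w**2 - omega0**2) ** 2 + gamma**2 * w**2)
    return SpectralDensity(w, j)


def model_sd(kind: str, params: dict, grid: np.ndarray) -> SpectralDensity:
    """Build a model spectral density: ``drude`` or ``underdamped``."""
    if kind == "drude":
        return drude_sd(params["lam"], params["gamma"], grid)
    if kind == "underdamped":
        return underdamped_sd(params["lam"], params["omega0"], params["gamma"], grid)
    raise ValueError(f"unknown spectral-density kind {kind!r}")


def reorganization_energy(sd: SpectralDensity) -> float:
    """lambda = (1/pi) Int J(w)/w dw by trapezoid on the grid (cm^-1).

    The segment between the origin and the first grid point is included by
    treating J/w as constant there (J vanishes linearly at w -> 0).
    """
    if sd.j.max(initial=0.0) > 0:
        peak = sd.omega[np.argmax(sd.j)]
        under = np.count_nonzero((sd.omega > 0.5 * peak) & (sd.omega < 1.5 * peak))
        if under < 10:
            import warnings

            warnings.warn("grid too coarse under the main peak", stacklevel=2)
    origin = sd.j[0]  # (J[0]/w[0]) * w[0]
    return float((np.trapezoid(sd.j / sd.omega, sd.omega) + origin) / np.pi)


def truncate_sd(sd: SpectralDensity, cutoff: float) -> SpectralDensity:
    """Zero the spectral density above the cutoff; unchanged below."""
    j = np.where(sd.omega > cutoff, 0.0, sd.j)
    return SpectralDensity(sd.omega.copy(), j)


def _max_supported_freq(sd: SpectralDensity) -> float:
    nz = sd.omega[sd.j > 1e-12 * max(sd.j.max(), 1e-300)]
    return float(nz[-1]) if nz.size else 0.0


def sample_trajectory(
    sd: SpectralDensity,
    temperature: float,
    dt: float,
    n_steps: int,
    n_sites: int = 1,
    seed: int | np.random.Generator = 0,
    mean_energies: np.ndarray | None = None,
) -> Trajectory:
    """Synthesize stationary Gaussian gap trajectories matching ``sd``.

    Random-phase Fourier synthesis: each realization is a sum of cosines
    with amplitudes set by the classical power spectrum
    ``S(w) = (2 kB T / pi) J(|w|)/|w|`` and independent uniform phases.
    Sites are independent; the result is reproducible for a given seed.
    The variance equals ``2 kB T lambda`` in expectation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wmax = _max_supported_freq(sd)
    if wmax > 0 and dt >= 1.0 / (4.0 * C_CM_FS * wmax):
        bound = 1.0 / (4.0 * C_CM_FS * wmax)
        raise ValueError(
            f"dt={dt} fs too large for spectral content up to {wmax:.0f} cm^-1; "
            f"Nyquist-safe bound is dt < {bound:.3f} fs"
        )
    n = int(n_steps)
    freqs = np.arange(1, n // 2) / (n * dt * C_CM_FS)  # wavenumber, cm^-1
    dnu = 1.0 / (n * dt * C_CM_FS)
    s1 = (2.0 * KB_CM * temperature / np.pi) * sd.interp(freqs) / freqs
    amps = np.sqrt(s1 * dnu)
    series = np.zeros((n_sites, n))
    for site in range(n_sites):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.shape)
        z = np.zeros(n, dtype=complex)
        z[1 : n // 2] = amps * np.exp(1j * phases)
        series[site] = np.sqrt(2.0) * np.real(np.fft.ifft(z) * n)
    return Trajectory(dt=dt, delta=series, mean_energies=mean_energies)


def sd_from_trajectory(
    traj: Trajectory,
    temperature: float,
    site: int | None = None,
    pad_factor: int = 4,
    max_lag_fraction: float = 0.125,
) -> SpectralDensity | list[SpectralDensity]:
    """Extract spectral densities from energy-gap trajectories.

    The unbiased autocorrelation ``C(t) = <dE(0) dE(t)>`` is computed up to
    a fraction of the trajectory length (``max_lag_fraction``, short enough
    to keep the periodogram variance down while covering the bath
    correlation time), tapered with a Hann half-window, zero-padded and
    cosine-transformed; the harmonic prefactor ``beta * w`` then gives

        J(w) = 2 pi c beta w Int_0^inf C(t) cos(2 pi c w t) dt,

    the exact inverse of :func:`sample_trajectory` in expectation.  Negative
    values are clipped to zero (clip fraction stored as ``clip_fraction``
    on the returned object).  With ``site=None`` a list over sites is
    returned (a single `SpectralDensity` for one-site trajectories).
    """
    if np.all(traj.delta == 0.0):
        grid = np.linspace(1.0, 1000.0, 1000)
        out = SpectralDensity(grid, np.zeros_like(grid))
        out.clip_fraction = 0.0
        return out if traj.n_sites == 1 or site is not None else [out] * traj.n_sites

    def _one(x: np.ndarray) -> SpectralDensity:
        n = x.size
        x = x - x.mean()
        nlag = max(int(n * max_lag_fraction), 16)
        # unbiased autocorrelation via FFT
        fx = np.fft.rfft(x, 2 * n)
        acf = np.fft.irfft(fx * np.conj(fx))[:nlag]
        acf /= n - np.arange(nlag)
        window = 0.5 * (1.0 + np.cos(np.pi * np.arange(nlag) / nlag))
        cw = acf * window
        npad = pad_factor * nlag
        # Int_0^inf C cos(w t) dt by half-sample-corrected rectangle rule
        spec = np.fft.rfft(cw, 2 * npad)
        integral = traj.dt * (np.real(spec) - 0.5 * cw[0])
        freqs = np.fft.rfftfreq(2 * npad, d=traj.dt) / C_CM_FS  # cm^-1
        beta = 1.0 / (KB_CM * temperature)
        j = TWO_PI_C * beta * freqs * integral
        keep = freqs > 0
        j, freqs = j[keep], freqs[keep]
        clip_fraction = float(np.mean(j < 0))
        out = SpectralDensity(freqs, np.clip(j, 0.0, None))
        out.clip_fraction = clip_fraction
        return out

    if site is not None:
        return _one(traj.delta[site])
    sds = [_one(traj.delta[s]) for s in range(traj.n_sites)]
    return sds[0] if traj.n_sites == 1 else sds
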