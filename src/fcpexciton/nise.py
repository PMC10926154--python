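"""NISE propagation, population transfer, linear response, and 2DES.

Numerical Integration of the Schrodinger Equation (NISE): the one- and
two-exciton wavefunctions are propagated under a Hamiltonian whose site
energies fluctuate along classical trajectories while the couplings stay
fixed.  Each time step applies the unitary
``exp(-i * 2*pi*c * H(t_i) * dt)`` built from the eigendecomposition of the
instantaneous Hamiltonian, so the norm is conserved to machine precision.

Third-order signals are accumulated from the six double-sided pathways
(ground-state bleach, stimulated emission and excited-state absorption,
each in rephasing and non-rephasing flavour), isotropically averaged for
parallel (xxxx) polarization with the standard 1/15 weights, and combined
into the real absorptive 2D spectrum with bleach-positive sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bath import Trajectory
from .constants import C_CM_FS, TWO_PI_C
from .lineshape import Spectrum
from .pigments import ExcitonHamiltonian, TwoExcitonManifold, two_exciton_expand

__all__ = [
    "StochasticHamiltonian",
    "Spectrum2D",
    "PoolPopulations",
    "propagate",
    "pool_transfer",
    "linear_response",
    "response_2d",
    "diagonal_trace",
    "forster_transfer_time",
]


@dataclass
class StochasticHamiltonian:
    """Exciton Hamiltonian with site-diagonal energy fluctuations.

    ``H(t_i) = diag(E + dE(t_i)) + J`` — couplings are time independent
    (the network Hamiltonian is a time average); fluctuations ride on the
    diagonal only.
    """

    base: ExcitonHamiltonian
    fluctuations: Trajectory

    def __post_init__(self) -> None:
        if self.fluctuations.n_sites != self.base.n:
            raise ValueError("fluctuation trajectory does not match site count")

    @property
    def dt(self) -> float:
        return self.fluctuations.dt

    @property
    def n_steps(self) -> int:
        return self.fluctuations.n_steps

    def h_at(self, i: int) -> np.ndarray:
        h = self.base.J.copy()
        np.fill_diagonal(h, self.base.E + self.fluctuations.delta[:, i])
        return h


@dataclass
class Spectrum2D:
    """Absorptive 2D spectra per waiting time, bleach-positive.

    ``signal[i]`` is the real detection x excitation matrix for waiting
    time ``t2_list[i]`` (indexed ``[i3, i1]``, rows = detection axis w3).
    ``components[i]`` retains the signed GSB / SE / ESA contributions (ESA
    enters negatively).
    """

    t2_list: list[float]
    w1: np.ndarray
    w3: np.ndarray
    signal: list[np.ndarray]
    components: list[dict[str, np.ndarray]]


@dataclass
class PoolPopulations:
    """Site populations and their Chl-a / Chl-c pool sums vs time."""

    t: np.ndarray
    p_site: np.ndarray  # (nt, n)
    p_stay_a: np.ndarray
    p_c: np.ndarray


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def _step_propagator(h: np.ndarray, dt: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(h)
    phase = np.exp(-1j * TWO_PI_C * vals * dt)
    return (vecs * phase) @ vecs.conj().T


def propagate(
    sh: StochasticHamiltonian,
    psi0: np.ndarray,
    n_steps: int,
    start: int = 0,
) -> np.ndarray:
    """Propagate a wavefunction (or stacked columns) through ``n_steps``.

    Returns the series of states at steps 0..n_steps (inclusive), shape
    ``(n_steps+1, n)`` for a vector input or ``(n_steps+1, n, k)`` for k
    stacked initial states.  Errors out if the norm drifts beyond 1e-6.
    """
    psi = np.asarray(psi0, dtype=complex)
    single = psi.ndim == 1
    if single:
        psi = psi[:, None]
    if start + n_steps > sh.n_steps:
        raise ValueError("trajectory too short for the requested propagation")
    out = np.empty((n_steps + 1,) + psi.shape, dtype=complex)
    out[0] = psi
    norm0 = np.linalg.norm(psi, axis=0)
    for i in range(n_steps):
        psi = _step_propagator(sh.h_at(start + i), sh.dt) @ psi
        out[i + 1] = psi
    drift = np.max(np.abs(np.linalg.norm(psi, axis=0) - norm0))
    if drift > 1e-6:
        raise RuntimeError(f"norm drift {drift:.2e} exceeds 1e-6")
    return out[:, :, 0] if single else out


def pool_transfer(
    ensemble: list[StochasticHamiltonian],
    horizon_fs: float,
    init_pool: str = "a",
) -> PoolPopulations:
    """Excitation transfer between the Chl-a and Chl-c pools.

    Each realization is propagated once for every initial site of the
    starting pool (uniform average over the Chl-a initial excitations);
    ``p_stay_a`` sums the site populations over the starting pool and
    ``p_c`` over the other pool.  ``p_stay_a(0) = 1`` by construction.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    base = ensemble[0].base
    sites_init = base.pool_sites(init_pool)
    other = "c" if init_pool == "a" else "a"
    sites_other = base.pool_sites(other)
    if not sites_init:
        raise ValueError(f"empty initial pool {init_pool!r}")
    n_steps = int(round(horizon_fs / ensemble[0].dt))
    n = base.n
    psi0 = np.zeros((n, len(sites_init)), dtype=complex)
    for k, s in enumerate(sites_init):
        psi0[s, k] = 1.0
    acc = np.zeros((n_steps + 1, n))
    for sh in ensemble:
        psi = propagate(sh, psi0, n_steps)
        acc += np.mean(np.abs(psi) ** 2, axis=2)
    p_site = acc / len(ensemble)
    total = p_site.sum(axis=1)
    if np.max(np.abs(total - 1.0)) > 1e-8:
        raise RuntimeError("population not conserved")
    t = np.arange(n_steps + 1) * ensemble[0].dt
    return PoolPopulations(
        t=t,
        p_site=p_site,
        p_stay_a=p_site[:, sites_init].sum(axis=1),
        p_c=p_site[:, sites_other].sum(axis=1),
    )


# ---------------------------------------------------------------------------
# linear response
# ---------------------------------------------------------------------------

def linear_response(
    ensemble: list[StochasticHamiltonian],
    n_t: int = 1024,
    pad_factor: int = 4,
    apodization_fs: float | None = None,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Linear absorption from the NISE dipole autocorrelation.

    ``R(t) = (1/3) <mu . U(t,0) mu>`` (isotropic orientational average),
    ensemble averaged and Fourier transformed in a rotating frame at the
    mean site energy.  Serves as the independent absorption engine next to
    the cumulant route.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    base = ensemble[0].base
    dt = ensemble[0].dt
    mu = base.mu  # (n, 3)
    carrier = float(base.E.mean())
    tgrid = np.arange(n_t) * dt
    resp = np.zeros(n_t, dtype=complex)
    for sh in ensemble:
        psi = propagate(sh, mu.astype(complex), n_t - 1)  # (n_t, n, 3)
        corr = np.einsum("na,tna->t", mu, psi) / 3.0
        resp += corr * np.exp(1j * TWO_PI_C * carrier * tgrid)
    resp /= len(ensemble)
    if apodization_fs:
        resp *= np.exp(-tgrid / apodization_fs)
    npad = pad_factor * n_t
    spec = np.fft.ifft(resp, npad) * npad * dt
    nu = np.fft.fftfreq(npad, d=dt) / C_CM_FS + carrier
    order = np.argsort(nu)
    nu, amp = nu[order], np.real(spec[order]) - 0.5 * dt * np.real(resp[0])
    if grid is None:
        grid = nu[(nu > carrier - 4000) & (nu < carrier + 4000)]
    intensity = np.interp(grid, nu, amp, left=0.0, right=0.0) * grid
    return Spectrum(omega=np.asarray(grid, float), intensity=intensity)


# ---------------------------------------------------------------------------
# third-order response
# ---------------------------------------------------------------------------

def _cumulative_propagators(dt: float, n_steps: int, hams) -> np.ndarray:
    """U[tau] = U(tau, 0) for tau = 0..n_steps, piecewise-constant H."""
    dim = hams(0).shape[0]
    U = np.empty((n_steps + 1, dim, dim), dtype=complex)
    U[0] = np.eye(dim)
    for i in range(n_steps):
        U[i + 1] = _step_propagator(hams(i), dt) @ U[i]
    return U


def _xxxx_weights() -> np.ndarray:
    """Isotropic <xxxx> tensor (1/15)(d_ab d_cd + d_ac d_bd + d_ad d_bc)."""
    d = np.eye(3)
    return (
        np.einsum("ab,cd->abcd", d, d)
        + np.einsum("ac,bd->abcd", d, d)
        + np.einsum("ad,bc->abcd", d, d)
    ) / 15.0


def response_2d(
    ensemble: list[StochasticHamiltonian],
    n_t1: int = 128,
    n_t3: int = 128,
    t2_list=(0.0,),
    w1_grid: np.ndarray | None = None,
    w3_grid: np.ndarray | None = None,
    include_esa: bool = True,
) -> Spectrum2D:
    """Absorptive 2DES with parallel (xxxx) polarization.

    For every realization and waiting time the six pathways are accumulated
    from NISE propagators in the one- and two-exciton manifolds, contracted
    with the isotropic 1/15 weights, apodized with a cosine-squared window
    along t1 and t3, and transformed to the requested excitation and
    detection grids by explicit discrete Fourier kernels.  Bleach (GSB+SE)
    enters positive, induced absorption (ESA) negative.

    Pathway amplitudes (U = one-exciton, V = two-exciton propagator; pulse
    dipole components a, b, c, d in interaction order; ts = t1+t2,
    tau = t1+t2+t3):

    * GSB  r/nr: (mu_d' U(tau,ts) mu_c) x conj/plain (mu_b' U(t1,0) mu_a)
    * SE   r:    (mu_d' U(tau,t1) mu_b) x conj(mu_c' U(ts,0) mu_a)
    * SE   nr:   (mu_d' U(tau,0) mu_a) x conj(mu_c' U(ts,t1) mu_b)
    * ESA  r:    -(U(tau,0) mu_a)^H T_d' V(tau,ts) T_c U(ts,t1) mu_b
    * ESA  nr:   -(U(tau,t1) mu_b)^H T_d' V(tau,ts) T_c U(ts,0) mu_a

    with T the one- to two-exciton raising operator.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    base = ensemble[0].base
    n = base.n
    dt = ensemble[0].dt
    if w1_grid is None or w3_grid is None:
        span = float(np.ptp(base.E)) + 2500.0
        step = max(1.0 / (n_t1 * dt * C_CM_FS) / 2.0, 5.0)
        default = np.arange(base.E.mean() - span, base.E.mean() + span, step)
        w1_grid = default if w1_grid is None else np.asarray(w1_grid, float)
        w3_grid = default.copy() if w3_grid is None else np.asarray(w3_grid, float)
    w1_grid = np.asarray(w1_grid, float)
    w3_grid = np.asarray(w3_grid, float)
    if np.ptp(base.E) > 1.0 / (2.0 * dt * C_CM_FS):
        import warnings

        warnings.warn("time grid too coarse to resolve the exciton band", stacklevel=2)

    manifold: TwoExcitonManifold | None = None
    if include_esa and n >= 2:
        manifold = two_exciton_expand(base)

    t2_steps = [int(round(t2 / dt)) for t2 in t2_list]
    n_tot = n_t1 + max(t2_steps) + n_t3
    W = _xxxx_weights()
    mu = base.mu  # (n, 3)

    t1_ax = np.arange(n_t1) * dt
    t3_ax = np.arange(n_t3) * dt
    apo1 = np.cos(0.5 * np.pi * np.arange(n_t1) / n_t1) ** 2
    apo3 = np.cos(0.5 * np.pi * np.arange(n_t3) / n_t3) ** 2
    # DFT kernels; rephasing evolves as exp(+iEt1), both families exp(-iEt3)
    k1_r = np.exp(-1j * TWO_PI_C * np.outer(w1_grid, t1_ax))
    k1_nr = np.conj(k1_r)
    k3 = np.exp(+1j * TWO_PI_C * np.outer(w3_grid, t3_ax))
    k1_r[:, 0] *= 0.5
    k1_nr[:, 0] *= 0.5
    k3[:, 0] *= 0.5

    accum = [
        {name: np.zeros((w3_grid.size, w1_grid.size)) for name in ("gsb", "se", "esa")}
        for _ in t2_list
    ]

    for sh in ensemble:
        if sh.n_steps < n_tot:
            raise ValueError("trajectory too short for the requested 2D grids")
        U1 = _cumulative_propagators(dt, n_tot, sh.h_at)
        U2 = None
        if manifold is not None:
            fl = sh.fluctuations.delta
            pairs = np.array(manifold.pairs)

            def h2_at(i: int) -> np.ndarray:
                h = manifold.H2.copy()
                h[np.diag_indices_from(h)] += fl[pairs[:, 0], i] + fl[pairs[:, 1], i]
                return h

            U2 = _cumulative_propagators(dt, n_tot, h2_at)
        # component-resolved one-exciton blocks
        A1 = np.einsum("na,tnm,mb->tab", mu, U1, mu)  # mu_b' U1[t] mu_a -> [t,a,b]
        Y = np.einsum("tnm,na->tma", U1.conj(), mu)  # U1[t]^H mu_a -> [t,m,a]

        for it2, t2s in enumerate(t2_steps):
            parts = _pathways_for_t2(
                manifold, mu, U1, U2, A1, Y, n_t1, n_t3, t2s, W
            )
            for name, (s_r, s_nr) in parts.items():
                s_r = s_r * apo1[:, None] * apo3[None, :]
                s_nr = s_nr * apo1[:, None] * apo3[None, :]
                mat = np.real(k3 @ (k1_r @ s_r + k1_nr @ s_nr).T)
                accum[it2][name] += mat * dt * dt

    nreal = len(ensemble)
    components = [{k: v / nreal for k, v in acc.items()} for acc in accum]
    signal = [c["gsb"] + c["se"] + c["esa"] for c in components]
    return Spectrum2D(
        t2_list=list(t2_list),
        w1=w1_grid,
        w3=w3_grid,
        signal=signal,
        components=components,
    )


def _pathways_for_t2(manifold, mu, U1, U2, A1, Y, n_t1, n_t3, t2s, W):
    """Six pathway amplitudes on the (t1, t3) grid for one waiting time.

    Returns ``{"gsb": (r, nr), "se": (r, nr), "esa": (r, nr)}`` with the
    ESA sign already applied (negative).
    """
    sl_ts = slice(t2s, t2s + n_t1)
    Yts = Y[sl_ts]  # (t1, m, c) at ts = t1 + t2s
    Y1 = Y[:n_t1]

    gsb_r = np.empty((n_t1, n_t3), dtype=complex)
    gsb_nr = np.empty_like(gsb_r)
    se_r = np.empty_like(gsb_r)
    se_nr = np.empty_like(gsb_r)

    A1c_t1 = A1[:n_t1].conj()
    A1_t1 = A1[:n_t1]
    A1c_ts = A1[sl_ts].conj()
    # E[t, b, c] = Y[ts,c]^H Y[t1,b]
    Ebc = np.einsum("tmc,tmb->tbc", Yts.conj(), Y1)

    for u in range(n_t3):
        tau = slice(t2s + u, t2s + u + n_t1)
        Ytau = Y[tau]  # aligned with t1
        # B[t,c,d] = Y[tau,d]^H Y[ts,c]
        B = np.einsum("tmd,tmc->tcd", Ytau.conj(), Yts)
        gsb_r[:, u] = np.einsum("tcd,tab,abcd->t", B, A1c_t1, W)
        gsb_nr[:, u] = np.einsum("tcd,tab,abcd->t", B, A1_t1, W)
        # C[t,b,d] = Y[tau,d]^H Y[t1,b]
        C = np.einsum("tmd,tmb->tbd", Ytau.conj(), Y1)
        se_r[:, u] = np.einsum("tbd,tac,abcd->t", C, A1c_ts, W)
        # D[t,a,d] = A1[tau,a,d]
        se_nr[:, u] = np.einsum("tad,tbc,abcd->t", A1[tau], Ebc.conj(), W)

    if manifold is None:
        zero = np.zeros((n_t1, n_t3), dtype=complex)
        esa = (zero, zero.copy())
    else:
        esa = _esa_pathways(manifold, mu, U1, U2, Y, n_t1, n_t3, t2s, W)
    return {"gsb": (gsb_r, gsb_nr), "se": (se_r, se_nr), "esa": esa}


def _esa_pathways(manifold, mu, U1, U2, Y, n_t1, n_t3, t2s, W):
    """Excited-state-absorption amplitudes (sign included)."""
    T = np.stack([manifold.raising_operator(mu[:, a]) for a in range(3)])  # (3, m, n)
    sl_ts = slice(t2s, t2s + n_t1)
    Uts = U1[sl_ts]  # U1[ts] aligned with t1
    U2ts_H = U2[sl_ts].conj().transpose(0, 2, 1)
    tau_hi = t2s + n_t1 + n_t3

    # rephasing: ket U(ts,t1) mu_b lifted by T_c, bra U(tau,0) mu_a via T_d
    ket1 = np.einsum("tnm,tmb->tnb", Uts, Y[:n_t1])  # U1(ts,t1) mu_b
    v = np.einsum("tqp,cpn,tnb->tqbc", U2ts_H, T, ket1)
    # pre-contract the isotropic weights: vv[t,q,a,d] = sum_bc v W
    vv = np.einsum("tqbc,abcd->tqad", v, W)
    phi = np.einsum("tnm,ma->tna", U1[:tau_hi], mu)  # U1[tau] mu_a
    rows = np.einsum("dpn,tna,tpq->tqad", T, phi.conj(), U2[:tau_hi])

    # non-rephasing: ket U(ts,0) mu_a lifted by T_c, bra U(tau,t1) mu_b
    ket2 = np.einsum("tnm,ma->tna", Uts, mu)
    v2 = np.einsum("tqp,cpn,tna->tqac", U2ts_H, T, ket2)
    vw = np.einsum("tqac,abcd->tqbd", v2, W)
    K = np.einsum("tmn,dpm,tpq->tnqd", U1[:tau_hi].conj(), T, U2[:tau_hi])

    Y1c = Y[:n_t1].conj()
    esa_r = np.empty((n_t1, n_t3), dtype=complex)
    esa_nr = np.empty_like(esa_r)
    for u in range(n_t3):
        tau = slice(t2s + u, t2s + u + n_t1)
        esa_r[:, u] = np.einsum("tqad,tqad->t", rows[tau], vv)
        esa_nr[:, u] = np.einsum("tnb,tnqd,tqbd->t", Y1c, K[tau], vw)
    return -esa_r, -esa_nr


def diagonal_trace(
    s2d: Spectrum2D, region: tuple[float, float], normalize: bool = True
) -> np.ndarray:
    """Mean signal in a square diagonal region per waiting time.

    ``region = (lo, hi)`` in cm^-1 selects excitation and detection
    frequencies inside [lo, hi]; the trace is normalized to its t2 = 0
    value by default.
    """
    lo, hi = region
    m1 = (s2d.w1 >= lo) & (s2d.w1 <= hi)
    m3 = (s2d.w3 >= lo) & (s2d.w3 <= hi)
    if not (m1.any() and m3.any()):
        raise ValueError("region outside the spectral grids")
    trace = np.array([float(s[np.ix_(m3, m1)].mean()) for s in s2d.signal])
    if normalize:
        if 0.0 not in s2d.t2_list:
            raise ValueError("normalization requires a t2 = 0 spectrum")
        ref = trace[s2d.t2_list.index(0.0)]
        if ref == 0.0:
            raise ValueError("zero signal in the region at t2 = 0")
        trace = trace / ref
    return trace


def forster_transfer_time(
    coupling: float,
    donor: Spectrum,
    acceptor: Spectrum,
) -> tuple[float, float]:
    """Forster transfer time from a coupling and area-normalized lineshapes.

    ``k = 2 pi * (2 pi c) * J^2 * Int L_D(w) L_A(w) dw`` in 1/fs for J in
    cm^-1 and unit-area lineshapes on a cm^-1 grid (``2 pi c`` is 1/hbar in
    the package units).  Returns ``(time_ps, rate_per_fs)``; zero overlap
    gives an infinite time.
    """
    for name, ls in (("donor", donor), ("acceptor", acceptor)):
        area = np.trapezoid(ls.intensity, ls.omega)
        if abs(area - 1.0) > 1e-2:
            raise ValueError(
                f"{name} lineshape not normalized to unit area (got {area:.4f})"
            )
    grid = donor.omega
    la = np.interp(grid, acceptor.omega, acceptor.intensity, left=0.0, right=0.0)
    overlap = float(np.trapezoid(donor.intensity * la, grid))
    rate = 2.0 * np.pi * TWO_PI_C * coupling**2 * overlap
    if rate <= 0.0:
        return float("inf"), 0.0
    return 1.0 / rate / 1000.0, rate
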