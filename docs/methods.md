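# Methods

`fcpexciton` implements the exciton-model analysis chain for the
chlorophyll a/c network of the diatom light-harvesting antenna FCP
(fucoxanthin–chlorophyll protein): a 9-site Frenkel Hamiltonian (seven
Chl-a, two Chl-c), the electrostatics that make Chl-c anomalously
field-sensitive, bath spectral densities, cumulant linear absorption, and
NISE wavefunction dynamics up to third-order (2DES) response.  This note
records the models, the numerical choices, and what the synthetic data do
and do not establish.

## Units and constants

Energies and frequencies are in cm⁻¹, time in fs, dipoles in Debye,
coordinates in Å, fields and charges in atomic units.  Phase evolution is
`exp(−i·2πc·E·t)` with `2πc = 1.8836516×10⁻⁴ rad/(cm⁻¹·fs)`; `1 eV =
8065.544 cm⁻¹`, `k_B = 0.6950348 cm⁻¹/K`.  All factors, including the
point-dipole coupling constant `f ≈ 5034 cm⁻¹·Å³/D²`, are derived from
CODATA primaries at import (`constants.py`), never transcribed.  One atomic
unit of field is 51.422 V/Å, so the 0.01 au scans correspond to 0.514 V/Å;
a tenfold larger figure sometimes quoted for this strength is a units slip,
and the CODATA value is used throughout.

## Exciton model

Site energies on the diagonal, excitonic couplings `J` off it; couplings
are treated as static (the network Hamiltonian is a time average) while
site energies fluctuate.  The two-exciton manifold uses hard-core bosons:
pair states `(i<j)` at `E_i+E_j`, pairs sharing a site coupled by the
one-exciton `J` of the differing sites, no intra-site double excitation and
no anharmonic shift — the standard choice for chlorophyll Q_y manifolds,
which prints no anharmonicity parameter to disagree with.  One→two dipoles
equal the dipole of the added site.

## Field analysis

`ring_frame` defines a reproducible molecular frame: best-fit plane of the
four ring nitrogens with +z fixed by the NA→NB→NC→ND circulation, nitrogen
centroid at the origin, and the in-plane y axis along the NC→NA projection
(the Q_y axis through the NA/NC pair).  The original in-plane orientation
used for the published field tables was chosen to maximize the +y response
and is not reproducible from geometry alone, so comparisons of in-protein
field components are by sign pattern (which atoms carry +y components), not
element-wise.  Coulomb fields are exact point-charge sums in the pigment
frame; the environment is always co-transformed with the pigment.

The Stark analysis consumes printed energy-vs-field tables: shifts are
differences against the zero-field row, the susceptibility ratio compares
the largest absolute shift per pigment group, and `difference_dipole_fit`
summarizes the scan with a first-order Stark model `ΔE = −Δμ·F` from ±
pairs.  The large residuals of that fit for Chl-c (+y response an order of
magnitude beyond the −y one) are themselves the result: the Chl-c response
is strongly one-sided, beyond a linear Stark picture.

## Spectral densities and trajectories

Model baths combine a Drude term `J(ω)=2λωγ/(ω²+γ²)` with underdamped
Brownian-oscillator modes `J(ω)=2λ_jω_j²γ_jω/((ω²−ω_j²)²+γ_j²ω²)`.
Reorganization energies are `(1/π)∫J/ω dω` by trapezoid with the
origin-segment included analytically (J vanishes linearly at ω→0).

Trajectory synthesis uses random-phase Fourier synthesis of a stationary
Gaussian process with classical power spectrum `S(ω) = (2k_BT/π)·J(|ω|)/|ω|`,
giving variance `2k_BTλ`; a hard error enforces `dt < 1/(4c·ω_max)`.
Extraction computes the unbiased autocorrelation up to 1/8 of the record
(a bias/variance compromise: long enough for the slowest default bath
component, short enough to keep periodogram noise at the few-percent
level), tapers with a Hann half-window, zero-pads ×4, and applies the
harmonic prefactor `J(ω) = 2πc·βω·∫C(t)cos(2πcωt)dt`.  This prefactor is
chosen to make synthesis→extraction an identity in expectation — the
round trip over 20 realizations of 16 k samples recovers the default
Chl-a bath within ~5% RMS on its support.

Default baths (the synthetic stand-ins for the pigment spectral
densities): both pools share Drude λ=40 cm⁻¹, γ=40 cm⁻¹; Chl-a adds modes
at 750, 1150, 1520 cm⁻¹ with λ = 30, 45, 35 cm⁻¹ and widths of 20 cm⁻¹;
Chl-c carries the same modes at 0.3× intensity.  Positions follow typical
chlorophyll intramolecular frequencies; intensities were set so the
absorption vibronic sideband is Chl-a-dominated, and widths to a ~250 fs
vibrational dephasing time.  These are configuration values, not constants.

## Cumulant absorption

Per-site lineshape functions
`g(t) = (1/π)∫dω J/ω² [coth(βω/2)(1−cosωt) + i(sinωt−ωt)]`
are combined secularly per exciton with participation weights `|c_nk|⁴`
(and λ_k likewise).  Because the `−iωt` term already carries the
`−2πcλt` asymptote, the stick position of exciton k is its vertical energy
`E_k`; the lineshape then shifts the peak toward `E_k−λ_k`.  This keeps the
first-moment sum rule exact: the mean of `A(ω)/ω` for a single site equals
the site energy (verified to <1 cm⁻¹).  The secular form is exact for
uncoupled aggregates and a documented approximation otherwise; the NISE
linear response is kept as a second, independent absorption engine, and the
two agree on peak positions within ~10 cm⁻¹ for a motional-narrowing Drude
dimer.  No static disorder is added.  Spectra are reported on a 1 cm⁻¹ grid
over [12000, 20000] cm⁻¹ by default; lifetime broadening is off unless an
apodization time is supplied.

## NISE dynamics and 2DES

Propagation is stepwise-unitary: `ψ ← exp(−i·2πc·H(t_i)·dt)·ψ` from the
eigendecomposition of each instantaneous Hamiltonian (dt = trajectory step,
default 2 fs), norm-conserving to machine precision.  Population transfer
averages over all Chl-a initial sites and trajectory realizations; the
long-time limit of a symmetric dimer is equal population (the classical-bath
high-temperature limit of the method, checked by simulation).

The 2DES engine accumulates the six double-sided pathways (GSB, SE, ESA ×
rephasing/non-rephasing) with cumulative one- and two-exciton propagators,
contracts the four transition dipoles with the isotropic ⟨xxxx⟩ weights
`(1/15)(δδ+δδ+δδ)`, apodizes t₁ and t₃ with a cosine-squared window, and
transforms with explicit DFT kernels onto the requested frequency grids
(the exciton band plus vibronic sidebands fits within one Nyquist period of
the 2 fs sampling, so no rotating frame is needed).  Sign convention:
bleach positive, induced absorption negative; the stored data are linear
(any arcsin contour scaling is a plotting matter).  For uncoupled sites the
GSB/SE cross terms cancel the ESA exactly pathway-by-pathway; the standing
regression test verifies the two-site spectrum equals the sum of the
isolated single-site spectra to machine precision, which isolates the
cancellation from finite-window Fourier leakage of the diagonal peaks.

Waiting-time traces average the signed signal over a square diagonal
region, normalized at t₂ = 0.  With the sparse three-mode synthetic bath
the vibronic diagonal feature beats coherently (vibrational dephasing
~250 fs) instead of damping within 50 fs, so its normalized trace depends
strongly on the network realization and can overshoot or invert.  The fast
decay to ~20% at 50 fs reported for the real system requires the dense
many-mode pigment spectral densities; the synthetic runs establish the
qualitative contrast — main-band trace near unity, vibronic trace changing
completely on tens of fs — not that number.

`forster_transfer_time` computes `k = 2π·(2πc)·J²·∫L_D L_A dω` (the
`2πc` is 1/ħ in these units) from unit-area lineshapes.  With the default
baths' single-site lineshapes and the 25 cm⁻¹ maximum inter-pool coupling
it gives ~2.4 ps, consistent with the picosecond NISE transfer; the exact
value depends entirely on the lineshape overlap supplied.

## Synthetic data

`make_network` generates the study conditions: 9 pigments labeled
401–410 (CLC403 = Chl-c2, CLC408 = Chl-c1), Chl-a site energies
14950 ± 80 cm⁻¹ and Chl-c 14600 ± 80 cm⁻¹ with the Chl-c2 site forced
red-most (the in-protein energy ladder), dipole magnitudes 4.0 D (Chl-a)
and 2.4 D (Chl-c, 0.6×), random non-overlapping geometry (≥8 Å spacing),
point-dipole couplings rescaled so the largest Chl-a/Chl-c coupling is
exactly 25 cm⁻¹.  Energy means put the main absorption band near
14900–15000 cm⁻¹ and the Chl-a modes place vibronic sidebands near
16100–16500 cm⁻¹, matching the diagonal regions analyzed.  The generator
does not emulate the real FCP geometry beyond counts, labels, dipole ratio
and coupling scale; consequently passing tests demonstrate the machinery
and the coupling-scale physics (picosecond inter-pool transfer, Chl-a
dominated absorption, vibronic sideband origin), not pigment-specific
energies.  `make_environment` builds charge shells that reproduce a
prescribed field at a probe atom exactly (analytic corrector charge), with
decoy charges so the superposition is nontrivial.

## Numerical choices and degenerate inputs

Eigendecompositions via LAPACK (`eigh`); ladder ties broken by label;
trapezoid quadrature on the native grids with documented origin handling;
FFT-based spectra use 4× zero padding and interpolation onto the reporting
grid; the t₂ = 0 DFT samples carry half weight (trapezoid in time).
Degenerate inputs fail loudly: asymmetric Hamiltonians (>10⁻⁶ cm⁻¹ on
read, >10⁻⁹ on construction), collinear ring nitrogens, evaluation points
on charges, flat spectra in `align_shift`, missing ± pairs in the Stark
fit, Nyquist-violating sampling steps, and norm drift beyond 10⁻⁶.

## Reproducibility

Every stochastic stage takes a seed; ensembles spawn child seeds from one
master `SeedSequence`.  The pipeline driver validates its configuration
(unknown keys rejected), logs every stage with a configuration hash, and
reruns byte-identically for the same configuration and seed.

## Problem sizes

Default analysis runs use a 9-site network, 20-realization bath round
trips of 16 k samples, 30-realization population ensembles over 2 ps, and
6–10-realization 2DES grids of 96×96 time points over two waiting times —
sizes chosen so the full chain (tests, analysis scripts, acceptance
script) completes on a single CPU in minutes.  All realization counts and
grids are arguments, so larger production runs only change a number.

## Known limitations

Secular cumulant (no non-secular lineshape corrections); site-diagonal
fluctuations only, static couplings; classical (high-temperature) bath in
NISE, hence no detailed balance — pool populations equilibrate toward
uniformity rather than Boltzmann weights; parallel ⟨xxxx⟩ polarization
only; no finite pulse envelopes (the absence of experimental oscillations
attributed to pulse duration is therefore outside the model); point-dipole
couplings in the generator (no transition-charge or screening effects);
c1/c2 assignment from structure files requires a user map, since PDB
residue names do not distinguish them.
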