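# Methods

## Model

`qclines` treats a molecular aggregate as a Frenkel-exciton system: one
two-level chromophore per site, excitation energies `ε_n` and resonance
couplings `J_mn` (cm⁻¹), each site coupled linearly to its own set of
harmonic bath oscillators written in dimensionless coordinates,

    H = H_S + Σ_{n,ν} (ω_nν/2)(P²_nν + R²_nν) − Σ_{n,ν} ω_nν d_nν R_nν |n⟩⟨n|.

The per-site reorganization energy is `λ_n = Σ_ν ω_nν d_nν²/2`.  Units:
energies and frequencies in cm⁻¹, time in fs, dipoles in debye, ħ = 1
(a wavenumber `w` maps to the angular frequency `2πc·w` with `c` in
cm/fs).  The optical coupling connects the common ground state `|0⟩` to
each one-exciton state with transition dipole `μ_0n = μ_n0`; `|0⟩`
carries no bath coupling.

Two spectral densities are built in.  The Debye form
`J(w) = 2λγw/(w²+γ²)` is parameterized by the reorganization energy λ
and the bath relaxation time `γ⁻¹` (fs).  The B777 form — the standard
two-term fit to the fluorescence line-narrowing spectrum of the
bacteriochlorophyll B777 complex, here in the convention
`λ = (1/π)∫J(w)/w dw` —

    J(w) = πS/(s₁+s₂) Σ_k s_k/(2·7!·w_k⁴) w⁵ e^{−(w/w_k)^{1/2}},

uses `s₁ = 0.8`, `s₂ = 0.5`, `w₁ = 0.557 cm⁻¹`, `w₂ = 1.936 cm⁻¹` and
scales linearly with the Huang–Rhys factor S; the closed-form
reorganization energy is `λ = (9!/7!)·S·(s₁w₁+s₂w₂)/(s₁+s₂) ≈ 78.3·S`
cm⁻¹, so S = 0.5 corresponds to λ ≈ 39 cm⁻¹.

### Bath discretization

The continuum J(w) is represented by `K` modes per site.  The default
`quantile` scheme places nodes at equal increments of the cumulative
reorganization integral up to a coverage fraction `q = 0.999`, giving
every mode the same weight `qλ/K`; the discrete reorganization energy
then equals `qλ` by construction (0.1% closure).  Equally spaced
frequencies (`linear` scheme) are also available; because a midpoint
rule badly under-resolves the sharply peaked λ-density of the Debye
form, the linear weights are rescaled so the same closure holds — the
closure invariant, not the node placement, is the contract.  The
quantile default matters dynamically: equal spacing at practical mode
counts produces bath recurrences at `2π/Δω`, of order 100 fs for the
Debye parameters used here, which would corrupt the 1–2 ps
equilibration phase of a fluorescence run; quantile nodes concentrate
where the λ-density lives and push recurrences beyond the simulated
window.  Defaults: K = 100 (Debye) / 200 (B777) per site; the
fluorescence pipelines use K = 60 at desk scale.

### Initial conditions

Bath modes are sampled from the thermal Wigner distribution of a
harmonic oscillator: independent Gaussians in (R, P) with variance
`coth(βω/2)/2` per variable — zero-point width 1/2 at T → 0, classical
`kT/ω` at high temperature.  This reproduces the exact short-time
(Gaussian) decay of the optical response including the quantum
high-frequency modes.

Mapping variables represent each electronic state by a fictitious
oscillator.  All mapping variables are sampled i.i.d. standard normal;
with the estimator weights below this measure is self-normalizing
(propagating the identity returns the identity exactly in expectation
for any norm-conserving dynamics).

## Trajectory engines

Writing `c_j = q_j + i p_j`, both engines rotate the mapping variables
under the bath-dressed subsystem Hamiltonian
`h(R) = H_S − diag(Σ_ν ω_nν d_nν R_nν)`; the engines differ in the bath
force and in the estimator:

* **FBTS**: two copies c (forward) and c′ (backward), both rotating
  under h(R); the bath oscillator (n, ν) advances about the displaced
  center `d_nν·w_n` with the copy-averaged mapping weight
  `w_n = (|c_n|² + |c′_n|²)/4`.  A time-evolved operator element is
  estimated per trajectory as

      A_{ll'}(t) ≈ (1/2) c_l(0) c′*_{l'}(0) · (1/2) Σ_{mm'} A_{mm'} c*_m(t) c′_{m'}(t).

* **PBME-nH**: one copy; the bath force uses population-normalized
  weights `w_n = |c_n|²/Σ_k|c_k|²` (the non-Hamiltonian correction that
  removes the inverted-potential pathology of plain PBME; the plain
  variant, weights `(|c_n|²−1)/2`, is retained behind a diagnostics-only
  flag and is not a supported production method).  The initial-time
  weight is `(1/2) c_l c*_{l'} − δ_{ll'}`, the time-t factor as above
  with c′ → c.

In the uncoupled limit (λ → 0) both estimators reproduce the exact
subsystem Heisenberg evolution — the QCLE-exactness anchor for this
model class — and cost scales linearly with the total mode count.

### Integrator

One step of size h: (i) advance every bath mode analytically by h/2
about its current displaced center and accumulate the exact path
integral `∫R dτ`; (ii) apply the resulting diagonal mapping phases and
the constant resonance-coupling rotation `exp(−iJh)` (precomputed
eigendecomposition); (iii) recompute the mapping weights (invariant
under the pending diagonal phases, which keeps the step time-symmetric)
and advance the bath the second h/2, feeding the second diagonal
phase.  Using the analytically integrated bath path instead of frozen
endpoint values is what lets the highest quantile modes (ωh ≫ 1) pass
through the splitting without stability or aliasing problems.  The
symmetric base step is composed to 4th order (Yoshida) by default;
halving dt = 1 fs changes propagated dipole elements at t = 500 fs by
≲2×10⁻⁷ on the dimer benchmark.  Defaults: dt = 1 fs, 0.25 fs when
γ⁻¹ ≤ 35 fs.  Non-finite trajectories are dropped and counted; a run
fails if more than 0.1% drop.

### Monte-Carlo plumbing

Each trajectory i of a run with master seed s draws from the spawned
substream `SeedSequence(s, spawn_key=(i,))`, so results are bitwise
reproducible regardless of chunking or execution order; the
fluorescence phase-2 redraws use substream indices offset by the
ensemble size.  Correlation functions are stored as slow envelopes
about a carrier (the mean site energy) so a 1–2 fs recording grid
resolves 12 000 cm⁻¹ transitions; the carrier is restored on the
spectrum axis.  Standard errors are accumulated per time point and
propagate as 1/√n.

## Absorption

`C(t) = (1/3)⟨μ̂ᴵ(t)·μ̂(0)⟩` starting from `|0⟩⟨0| ⊗ ρ_B(thermal)`;
the 1/3 is the analytic isotropic orientational average.  The spectrum
is the half-axis transform `I(w) = Re∫₀^∞ C(t) e^{+i2πcwt} dt`
(trapezoidal; with this convention the prefactor-free integral over
wavenumber equals `C(0)/2c`).  Optional ω prefactor (used for FMO
absorption in the frequency-weighted convention), ground-state offset
(the dimer's 15 000 cm⁻¹), optional exponential apodization, unit-max
normalization.  Static Gaussian site-energy disorder is redrawn per
trajectory, so disorder averaging adds no cost; the 7/8-BChl sample
composition is a 0.65/0.35 weighted sum of two runs.

## Fluorescence

Two phases.  **Equilibration**: sample mapping + bath, propagate the
coupled equations to t1 (defaults 1 ps dimer / 2 ps FMO) on the excited
manifold, starting from the impulsive dipole-weighted state
`ρ ∝ μ̂|0⟩⟨0|μ̂` (single-site and uniform starts available).  The
subsystem matrix ρ_S(t1) is estimated by projector propagation; the
propagated bath phase points at t1 are the captured bath ensemble.  A
plateau check warns when any global-basis population still drifts more
than 1% over the final 200 fs (at 77 K the PBME-nH projector estimate
does drift — a known low-temperature weakness of the method; the warning
is informative in Jeff mode, escalated to an error above 5% drift in
dynamical runs).  The mean bath energy trace is recorded as the
dissipation diagnostic.  **Emission**: `C(t) = (1/3)Σ_a Σ_{mn} ρ_nm
μ_{n,a} [μ̂_a(t)]_{m0}` over the captured ensemble, transformed with
the opposite-sign kernel `e^{−i2πcwt}`; optional ω³ prefactor (off by
default).

In the **Jeff hybrids** ρ_S(t1) is replaced by the Boltzmann state of
the effective Hamiltonian

    H_eff = H_ε + e^{−βΛ/6} H_J e^{−βΛ/6},   Λ = diag({λ_n}),

with λ_n taken from the configured spectral density; the phase-space
ensemble is still propagated dynamically to t1, and the subsystem
mapping variables at t1 are kept and continued through the emission
phase (fresh variables are drawn only for the ground-state slot).  The
effective-coupling approximation weakens at low temperature, for fast
baths and at very strong coupling, but in the regimes covered here it
tracks exact equilibrium coherences to a few percent.  Emission spectra
from PBME-nH-family methods are red-shifted by λ/2 afterwards — an
empirical correction for the systematic blue shift of those methods —
recorded in the spectrum metadata and guarded against double
application.

## Numerical and design choices

* Equation-of-motion and estimator conventions are pinned by executable
  invariants (identity-estimator sanity, free-limit exactness,
  cross-engine agreement on the dimer absorption) rather than by any
  particular normalization tradition; the documented standard-normal
  measure plus the weights above form a consistent set.  The PBME trace
  subtraction is placed on the time-t estimator factor; the alternative
  (initial-time) placement passes the same invariants but degrades the
  long-time equilibrium coherence on the strong-coupling dimer
  benchmark from ~16% to ~60% error against the effective-coupling
  value, so the time-t placement is the package convention.  The FBTS
  dynamical equilibrium underestimates the same coherence by ~35% —
  consistent with its generally poorer equilibrium matrices and the
  motivation for the Jeff hybrids.
* The effective-coupling exponent β(λ_m+λ_n)/6 was fixed against the
  worked 7-site FMO equilibrium example that the theory must reproduce
  (populations 0.95/0.026, dipole strengths 21/54 D² at 77 K).
* Peak detection smooths the normalized spectrum with a 3-point
  [1, 2, 1]/4 window; plateau ties resolve toward lower wavenumber.
* Apodization default: none.  The emission correlation functions of the
  built-in fixtures decay to a few percent within the simulated window,
  so windowing is not needed for convergence, and a resolution study on
  the FMO emission showed that exponential apodization (e.g. 250 fs,
  ~21 cm⁻¹ of added Lorentzian width) systematically depresses the
  dominant-to-secondary band-height ratio by ~20% by smearing the
  narrow secondary structure into the inter-band valley.  Apodization
  remains available as a config option and, when used, must be applied
  identically to any spectra being compared.
* Desk-scale problem sizes: 2×10⁴ trajectories and 100 modes/site for
  the FMO fluorescence band analysis (the same resolution study showed
  60 modes/site under-resolves the band ratio by ~10%, and that peak
  picking on noisier 10⁴-trajectory spectra biases the secondary band
  maximum upward, i.e. the measured band ratio downward, by ~10%),
  10³–10⁵ trajectories for the dimer properties.  These are the package's default study conditions;
  ensembles of 10⁶⁺ trajectories simply shrink the Monte-Carlo error
  bands.

## What the built-in models do and do not show

The dimer family and the FMO fixtures are complete, parameter-exact
study systems (printed Hamiltonian, dipoles, disorder widths), so tests
against them exercise the full pipeline.  They do not emulate
anharmonic or correlated baths, site-dependent spectral densities
(beyond per-site λ scaling), coherence transfer between non-orthogonal
dipoles in the dimer (its dipoles are perpendicular by construction),
or vibronic structure beyond what the harmonic spectral densities
carry.  Passing tests therefore validate the method implementation
under the stated model assumptions, not the photophysics of any real
sample preparation.

## Known limitations

* FBTS and PBME-nH inherit zero-point-energy leakage; PBME-nH can yield
  transiently negative populations at low temperature (reported, never
  silently renormalized), and emission lineshapes can contain genuine
  negative-intensity artifacts at strong coupling — these are preserved
  in the output.
* The quantum-classical emission of a multi-site aggregate carries the
  bath relaxation of *sampled* mapping populations, not of the physical
  equilibrium populations; the λ/2 rule compensates the resulting blue
  shift only on average.
* The half-axis transform assumes C(t) has decayed by t_max; a warning
  fires at |C(t_max)| > 0.1|C(0)|.
* Orientational averaging is isotropic; no polarization-resolved or
  circular-dichroism observables.
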