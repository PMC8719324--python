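"""Dipole-dipole correlation functions and optical lineshapes.

The absorption lineshape is the half-axis Fourier transform

    I_abs(w)  = Re Int_0^inf dt C(t) exp(+i 2 pi c w t),
    I_fluo(w) = Re Int_0^inf dt C(t) exp(-i 2 pi c w t),

of the orientationally averaged dipole-dipole correlation function
C(t) = (1/3) < mu^I(t) . mu(0) >, the (1/3) being the analytic isotropic
average over molecular orientations.  Absorption starts from the
electronic ground state with the bath in thermal (Wigner) equilibrium;
fluorescence starts from the excited-state equilibrium (subsystem matrix
plus relaxed bath ensemble) produced by :mod:`qclines.equilibrium`.

Dimensional prefactors (w/2 hbar eps0 c n_r for absorption, w^3/3 pi^2
hbar eps0 c^3 for emission) are dropped; the optional ``omega_prefactor``
/ ``omega_cubed`` flags multiply the lineshape by w or w^3 when the
frequency-weighted convention is wanted.  Correlation functions are
stored as slow envelopes about a carrier wavenumber (the mean site
energy); the carrier and any ground-state offset are restored on the
spectrum axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bath import DiscretizedBath
from .engines import (_METHOD_CODES, EngineConfig, TrajectoryEnsemble,
                      _correlation_kernel, _prepare, _record_times,
                      draw_ensemble)
from .equilibrium import EquilibriumState
from .sampling import trajectory_rng
from .systems import DisorderSpec, ExcitonSystem
from .units import ANG_PER_CM

__all__ = [
    "CorrelationRecord",
    "Spectrum",
    "absorption_correlation",
    "fluorescence_correlation",
    "spectrum_from_correlation",
    "apply_half_lambda_redshift",
    "ensemble_average",
    "find_peaks",
]


@dataclass
class CorrelationRecord:
    """Complex correlation envelope on a uniform time grid."""

    times: np.ndarray        # fs
    values: np.ndarray       # complex C(t) envelope
    stderr: np.ndarray       # per-point MC standard error (magnitude)
    n_trajectories: int
    kind: str                # "absorption" or "fluorescence"
    carrier: float = 0.0     # cm^-1 removed from the phase evolution
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("absorption", "fluorescence"):
            raise ValueError(f"unknown correlation kind {self.kind!r}")
        if np.any(self.stderr < 0):
            raise ValueError("standard errors must be non-negative")


@dataclass
class Spectrum:
    """Real lineshape on a strictly increasing wavenumber grid."""

    wavenumbers: np.ndarray  # cm^-1
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")

    def normalized(self) -> "Spectrum":
        m = float(np.max(self.intensity))
        meta = dict(self.meta, normalized=True)
        return Spectrum(self.wavenumbers.copy(), self.intensity / m, meta)


def _run_correlation(system, bath, ensemble, config, falpha, e_ref,
                     kind, drop_tolerance=1e-3):
    prep = _prepare(system, bath, config, True, e_ref,
                    ensemble.site_energies)
    n_rec = config.n_steps // config.record_every + 1
    sum_re = np.zeros(n_rec)
    sum_im = np.zeros(n_rec)
    sum_re2 = np.zeros(n_rec)
    sum_im2 = np.zeros(n_rec)
    n_kept, n_drop = _correlation_kernel(
        ensemble.c0, ensemble.cb0, ensemble.R0, ensemble.P0,
        prep["eps_ang"], np.ascontiguousarray(falpha),
        np.ascontiguousarray(system.dipoles),
        prep["UJ"], prep["sub_h"], prep["cth"], prep["sth"],
        prep["swo"], prep["cwo"], prep["dcoup"], prep["g_ang"],
        _METHOD_CODES[ensemble.method], config.n_steps,
        config.record_every, sum_re, sum_im, sum_re2, sum_im2)
    if n_drop > drop_tolerance * ensemble.n_traj:
        raise FloatingPointError(
            f"{n_drop}/{ensemble.n_traj} trajectories dropped as "
            "non-finite")
    mean = (sum_re + 1j * sum_im) / n_kept
    var = (sum_re2 / n_kept - (sum_re / n_kept) ** 2
           + sum_im2 / n_kept - (sum_im / n_kept) ** 2)
    stderr = np.sqrt(np.maximum(var, 0.0) / n_kept)
    return CorrelationRecord(
        times=_record_times(config), values=mean, stderr=stderr,
        n_trajectories=n_kept, kind=kind, carrier=e_ref,
        meta=dict(method=ensemble.method, n_dropped=n_drop,
                  seed=ensemble.master_seed))


def absorption_correlation(system: ExcitonSystem, bath: DiscretizedBath,
                           temperature: float, config: EngineConfig,
                           n_traj: int, seed: int,
                           disorder: Optional[DisorderSpec] = None
                           ) -> CorrelationRecord:
    """Monte-Carlo estimate of the absorption dipole-dipole correlation
    function, starting from the ground state and the thermal bath.
    Static disorder, when given, is redrawn per trajectory."""
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    ens = draw_ensemble(system, bath, config.method, temperature, n_traj,
                        seed, include_ground=True, disorder=disorder)
    e_ref = float(np.mean(system.site_energies))
    mu = system.dipoles
    back = ens.cb0 if config.method == "fbts" else ens.c0
    # f_alpha = (1/6) c_0(0) sum_n mu_na conj(c'_n(0))
    falpha = (1.0 / 6.0) * ens.c0[:, 0:1] * (np.conj(back[:, 1:]) @ mu)
    rec = _run_correlation(system, bath, ens, config, falpha, e_ref,
                           "absorption")
    rec.meta["temperature"] = temperature
    return rec


def fluorescence_correlation(system: ExcitonSystem, bath: DiscretizedBath,
                             eq_state: EquilibriumState,
                             config: EngineConfig, seed: int,
                             reuse_mapping: bool = False
                             ) -> CorrelationRecord:
    """Monte-Carlo estimate of the emission dipole-dipole correlation
    function from the captured equilibrium.

    The bath phase points of ``eq_state.ensemble`` (already propagated to
    t1) are used as initial conditions.  Fresh mapping variables are
    drawn for the enlarged (ground + excited) space; with
    ``reuse_mapping=True`` (the Jeff refinement) the excited-state
    mapping variables kept from the equilibration phase are continued and
    only the ground-state oscillator is drawn fresh.
    """
    ens1 = eq_state.ensemble
    if ens1 is None:
        raise ValueError("equilibrium state carries no bath ensemble")
    n_traj = ens1.n_traj
    n_sites = system.n_sites
    n_map = n_sites + 1
    c2 = np.empty((n_traj, n_map), dtype=np.complex128)
    cb2 = np.zeros((n_traj, n_map), dtype=np.complex128)
    fbts = config.method == "fbts"
    for i in range(n_traj):
        rng = trajectory_rng(ens1.master_seed, n_traj + i)
        if reuse_mapping:
            g = rng.normal(size=4 if fbts else 2)
            c2[i, 1:] = ens1.c0[i]
            c2[i, 0] = g[0] + 1j * g[1]
            if fbts:
                cb2[i, 1:] = ens1.cb0[i]
                cb2[i, 0] = g[2] + 1j * g[3]
        else:
            g = rng.normal(size=(4 if fbts else 2, n_map))
            c2[i] = g[0] + 1j * g[1]
            if fbts:
                cb2[i] = g[2] + 1j * g[3]
    ens2 = TrajectoryEnsemble(c0=c2, cb0=cb2, R0=ens1.R0, P0=ens1.P0,
                              site_energies=ens1.site_energies,
                              method=config.method,
                              master_seed=ens1.master_seed,
                              include_ground=True)
    rho = np.asarray(eq_state.rho_site, dtype=np.complex128)
    if rho.shape != (n_sites, n_sites):
        raise ValueError("equilibrium matrix size does not match system")
    mu = system.dipoles
    U = rho.T @ mu                          # U[m, a] = sum_n rho_nm mu_na
    front = cb2 if fbts else c2
    falpha = (1.0 / 6.0) * np.conj(front[:, 0:1]) * (c2[:, 1:] @ U)
    e_ref = float(np.mean(system.site_energies))
    rec = _run_correlation(system, bath, ens2, config, falpha, e_ref,
                           "fluorescence")
    rec.meta["equilibrium_source"] = eq_state.source
    rec.meta["reuse_mapping"] = reuse_mapping
    return rec


def default_grid(record: CorrelationRecord, ground_offset: float = 0.0,
                 halfwidth: float = 1200.0, spacing: float = 2.0
                 ) -> np.ndarray:
    """Wavenumber grid centered on the carrier plus offset."""
    center = record.carrier + ground_offset
    return np.arange(center - halfwidth, center + halfwidth + spacing,
                     spacing)


def spectrum_from_correlation(record: CorrelationRecord,
                              wavenumbers: Optional[np.ndarray] = None,
                              ground_offset: float = 0.0,
                              omega_prefactor: bool = False,
                              omega_cubed: bool = False,
                              normalize: bool = True,
                              apodization_fs: Optional[float] = None,
                              decay_warn_fraction: float = 0.1) -> Spectrum:
    """Half-axis Fourier transform of the correlation function.

    The transform kernel sign follows the record kind (positive
    frequencies for absorption, the opposite sign for emission).  The
    carrier and ``ground_offset`` shift the wavenumber axis.  Negative
    intensities are preserved.  With this convention the integral of the
    unnormalized, prefactor-free absorption lineshape over wavenumber
    equals C(0)/(2c) with c in cm/fs.
    """
    if wavenumbers is None:
        wavenumbers = default_grid(record, ground_offset)
    t = record.times
    vals = record.values.copy()
    if apodization_fs:
        vals = vals * np.exp(-t / apodization_fs)
    tail = np.abs(vals[-1])
    if tail > decay_warn_fraction * max(np.abs(vals[0]), 1e-30):
        warnings.warn(
            f"|C(t_max)| is {tail / np.abs(vals[0]):.2f} of |C(0)|; "
            "the spectrum may show truncation ripple", stacklevel=2)
    sign = +1.0 if record.kind == "absorption" else -1.0
    # detuning of each grid point from the stored envelope carrier
    detune = np.asarray(wavenumbers, dtype=float) - ground_offset \
        - record.carrier
    phase = np.exp(1j * sign * ANG_PER_CM * np.outer(detune, t))
    intensity = np.trapezoid(np.real(phase * vals[None, :]), t, axis=1)
    if omega_prefactor:
        intensity = intensity * np.abs(wavenumbers)
    if omega_cubed:
        intensity = intensity * np.abs(wavenumbers) ** 3
    meta = dict(record.meta)
    meta.update(kind=record.kind, carrier=record.carrier,
                ground_offset=ground_offset,
                omega_prefactor=omega_prefactor, omega_cubed=omega_cubed,
                apodization_fs=apodization_fs,
                n_trajectories=record.n_trajectories,
                normalized=bool(normalize))
    spec = Spectrum(np.asarray(wavenumbers, dtype=float), intensity, meta)
    if normalize:
        spec = spec.normalized()
        spec.meta = meta | {"normalized": True}
    return spec


def apply_half_lambda_redshift(spectrum: Spectrum, lam: float) -> Spectrum:
    """Red-shift a PBME-nH-family fluorescence spectrum by lambda/2.

    Empirical correction: emission lineshapes from PBME-nH and
    PBME-nH-Jeff come out blue-shifted by at least lambda/2 relative to
    numerically exact references, so the wavenumber axis is lowered by
    lambda/2.  Guarded against double application via metadata.
    """
    if spectrum.meta.get("kind") != "fluorescence":
        raise ValueError("the lambda/2 shift applies to fluorescence "
                         "spectra only")
    method = spectrum.meta.get("method", "pbme_nh")
    if not str(method).startswith("pbme_nh"):
        raise ValueError("the lambda/2 shift applies to PBME-nH-family "
                         "methods only")
    if "half_lambda_shift" in spectrum.meta:
        raise ValueError("lambda/2 shift already applied")
    shift = 0.5 * float(lam)
    meta = dict(spectrum.meta, half_lambda_shift=shift)
    return Spectrum(spectrum.wavenumbers - shift,
                    spectrum.intensity.copy(), meta)


def ensemble_average(spectra: Sequence[Spectrum],
                     weights: Sequence[float]) -> Spectrum:
    """Weighted sum of spectra on a common grid (weights sum to one);
    used for the 65/35 mixture of 7- and 8-BChl FMO complexes."""
    weights = np.asarray(weights, dtype=float)
    if len(spectra) != weights.size:
        raise ValueError("one weight per spectrum required")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.wavenumbers.shape != grid.shape or \
                not np.allclose(s.wavenumbers, grid):
            raise ValueError("spectra must share a common grid")
    intensity = sum(w * s.intensity for w, s in zip(weights, spectra))
    meta = dict(spectra[0].meta)
    meta["mixture_weights"] = weights.tolist()
    return Spectrum(grid.copy(), intensity, meta)


def find_peaks(spectrum: Spectrum, min_rel_height: float = 0.02):
    """Local maxima of the 3-point-smoothed lineshape.

    Returns a list of (wavenumber, unsmoothed intensity) sorted by
    descending intensity; plateau ties resolve toward lower wavenumber.
    """
    y = spectrum.intensity
    ys = np.convolve(y, [0.25, 0.5, 0.25], mode="same")
    ys[0] = y[0]
    ys[-1] = y[-1]
    floor = min_rel_height * np.max(ys)
    peaks = []
    for i in range(1, y.size - 1):
        if ys[i] > ys[i - 1] and ys[i] >= ys[i + 1] and ys[i] >= floor:
            peaks.append((float(spectrum.wavenumbers[i]), float(y[i])))
    peaks.sort(key=lambda p: -p[1])
    return peaks
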