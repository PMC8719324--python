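"""Trajectory propagation for the quantum-classical Liouville equation
(QCLE) mapping solutions.

Two engines are provided.  FBTS (forward-backward trajectory solution)
doubles the subsystem mapping space into forward variables ``c = q + ip``
and backward variables ``c' = q' + ip'``; both rotate under the
bath-dressed subsystem Hamiltonian ``h(R)`` while the bath feels the
mean of the forward and backward mapping populations.  PBME-nH (the
non-Hamiltonian variant of the Poisson-bracket mapping equation) carries
one mapping copy; its bath force uses population-normalized mapping
weights ``|c_n|^2 / sum_k |c_k|^2``, which is the non-Hamiltonian
correction that removes the inverted-potential pathology of plain PBME
(the plain variant is retained behind ``method="pbme"`` for diagnostics
only).

A time-evolved operator matrix element is estimated per trajectory as
``A_{ll'}(t) = f_{ll'}(x(0)) * g_A(x(t))`` with the initial-time weight
``f_{ll'} = (1/2) c_l c'*_{l'}`` (FBTS; c' -> c for the PBME family) and
``g_A = (1/2) sum_{mm'} A_{mm'} c*_m(t) c'_{m'}(t)``, minus ``Tr A`` for
the PBME family, the Gaussian sampling measure being standard normal per
mapping variable.  (The PBME trace subtraction may equivalently sit on
either factor as far as the identity invariant is concerned; placing it
on the time-t factor gives markedly more accurate long-time equilibrium
matrices, which is how the convention is fixed here.  Operators without
diagonal elements -- the optical dipole in particular -- are insensitive
to the choice.)
Propagating the identity with these conventions returns the identity in
expectation for arbitrary dynamics, and in the uncoupled limit the
estimator reproduces the exact subsystem Heisenberg evolution.

The integrator is a symmetric split step: the mapping variables rotate
under the diagonal (site-energy plus bath-shift) phases and the constant
resonance-coupling block in a Strang sandwich, while bath oscillators
advance analytically about their mapping-weighted displaced centers; the
diagonal mapping phases use the analytically integrated bath path, so
arbitrarily fast discretized modes are handled without stability limits.
A 4th-order Yoshida composition of this base step is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .bath import DiscretizedBath
from .sampling import sample_bath_wigner, sample_mapping, trajectory_rng
from .systems import DisorderSpec, ExcitonSystem, sample_disorder
from .units import ANG_PER_CM

__all__ = [
    "EngineConfig",
    "TrajectoryEnsemble",
    "OperatorTrajectory",
    "draw_ensemble",
    "propagate_trajectory",
    "evolve_dipole_operator",
    "propagate_projectors",
]

_METHOD_CODES = {"fbts": 0, "pbme_nh": 1, "pbme": 2}

# Yoshida 4th-order composition weights for a symmetric 2nd-order base step
_W1 = 1.0 / (2.0 - 2.0 ** (1.0 / 3.0))
_W0 = 1.0 - 2.0 * _W1


@dataclass(frozen=True)
class EngineConfig:
    """Propagation settings.

    dt is the composite step in fs; ``record_every`` counts steps between
    stored points.  ``integrator`` is ``"yoshida4"`` (default) or
    ``"split2"`` (the bare symmetric split step).
    """

    method: str = "fbts"
    dt: float = 1.0
    t_max: float = 500.0
    record_every: int = 1
    integrator: str = "yoshida4"

    def __post_init__(self):
        if self.method not in _METHOD_CODES:
            raise ValueError(f"unknown method {self.method!r}; "
                             f"choose from {sorted(_METHOD_CODES)}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_max < self.dt:
            raise ValueError("t_max must be at least dt")
        if self.integrator not in ("yoshida4", "split2"):
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt))

    @property
    def method_code(self) -> int:
        return _METHOD_CODES[self.method]

    @property
    def substeps(self) -> np.ndarray:
        if self.integrator == "split2":
            return np.array([self.dt])
        return np.array([_W1 * self.dt, _W0 * self.dt, _W1 * self.dt])


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=False)
def _mapping_weights(c, cb, method, so, w):
    n_sites = w.shape[0]
    if method == 0:  # FBTS: copy-averaged populations
        for n in range(n_sites):
            j = so + n
            w[n] = 0.25 * ((c[j].real ** 2 + c[j].imag ** 2)
                           + (cb[j].real ** 2 + cb[j].imag ** 2))
    elif method == 1:  # PBME-nH: normalized populations
        tot = 0.0
        for j in range(c.shape[0]):
            tot += c[j].real ** 2 + c[j].imag ** 2
        for n in range(n_sites):
            j = so + n
            w[n] = (c[j].real ** 2 + c[j].imag ** 2) / tot
    else:  # plain PBME (diagnostics only)
        for n in range(n_sites):
            j = so + n
            w[n] = 0.5 * (c[j].real ** 2 + c[j].imag ** 2 - 1.0)


@njit(cache=False)
def _substep(c, cb, R, P, eps_row, UJ, h, cth, sth, swo, cwo,
             dcoup, g_ang, method, so, w, phi, tmp):
    """One symmetric split step of size h (fs).  Bath halves advance
    analytically about displaced centers; the mapping diagonal phases use
    the integrated bath path over the step."""
    n_map = c.shape[0]
    n_sites = R.shape[0]
    K = R.shape[1]
    h2 = 0.5 * h

    # first bath half-step about the mapping-weighted centers; the
    # analytically integrated path feeds the first diagonal phase
    _mapping_weights(c, cb, method, so, w)
    for n in range(n_sites):
        ph = 0.0
        for v in range(K):
            s = dcoup[n, v] * w[n]
            dR = R[n, v] - s
            p0 = P[n, v]
            R[n, v] = s + dR * cth[v] + p0 * sth[v]
            P[n, v] = -dR * sth[v] + p0 * cth[v]
            ph += g_ang[n, v] * (s * h2 + dR * swo[v] + p0 * cwo[v])
        phi[so + n] = eps_row[so + n] * h2 - ph
    if so == 1:
        phi[0] = eps_row[0] * h2

    for j in range(n_map):
        e = np.exp(-1j * phi[j])
        c[j] = c[j] * e
        if method == 0:
            cb[j] = cb[j] * e

    # resonance-coupling rotation over the full step
    for j in range(n_map):
        acc = 0.0 + 0.0j
        for k in range(n_map):
            acc += UJ[j, k] * c[k]
        tmp[j] = acc
    for j in range(n_map):
        c[j] = tmp[j]
    if method == 0:
        for j in range(n_map):
            acc = 0.0 + 0.0j
            for k in range(n_map):
                acc += UJ[j, k] * cb[k]
            tmp[j] = acc
        for j in range(n_map):
            cb[j] = tmp[j]

    # second bath half-step (weights are invariant under the pending
    # diagonal phases, so this ordering keeps the step time-symmetric)
    _mapping_weights(c, cb, method, so, w)
    for n in range(n_sites):
        ph = 0.0
        for v in range(K):
            s = dcoup[n, v] * w[n]
            dR = R[n, v] - s
            p0 = P[n, v]
            R[n, v] = s + dR * cth[v] + p0 * sth[v]
            P[n, v] = -dR * sth[v] + p0 * cth[v]
            ph += g_ang[n, v] * (s * h2 + dR * swo[v] + p0 * cwo[v])
        phi[so + n] = eps_row[so + n] * h2 - ph
    if so == 1:
        phi[0] = eps_row[0] * h2
    for j in range(n_map):
        e = np.exp(-1j * phi[j])
        c[j] = c[j] * e
        if method == 0:
            cb[j] = cb[j] * e


@njit(cache=False)
def _dipole_g(c, cb, mu_e, method, gout):
    """G_alpha(t) = (1/2)[c*_0 (mu_a . c'_exc) + (mu_a . c*_exc) c'_0]
    for the three Cartesian components; PBME family uses c for both
    copies."""
    n_exc = mu_e.shape[0]
    for a in range(3):
        s1 = 0.0 + 0.0j
        s2 = 0.0 + 0.0j
        for n in range(n_exc):
            if method == 0:
                s1 += mu_e[n, a] * cb[1 + n]
            else:
                s1 += mu_e[n, a] * c[1 + n]
            s2 += mu_e[n, a] * np.conj(c[1 + n])
        if method == 0:
            gout[a] = 0.5 * (np.conj(c[0]) * s1 + s2 * cb[0])
        else:
            gout[a] = 0.5 * (np.conj(c[0]) * s1 + s2 * c[0])


@njit(cache=False)
def _correlation_kernel(c0, cb0, R0, P0, eps_ang, falpha, mu_e,
                        UJ, sub_h, cth, sth, swo, cwo, dcoup, g_ang,
                        method, n_steps, record_every,
                        sum_re, sum_im, sum_re2, sum_im2):
    """Accumulate the dipole-dipole correlation estimator over an
    ensemble.  Returns (n_kept, n_dropped)."""
    n_traj = c0.shape[0]
    n_map = c0.shape[1]
    n_sites = R0.shape[1]
    K = R0.shape[2]
    n_sub = sub_h.shape[0]
    n_rec = n_steps // record_every + 1

    w = np.empty(n_sites)
    phi = np.empty(n_map)
    tmp = np.empty(n_map, dtype=np.complex128)
    gbuf = np.empty(3, dtype=np.complex128)
    buf = np.empty(n_rec, dtype=np.complex128)
    c = np.empty(n_map, dtype=np.complex128)
    cb = np.empty(n_map, dtype=np.complex128)
    R = np.empty((n_sites, K))
    P = np.empty((n_sites, K))

    n_kept = 0
    n_drop = 0
    for i in range(n_traj):
        for j in range(n_map):
            c[j] = c0[i, j]
            cb[j] = cb0[i, j]
        for n in range(n_sites):
            for v in range(K):
                R[n, v] = R0[i, n, v]
                P[n, v] = P0[i, n, v]
        eps_row = eps_ang[i]

        _dipole_g(c, cb, mu_e, method, gbuf)
        acc = falpha[i, 0] * gbuf[0] + falpha[i, 1] * gbuf[1] \
            + falpha[i, 2] * gbuf[2]
        buf[0] = acc
        r = 1
        for k in range(1, n_steps + 1):
            for s in range(n_sub):
                _substep(c, cb, R, P, eps_row, UJ[s], sub_h[s],
                         cth[s], sth[s], swo[s], cwo[s],
                         dcoup, g_ang, method, 1, w, phi, tmp)
            if k % record_every == 0:
                _dipole_g(c, cb, mu_e, method, gbuf)
                buf[r] = falpha[i, 0] * gbuf[0] + falpha[i, 1] * gbuf[1] \
                    + falpha[i, 2] * gbuf[2]
                r += 1

        ok = True
        for r in range(n_rec):
            if not (np.isfinite(buf[r].real) and np.isfinite(buf[r].imag)):
                ok = False
                break
        if ok:
            n_kept += 1
            for r in range(n_rec):
                x = buf[r].real
                y = buf[r].imag
                sum_re[r] += x
                sum_im[r] += y
                sum_re2[r] += x * x
                sum_im2[r] += y * y
        else:
            n_drop += 1
    return n_kept, n_drop


@njit(cache=False)
def _equilibrate_kernel(c0, cb0, R0, P0, eps_ang, w0, omega_cm,
                        UJ, sub_h, cth, sth, swo, cwo, dcoup, g_ang,
                        method, n_steps, record_every,
                        rho_sum, bathE_sum):
    """Propagate subsystem projectors over the excited manifold,
    accumulating the equilibrium-matrix estimator and the mean bath
    energy.  Final phase-space states are written back into the input
    arrays.  Returns (n_kept, n_dropped)."""
    n_traj = c0.shape[0]
    n_map = c0.shape[1]
    n_sites = R0.shape[1]
    K = R0.shape[2]
    n_sub = sub_h.shape[0]
    n_rec = n_steps // record_every + 1

    w = np.empty(n_sites)
    phi = np.empty(n_map)
    tmp = np.empty(n_map, dtype=np.complex128)
    rho_buf = np.empty((n_rec, n_map, n_map), dtype=np.complex128)
    e_buf = np.empty(n_rec)

    n_kept = 0
    n_drop = 0
    for i in range(n_traj):
        c = c0[i]
        cb = cb0[i]
        R = R0[i]
        P = P0[i]
        eps_row = eps_ang[i]

        r = 0
        for k in range(n_steps + 1):
            if k > 0:
                for s in range(n_sub):
                    _substep(c, cb, R, P, eps_row, UJ[s], sub_h[s],
                             cth[s], sth[s], swo[s], cwo[s],
                             dcoup, g_ang, method, 0, w, phi, tmp)
            if k % record_every == 0:
                for m in range(n_map):
                    for n in range(n_map):
                        if method == 0:
                            rho_buf[r, m, n] = w0[i] * 0.5 * cb[m] \
                                * np.conj(c[n])
                        else:
                            # PBME family: the estimator's delta
                            # subtraction sits on the time-t factor
                            val = 0.5 * c[m] * np.conj(c[n])
                            if m == n:
                                val -= 1.0
                            rho_buf[r, m, n] = w0[i] * val
                eb = 0.0
                for n in range(n_sites):
                    for v in range(K):
                        eb += 0.5 * omega_cm[v] * (R[n, v] ** 2
                                                   + P[n, v] ** 2)
                e_buf[r] = eb
                r += 1

        ok = True
        for j in range(n_map):
            if not (np.isfinite(c[j].real) and np.isfinite(c[j].imag)):
                ok = False
        if ok:
            n_kept += 1
            for r in range(n_rec):
                bathE_sum[r] += e_buf[r]
                for m in range(n_map):
                    for n in range(n_map):
                        rho_sum[r, m, n] += rho_buf[r, m, n]
        else:
            n_drop += 1
    return n_kept, n_drop


@njit(cache=False)
def _operator_kernel(c0, cb0, R0, P0, eps_ang, A,
                     UJ, sub_h, cth, sth, swo, cwo, dcoup, g_ang,
                     method, so, n_steps, record_every,
                     g_out, record_bath, R_rec, P_rec):
    """Per-trajectory time series of g_A(t) = (1/2) sum A_mm' c*_m c'_m'.
    Optionally records the bath phase-space path of trajectory 0."""
    n_traj = c0.shape[0]
    n_map = c0.shape[1]
    n_sites = R0.shape[1]
    K = R0.shape[2]
    n_sub = sub_h.shape[0]

    w = np.empty(n_sites)
    phi = np.empty(n_map)
    tmp = np.empty(n_map, dtype=np.complex128)
    c = np.empty(n_map, dtype=np.complex128)
    cb = np.empty(n_map, dtype=np.complex128)
    R = np.empty((n_sites, K))
    P = np.empty((n_sites, K))

    for i in range(n_traj):
        for j in range(n_map):
            c[j] = c0[i, j]
            cb[j] = cb0[i, j]
        for n in range(n_sites):
            for v in range(K):
                R[n, v] = R0[i, n, v]
                P[n, v] = P0[i, n, v]
        eps_row = eps_ang[i]
        trA = 0.0 + 0.0j
        for m in range(n_map):
            trA += A[m, m]
        r = 0
        for k in range(n_steps + 1):
            if k > 0:
                for s in range(n_sub):
                    _substep(c, cb, R, P, eps_row, UJ[s], sub_h[s],
                             cth[s], sth[s], swo[s], cwo[s],
                             dcoup, g_ang, method, so, w, phi, tmp)
            if k % record_every == 0:
                acc = 0.0 + 0.0j
                for m in range(n_map):
                    for n in range(n_map):
                        if A[m, n] != 0.0:
                            if method == 0:
                                acc += A[m, n] * np.conj(c[m]) * cb[n]
                            else:
                                acc += A[m, n] * np.conj(c[m]) * c[n]
                g_out[i, r] = 0.5 * acc
                if method != 0:
                    g_out[i, r] -= trA
                if record_bath and i == 0:
                    for n in range(n_sites):
                        for v in range(K):
                            R_rec[r, n, v] = R[n, v]
                            P_rec[r, n, v] = P[n, v]
                r += 1


# ---------------------------------------------------------------------------
# python-level plumbing
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryEnsemble:
    """Monte-Carlo initial conditions (and, after equilibration, the
    propagated phase-space states) for a batch of trajectories."""

    c0: np.ndarray          # (n_traj, n_map) complex
    cb0: np.ndarray         # (n_traj, n_map) complex (zeros for PBME family)
    R0: np.ndarray          # (n_traj, n_sites, K)
    P0: np.ndarray          # (n_traj, n_sites, K)
    site_energies: np.ndarray  # (n_traj, n_sites) cm^-1, disorder included
    method: str = "fbts"
    master_seed: int = 0
    include_ground: bool = True

    @property
    def n_traj(self) -> int:
        return self.c0.shape[0]

    @property
    def n_map(self) -> int:
        return self.c0.shape[1]


def draw_ensemble(system: ExcitonSystem, bath: DiscretizedBath, method: str,
                  temperature: float, n_traj: int, master_seed: int,
                  include_ground: bool = True,
                  disorder: Optional[DisorderSpec] = None,
                  index_offset: int = 0) -> TrajectoryEnsemble:
    """Draw per-trajectory initial conditions from counter-based
    substreams of the master seed.  Per trajectory the draw order is:
    disorder shifts (if any), bath Wigner point, mapping variables."""
    if n_traj < 1:
        raise ValueError("ensemble must contain at least one trajectory")
    n_sites = system.n_sites
    n_map = n_sites + 1 if include_ground else n_sites
    K = bath.modes_per_site
    c0 = np.empty((n_traj, n_map), dtype=np.complex128)
    cb0 = np.zeros((n_traj, n_map), dtype=np.complex128)
    R0 = np.empty((n_traj, n_sites, K))
    P0 = np.empty((n_traj, n_sites, K))
    energies = np.empty((n_traj, n_sites))
    for i in range(n_traj):
        rng = trajectory_rng(master_seed, index_offset + i)
        sys_i = system
        if disorder is not None:
            sys_i = sample_disorder(system, disorder, rng)
        energies[i] = sys_i.site_energies
        bp = sample_bath_wigner(bath, temperature, rng)
        R0[i] = bp.Q
        P0[i] = bp.P
        mv = sample_mapping(method, n_map, rng)
        c0[i] = mv.c
        if method == "fbts":
            cb0[i] = mv.cb
    return TrajectoryEnsemble(c0=c0, cb0=cb0, R0=R0, P0=P0,
                              site_energies=energies, method=method,
                              master_seed=master_seed,
                              include_ground=include_ground)


def _prepare(system: ExcitonSystem, bath: DiscretizedBath,
             config: EngineConfig, include_ground: bool, e_ref: float,
             site_energies: np.ndarray):
    """Precompute the propagator tables shared by all trajectories."""
    n_sites = system.n_sites
    n_map = n_sites + 1 if include_ground else n_sites
    so = 1 if include_ground else 0

    # diagonal angular energies per trajectory (carrier e_ref removed)
    eps_ang = np.zeros((site_energies.shape[0], n_map))
    eps_ang[:, so:] = (site_energies - e_ref) * ANG_PER_CM

    # constant resonance-coupling block propagators, one per substep
    Jm = np.zeros((n_map, n_map))
    Jm[so:, so:] = system.couplings
    evals, vecs = np.linalg.eigh(Jm)
    sub_h = config.substeps
    UJ = np.empty((sub_h.size, n_map, n_map), dtype=np.complex128)
    for s, h in enumerate(sub_h):
        UJ[s] = (vecs * np.exp(-1j * evals * ANG_PER_CM * h)) @ vecs.T

    # bath rotation tables per substep (half-step angles)
    omega_ang = bath.omega[0] * ANG_PER_CM  # modes shared across sites
    cth = np.empty((sub_h.size, omega_ang.size))
    sth = np.empty_like(cth)
    swo = np.empty_like(cth)
    cwo = np.empty_like(cth)
    for s, h in enumerate(sub_h):
        th = omega_ang * (0.5 * h)
        cth[s] = np.cos(th)
        sth[s] = np.sin(th)
        swo[s] = np.sin(th) / omega_ang
        cwo[s] = (1.0 - np.cos(th)) / omega_ang
    g_ang = bath.omega * bath.d * ANG_PER_CM
    return dict(n_map=n_map, so=so, eps_ang=eps_ang, UJ=UJ, sub_h=sub_h,
                cth=cth, sth=sth, swo=swo, cwo=cwo,
                dcoup=np.ascontiguousarray(bath.d), g_ang=g_ang,
                omega_cm=np.ascontiguousarray(bath.omega[0]))


def _record_times(config: EngineConfig) -> np.ndarray:
    n_rec = config.n_steps // config.record_every + 1
    return np.arange(n_rec) * config.record_every * config.dt


@dataclass
class OperatorTrajectory:
    """Per-trajectory estimates of a time-evolved operator's matrix
    elements A_{ll'}(t), plus (optionally) the bath path of the first
    trajectory."""

    times: np.ndarray                    # (n_rec,) fs
    elements: np.ndarray                 # (n_traj, n_rec, n_map, n_map)
    weight: np.ndarray                   # (n_traj, n_map, n_map) f-weights
    bath_Q: Optional[np.ndarray] = None  # (n_rec, n_sites, K)
    bath_P: Optional[np.ndarray] = None


def _initial_weights(ens: TrajectoryEnsemble) -> np.ndarray:
    """f_{ll'}(x(0)) per trajectory (the PBME-family delta subtraction
    lives on the time-t factor, not here)."""
    c0 = ens.c0
    if ens.method == "fbts":
        f = 0.5 * c0[:, :, None] * np.conj(ens.cb0)[:, None, :]
    else:
        f = 0.5 * c0[:, :, None] * np.conj(c0)[:, None, :]
    return f


def propagate_trajectory(system: ExcitonSystem, bath: DiscretizedBath,
                         ensemble: TrajectoryEnsemble, config: EngineConfig,
                         operator: np.ndarray, e_ref: float = 0.0,
                         record_bath: bool = False) -> OperatorTrajectory:
    """Propagate the ensemble and return per-trajectory estimates of the
    time-evolved ``operator`` (an (n_map, n_map) matrix in the mapping
    space).  Diagonal site energies are measured relative to ``e_ref``
    (the carrier); the estimate of element (l, l') is
    ``weight[l,l'] * g(t)``."""
    prep = _prepare(system, bath, config, ensemble.include_ground, e_ref,
                    ensemble.site_energies)
    n_rec = config.n_steps // config.record_every + 1
    A = np.ascontiguousarray(operator, dtype=np.complex128)
    if A.shape != (prep["n_map"], prep["n_map"]):
        raise ValueError("operator shape does not match mapping space")
    g = np.empty((ensemble.n_traj, n_rec), dtype=np.complex128)
    n_sites, K = ensemble.R0.shape[1:]
    R_rec = np.empty((n_rec, n_sites, K) if record_bath else (1, 1, 1))
    P_rec = np.empty_like(R_rec)
    _operator_kernel(ensemble.c0, ensemble.cb0, ensemble.R0, ensemble.P0,
                     prep["eps_ang"], A, prep["UJ"], prep["sub_h"],
                     prep["cth"], prep["sth"], prep["swo"], prep["cwo"],
                     prep["dcoup"], prep["g_ang"],
                     _METHOD_CODES[ensemble.method], prep["so"],
                     config.n_steps, config.record_every,
                     g, record_bath, R_rec, P_rec)
    if not np.all(np.isfinite(g)):
        bad = np.where(~np.isfinite(g).all(axis=1))[0]
        raise FloatingPointError(
            f"non-finite mapping state in trajectories {bad[:5].tolist()}")
    f = _initial_weights(ensemble)
    elements = f[:, None, :, :] * g[:, :, None, None]
    return OperatorTrajectory(
        times=_record_times(config), elements=elements, weight=f,
        bath_Q=R_rec if record_bath else None,
        bath_P=P_rec if record_bath else None)


def evolve_dipole_operator(system: ExcitonSystem, bath: DiscretizedBath,
                           ensemble: TrajectoryEnsemble,
                           config: EngineConfig, e_ref: float = 0.0):
    """Monte-Carlo average of the time-evolved dipole operator.

    Returns (times, mean, stderr) where mean and stderr have shape
    (n_rec, 3, n_map, n_map): one matrix per Cartesian component.
    """
    if ensemble.n_traj < 1:
        raise ValueError("empty ensemble")
    if not ensemble.include_ground:
        raise ValueError("dipole evolution requires the ground state")
    n_map = ensemble.n_map
    out_mean = []
    out_err = []
    times = _record_times(config)
    for a in range(3):
        mu_op = np.zeros((n_map, n_map))
        mu_op[0, 1:] = system.dipoles[:, a]
        mu_op[1:, 0] = system.dipoles[:, a]
        traj = propagate_trajectory(system, bath, ensemble, config, mu_op,
                                    e_ref=e_ref)
        out_mean.append(traj.elements.mean(axis=0))
        out_err.append(traj.elements.std(axis=0)
                       / np.sqrt(max(ensemble.n_traj, 2)))
    mean = np.stack(out_mean, axis=1)
    err = np.stack(out_err, axis=1)
    return times, mean, err


def propagate_projectors(system: ExcitonSystem, bath: DiscretizedBath,
                         ensemble: TrajectoryEnsemble, config: EngineConfig,
                         rho0: np.ndarray, drop_tolerance: float = 1e-3):
    """Propagate the subsystem projectors |m><n| over the excited
    manifold, returning the estimated subsystem matrix against the
    initial state ``rho0`` at every recorded time, together with the mean
    bath energy trace.  The ensemble's phase-space arrays are advanced in
    place to the final time (the captured bath state).

    Returns (times, rho_t, bath_energy) with rho_t of shape
    (n_rec, N, N).
    """
    if ensemble.include_ground:
        raise ValueError("projector propagation runs on the excited "
                         "manifold only")
    prep = _prepare(system, bath, config, False, 0.0,
                    ensemble.site_energies)
    n_map = prep["n_map"]
    rho0 = np.asarray(rho0, dtype=np.complex128)
    if rho0.shape != (n_map, n_map):
        raise ValueError("rho0 shape mismatch")
    if ensemble.method == "fbts":
        w0 = 0.5 * np.einsum("lm,im,il->i", rho0, ensemble.c0,
                             np.conj(ensemble.cb0))
    else:
        # PBME family: plain coherent-state weight; the estimator's
        # delta subtraction is applied on the time-t side in the kernel
        w0 = 0.5 * np.einsum("lm,im,il->i", rho0, ensemble.c0,
                             np.conj(ensemble.c0))
    n_rec = config.n_steps // config.record_every + 1
    rho_sum = np.zeros((n_rec, n_map, n_map), dtype=np.complex128)
    bathE_sum = np.zeros(n_rec)
    n_kept, n_drop = _equilibrate_kernel(
        ensemble.c0, ensemble.cb0, ensemble.R0, ensemble.P0,
        prep["eps_ang"], np.ascontiguousarray(w0, dtype=np.complex128),
        prep["omega_cm"], prep["UJ"], prep["sub_h"],
        prep["cth"], prep["sth"], prep["swo"], prep["cwo"],
        prep["dcoup"], prep["g_ang"], _METHOD_CODES[ensemble.method],
        config.n_steps, config.record_every, rho_sum, bathE_sum)
    if n_drop > drop_tolerance * ensemble.n_traj:
        raise FloatingPointError(
            f"{n_drop}/{ensemble.n_traj} trajectories went non-finite")
    return _record_times(config), rho_sum / n_kept, bathE_sum / n_kept
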