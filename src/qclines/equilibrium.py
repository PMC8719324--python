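"""Excited-state equilibrium of an exciton aggregate.

Fluorescence requires the subsystem density matrix and the bath
distribution after the aggregate, impulsively excited, has relaxed.  Two
routes are provided:

* **dynamical** -- propagate the subsystem projectors |m><n| with FBTS or
  PBME-nH until a plateau is reached (the bath ensemble is propagated
  simultaneously and captured at t1);

* **effective-coupling ("Jeff")** -- take the Boltzmann distribution of
  an effective Hamiltonian in which the bath reduces the resonance
  couplings,

      H_eff = H_eps + exp(-beta*Lambda/6) H_J exp(-beta*Lambda/6),

  i.e. J_mn -> J_mn exp(-beta (lambda_m + lambda_n)/6) with Lambda the
  diagonal matrix of per-site reorganization energies.  The diagonal of
  H_eff equals that of H_S.  The basis diagonalizing H_eff is the
  *global basis* (GB).  Even in this mode the coupled Hamilton equations
  are still propagated to t1, because the fluorescence algorithm needs
  the relaxed bath ensemble; the subsystem mapping variables at t1 are
  retained so the emission phase can reuse them (the "kept variables"
  refinement of the Jeff hybrids).

The effective-coupling approximation degrades for low temperatures, fast
baths and very strong system-bath coupling, but across the dimer
regimes studied here it tracks the numerically exact equilibrium
coherences to a few percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .bath import DiscretizedBath
from .engines import (EngineConfig, TrajectoryEnsemble, draw_ensemble,
                      propagate_projectors)
from .systems import ExcitonSystem
from .units import beta_cm

__all__ = [
    "EffectiveHamiltonian",
    "EquilibriumState",
    "effective_hamiltonian",
    "boltzmann_equilibrium",
    "global_basis_dipoles",
    "initial_excited_state",
    "equilibrate",
]


@dataclass(frozen=True)
class EffectiveHamiltonian:
    """Effective subsystem Hamiltonian of the equilibrium theory."""

    matrix: np.ndarray    # H_eff (cm^-1)
    h_eps: np.ndarray     # diagonal part of H_S
    h_j: np.ndarray       # off-diagonal part of H_S
    lambdas: np.ndarray   # per-site reorganization energies (cm^-1)
    beta: float           # 1/(kB T) in (cm^-1)^-1

    def global_basis(self):
        """Eigenvalues (ascending) and eigenvectors of H_eff."""
        return np.linalg.eigh(self.matrix)


@dataclass
class EquilibriumState:
    """Excited-state equilibrium subsystem matrix plus bath ensemble."""

    rho_site: np.ndarray                    # N x N, site basis
    source: str                             # "dynamical" or "jeff"
    rho_global: Optional[np.ndarray] = None  # GB representation (jeff)
    gb_energies: Optional[np.ndarray] = None
    gb_vectors: Optional[np.ndarray] = None
    ensemble: Optional[TrajectoryEnsemble] = None  # phase space at t1
    diagnostics: dict = field(default_factory=dict)


def effective_hamiltonian(system: ExcitonSystem, lambdas,
                          temperature: float) -> EffectiveHamiltonian:
    """Assemble H_eff; only the resonance couplings are modified."""
    beta = beta_cm(temperature)
    lam = np.broadcast_to(np.asarray(lambdas, dtype=float),
                          (system.n_sites,)).copy()
    if lam.size != system.n_sites:
        raise ValueError("lambdas length must equal n_sites")
    h_eps = np.diag(system.site_energies)
    h_j = system.couplings
    scale = np.exp(-beta * lam / 6.0)
    h_eff = h_eps + scale[:, None] * h_j * scale[None, :]
    return EffectiveHamiltonian(matrix=h_eff, h_eps=h_eps, h_j=h_j,
                                lambdas=lam, beta=beta)


def boltzmann_equilibrium(h_eff: EffectiveHamiltonian) -> EquilibriumState:
    """rho proportional to exp(-beta H_eff), trace exactly one, reported
    in the site basis and in the global basis."""
    evals, vecs = h_eff.global_basis()
    x = -h_eff.beta * (evals - evals.min())
    pops = np.exp(x)
    pops /= pops.sum()
    rho_site = (vecs * pops) @ vecs.T
    return EquilibriumState(rho_site=rho_site, source="jeff",
                            rho_global=np.diag(pops),
                            gb_energies=evals, gb_vectors=vecs)


def global_basis_dipoles(system: ExcitonSystem,
                         h_eff: EffectiveHamiltonian) -> np.ndarray:
    """Squared transition-dipole magnitudes |mu_0k^GB|^2 (D^2) of the
    global-basis excitons, ordered by ascending GB eigenvalue."""
    _, vecs = h_eff.global_basis()
    mu_gb = vecs.T @ system.dipoles      # (N, 3)
    return np.sum(mu_gb ** 2, axis=1)


def initial_excited_state(system: ExcitonSystem,
                          start: str = "dipole") -> np.ndarray:
    """Subsystem state right after impulsive excitation.

    ``"dipole"`` gives rho ~ mu |0><0| mu (site populations proportional
    to |mu_0n|^2, coherences included); ``"uniform"`` the maximally mixed
    excited state; ``"site:<i>"`` a single-site start (1-based index).
    """
    n = system.n_sites
    if start == "dipole":
        g = system.dipoles @ system.dipoles.T
        return g / np.trace(g)
    if start == "uniform":
        return np.eye(n) / n
    if start.startswith("site:"):
        i = int(start.split(":", 1)[1]) - 1
        if not 0 <= i < n:
            raise ValueError(f"site index out of range in {start!r}")
        rho = np.zeros((n, n))
        rho[i, i] = 1.0
        return rho
    raise ValueError(f"unknown initial condition {start!r}")


def _gb_populations(rho: np.ndarray, vecs: np.ndarray) -> np.ndarray:
    return np.real(np.einsum("nk,nm,mk->k", vecs, rho, vecs))


def equilibrate(system: ExcitonSystem, bath: DiscretizedBath,
                temperature: float, config: EngineConfig,
                mode: str, t1: float, n_traj: int, seed: int,
                start: str = "dipole",
                lambdas=None,
                plateau_window_fs: float = 200.0,
                plateau_tol: float = 0.01) -> EquilibriumState:
    """Produce the excited-state equilibrium at time t1.

    In ``"dynamical"`` mode the subsystem matrix is the projector-
    propagation estimate rho_S(t1); in ``"jeff"`` mode it is the
    Boltzmann state of the effective Hamiltonian while the phase-space
    ensemble is still propagated dynamically to t1.  In both modes the
    returned ensemble holds the bath -- and subsystem mapping --
    variables at t1.
    """
    if mode not in ("dynamical", "jeff"):
        raise ValueError(f"unknown equilibration mode {mode!r}")
    if t1 < config.dt:
        raise ValueError("t1 must cover at least one step")
    if lambdas is None:
        lambdas = bath.reorganization()
    h_eff = effective_hamiltonian(system, lambdas, temperature)
    gb_evals, gb_vecs = h_eff.global_basis()

    ens = draw_ensemble(system, bath, config.method, temperature, n_traj,
                        seed, include_ground=False)
    rho0 = initial_excited_state(system, start)
    run_cfg = EngineConfig(method=config.method, dt=config.dt, t_max=t1,
                           record_every=config.record_every,
                           integrator=config.integrator)
    times, rho_t, bath_energy = propagate_projectors(
        system, bath, ens, run_cfg, rho0)

    # plateau check on global-basis populations over the final window
    pops_t = np.stack([_gb_populations(r, gb_vecs) for r in rho_t])
    n_win = max(2, int(round(plateau_window_fs
                             / (config.dt * config.record_every))))
    tail = pops_t[-n_win:]
    ref = np.maximum(np.abs(tail[-1]), 0.02)
    drift = float(np.max(np.abs(tail.max(axis=0) - tail.min(axis=0)) / ref))
    if drift > plateau_tol:
        warnings.warn(
            f"equilibrium plateau not reached within t1={t1} fs: "
            f"max GB-population drift {drift:.2%} over the final "
            f"{plateau_window_fs} fs", stacklevel=2)

    diagnostics = dict(times=times, rho_t=rho_t, gb_populations=pops_t,
                       bath_energy=bath_energy, plateau_drift=drift)
    if mode == "dynamical":
        return EquilibriumState(rho_site=rho_t[-1], source="dynamical",
                                gb_energies=gb_evals, gb_vectors=gb_vecs,
                                ensemble=ens, diagnostics=diagnostics)
    eq = boltzmann_equilibrium(h_eff)
    eq.ensemble = ens
    eq.diagnostics = diagnostics
    return eq
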