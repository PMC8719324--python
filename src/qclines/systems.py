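"""Frenkel-exciton systems: the dimer family, the FMO complex and
user-defined aggregates.

The electronic subsystem Hamiltonian is

    H_S = sum_n eps_n |n><n| + sum_{m != n} J_mn |m><n|

with site excitation energies ``eps_n`` and resonance couplings ``J_mn``
in cm^-1.  Each site carries a transition dipole ``mu_0n`` (debye)
coupling it to the common electronic ground state; ``mu_0n = mu_n0``.
A constant ``ground_offset`` records the energy gap between the lowest
excited state manifold reference and the ground state when the site
energies are given relative to an arbitrary zero (the dimer convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ExcitonSystem",
    "DisorderSpec",
    "build_dimer",
    "build_fmo",
    "dimer_default",
    "DIMER_DEFAULTS",
    "sample_disorder",
]


@dataclass(frozen=True)
class ExcitonSystem:
    """Electronic subsystem of a Frenkel-exciton aggregate."""

    site_energies: np.ndarray  # (N,) cm^-1
    couplings: np.ndarray      # (N, N) cm^-1, symmetric, zero diagonal
    dipoles: np.ndarray        # (N, 3) debye
    ground_offset: float = 0.0  # cm^-1

    def __post_init__(self):
        e = np.atleast_1d(np.asarray(self.site_energies, dtype=float))
        J = np.asarray(self.couplings, dtype=float)
        mu = np.asarray(self.dipoles, dtype=float)
        n = e.size
        if J.shape != (n, n):
            raise ValueError(f"couplings must be ({n},{n}), got {J.shape}")
        if mu.shape != (n, 3):
            raise ValueError(f"dipoles must be ({n},3), got {mu.shape}")
        if not np.all(np.isfinite(e)) or not np.all(np.isfinite(J)):
            raise ValueError("non-finite Hamiltonian elements")
        if not np.all(np.isfinite(mu)):
            raise ValueError("non-finite dipoles")
        if np.max(np.abs(J - J.T)) > 1e-9:
            raise ValueError("couplings matrix must be symmetric within 1e-9")
        J = 0.5 * (J + J.T)
        np.fill_diagonal(J, 0.0)
        object.__setattr__(self, "site_energies", e)
        object.__setattr__(self, "couplings", J)
        object.__setattr__(self, "dipoles", mu)

    @property
    def n_sites(self) -> int:
        return self.site_energies.size

    @property
    def hamiltonian(self) -> np.ndarray:
        """Subsystem Hamiltonian H_S (N x N, cm^-1); exactly symmetric."""
        return np.diag(self.site_energies) + self.couplings

    def with_site_energies(self, energies) -> "ExcitonSystem":
        return replace(self, site_energies=np.asarray(energies, dtype=float))

    def dipole_strength(self) -> float:
        """Total dipole strength sum_n |mu_0n|^2 in D^2."""
        return float(np.sum(self.dipoles ** 2))


@dataclass(frozen=True)
class DisorderSpec:
    """Static Gaussian site-energy disorder, one sigma (cm^-1) per site."""

    sigmas: np.ndarray

    def __post_init__(self):
        s = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        if np.any(s < 0):
            raise ValueError("disorder sigmas must be non-negative")
        object.__setattr__(self, "sigmas", s)


# ---------------------------------------------------------------------------
# Dimer family
# ---------------------------------------------------------------------------

#: Default dimer parameters: the study conditions of the dimer benchmark.
#: Energies in cm^-1, relaxation time in fs, temperature in K.
DIMER_DEFAULTS = {
    "energy_gap": 100.0,
    "coupling": 100.0,
    "lambda": 60.0,
    "gamma_fs": 100.0,
    "temperature": 300.0,
    "ground_offset": 15000.0,
}


def build_dimer(energy_gap: float = 100.0, coupling: float = 100.0,
                ground_offset: float = 15000.0) -> ExcitonSystem:
    """Two-site system with H_S = [[0, J], [J, eps]] relative to site 1.

    The transition dipoles are unit vectors along x and y: perpendicular
    dipoles suppress coherence transfer in the optical response, and for
    normalized spectra only the relative orientation matters.
    """
    eps = float(energy_gap)
    J = float(coupling)
    return ExcitonSystem(
        site_energies=np.array([0.0, eps]),
        couplings=np.array([[0.0, J], [J, 0.0]]),
        dipoles=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        ground_offset=float(ground_offset),
    )


def dimer_default():
    """The default dimer fixture: (system, bath parameters, temperature)."""
    from .bath import SpectralDensityParams

    d = DIMER_DEFAULTS
    system = build_dimer(d["energy_gap"], d["coupling"], d["ground_offset"])
    sd = SpectralDensityParams(kind="debye", lam=d["lambda"],
                               gamma_fs=d["gamma_fs"])
    return system, sd, d["temperature"]


# ---------------------------------------------------------------------------
# FMO complex (Prosthecochloris aestuarii, structure-based monomer model)
# ---------------------------------------------------------------------------

# Excited-state Hamiltonian (cm^-1): site energies on the diagonal and
# resonance couplings off it, sites ordered BChl 1..7 and BChl 8'.
_FMO_H8 = np.array([
    [12650.70, -109.89,    5.46,   -6.12,    7.10,  -19.78,   -8.10,   26.47],
    [-109.89, 12414.10,   31.64,    7.97,    1.76,   12.38,    4.26,    4.85],
    [5.46,      31.64, 12195.30,  -67.30,   -0.13,   -9.26,   -2.57,    0.57],
    [-6.12,      7.97,  -67.30, 12394.60,  -69.58,  -18.73,  -63.21,   -1.58],
    [7.10,       1.76,   -0.13,  -69.58, 12557.60,   76.43,    2.67,    4.07],
    [-19.78,    12.38,   -9.26,  -18.73,   76.43, 12527.90,   31.82,   -9.59],
    [-8.10,      4.26,   -2.57,  -63.21,    2.67,   31.82, 12478.50,  -11.37],
    [26.47,      4.85,    0.57,   -1.58,    4.07,   -9.59,  -11.37, 12697.40],
])

# Standard deviations of the Gaussian site-energy distributions (cm^-1).
_FMO_SIGMA8 = np.array([36.9, 45.4, 54.6, 39.5, 36.5, 64.3, 50.4, 92.6])

# Transition dipole moments (debye).
_FMO_MU8 = np.array([
    [-0.037, -1.536,  5.279],
    [4.157,  -3.147,  1.691],
    [5.293,  -0.421, -1.863],
    [0.080,  -2.253,  5.015],
    [4.182,  -3.554, -0.282],
    [-4.714, -2.081,  2.005],
    [-1.182,  0.529,  5.380],
    [-1.884, -5.163, -0.807],
])

#: Fraction of FMO complexes carrying only seven BChls in a typical sample.
FMO_SEVEN_SITE_FRACTION = 0.65


def build_fmo(n_bchl: int = 7):
    """FMO monomer model with 7 or 8 BChl sites.

    The 7-site variant drops the eighth pigment (BChl 8', which belongs
    to the neighboring monomer in the trimer) row and column.

    Returns
    -------
    (ExcitonSystem, DisorderSpec)
    """
    if n_bchl not in (7, 8):
        raise ValueError("n_bchl must be 7 or 8")
    n = n_bchl
    H = _FMO_H8[:n, :n]
    J = H.copy()
    np.fill_diagonal(J, 0.0)
    system = ExcitonSystem(
        site_energies=np.diag(H).copy(),
        couplings=J,
        dipoles=_FMO_MU8[:n].copy(),
        ground_offset=0.0,
    )
    return system, DisorderSpec(sigmas=_FMO_SIGMA8[:n].copy())


# ---------------------------------------------------------------------------
# Static disorder
# ---------------------------------------------------------------------------

def sample_disorder(system: ExcitonSystem, spec: DisorderSpec,
                    rng: np.random.Generator) -> ExcitonSystem:
    """One disorder realization: site energies independently perturbed by
    zero-mean Gaussians of the given widths; couplings and dipoles untouched.
    """
    if spec.sigmas.size != system.n_sites:
        raise ValueError("sigma length must equal n_sites")
    if np.all(spec.sigmas == 0):
        return system
    shifts = rng.normal(0.0, 1.0, size=system.n_sites) * spec.sigmas
    return system.with_site_energies(system.site_energies + shifts)
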