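"""Harmonic bath models: spectral densities and their discretization.

Each electronic site couples linearly to its own set of harmonic
oscillators with dimensionless coordinates,

    H_B  = sum_{n,v} (w_nv / 2) (P_nv^2 + R_nv^2),
    H_SB = - sum_{n,v} w_nv d_nv R_nv |n><n|,

so the per-site reorganization energy is ``lambda_n = sum_v w_nv d_nv^2 / 2``.
The continuum limit is described by a spectral density J(w) with

    lambda = (1/pi) Int_0^inf dw J(w) / w.

Two spectral-density families are provided: the overdamped Debye form

    J(w) = 2 lambda gamma w / (w^2 + gamma^2),

with relaxation timescale ``gamma^-1``, and the B777 form fitted to the
fluorescence line-narrowing spectrum of the bacteriochlorophyll B777
complex, scaled linearly by the Huang-Rhys factor S:

    J(w) = (pi S / (s1+s2)) sum_k [s_k / (2 * 7! * w_k^4)] w^5 exp(-(w/w_k)^(1/2)),

with s_1 = 0.8, s_2 = 0.5 and w_1 = 0.557 cm^-1, w_2 = 1.936 cm^-1.
Closed form of the reorganization integral: lambda = (9!/7!) S
(s1 w1 + s2 w2) / (s1 + s2), about 78.3 * S cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .units import ANG_PER_CM

__all__ = [
    "SpectralDensityParams",
    "DiscretizedBath",
    "spectral_density",
    "reorganization_energy",
    "discretize_bath",
]

# B777 lineshape constants (s_k dimensionless, w_k in cm^-1; the latter are
# 0.069 meV and 0.24 meV expressed in wavenumbers).
B777_S = (0.8, 0.5)
B777_OMEGA = (0.556522, 1.935730)
_FACT7_2 = 2.0 * 5040.0  # 2 * 7!


@dataclass(frozen=True)
class SpectralDensityParams:
    """Continuous spectral-density parameters.

    Parameters
    ----------
    kind : {"debye", "b777"}
    lam : float
        Debye reorganization energy lambda (cm^-1).  Ignored for B777.
    gamma_fs : float
        Debye bath relaxation timescale gamma^-1 in fs.
    huang_rhys : float
        Huang-Rhys factor S of the B777 form.  Ignored for Debye.
    """

    kind: str = "debye"
    lam: float = 60.0
    gamma_fs: float = 100.0
    huang_rhys: float = 0.5

    def __post_init__(self):
        if self.kind not in ("debye", "b777"):
            raise ValueError(f"unknown spectral density kind {self.kind!r}")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.gamma_fs <= 0:
            raise ValueError("gamma_inv must be positive")
        if self.huang_rhys < 0:
            raise ValueError("Huang-Rhys factor must be non-negative")

    @property
    def gamma_cm(self) -> float:
        """Debye cutoff gamma as a wavenumber (cm^-1)."""
        return 1.0 / (ANG_PER_CM * self.gamma_fs)

    @property
    def reorganization(self) -> float:
        """Closed-form continuum reorganization energy (cm^-1)."""
        if self.kind == "debye":
            return self.lam
        s1, s2 = B777_S
        w1, w2 = B777_OMEGA
        return 72.0 * self.huang_rhys * (s1 * w1 + s2 * w2) / (s1 + s2)


def spectral_density(params: SpectralDensityParams, omega) -> np.ndarray:
    """Evaluate J(omega) in cm^-1 for omega >= 0 in cm^-1."""
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("omega must be non-negative")
    if params.kind == "debye":
        g = params.gamma_cm
        out = 2.0 * params.lam * g * w / (w ** 2 + g ** 2)
    else:
        s1, s2 = B777_S
        pref = np.pi * params.huang_rhys / (s1 + s2)
        out = np.zeros_like(w)
        for sk, wk in zip(B777_S, B777_OMEGA):
            with np.errstate(over="ignore"):
                out += sk / (_FACT7_2 * wk ** 4) * w ** 5 * \
                    np.exp(-np.sqrt(w / wk))
        out *= pref
    return out if out.shape else float(out)


def reorganization_energy(params: SpectralDensityParams) -> float:
    """Continuum reorganization energy (1/pi) Int J(w)/w dw by adaptive
    quadrature (relative accuracy well below 0.1%)."""
    if params.kind == "debye" and params.lam == 0:
        return 0.0
    if params.kind == "b777" and params.huang_rhys == 0:
        return 0.0

    def integrand(w):
        return spectral_density(params, w) / w

    if params.kind == "debye":
        g = params.gamma_cm
        val, _ = integrate.quad(integrand, 0.0, np.inf,
                                points=None, limit=400)
        # quad on [0, inf) with 1/(w^2+g^2) tail converges well directly
        return val / np.pi
    wmax = B777_OMEGA[1] * 60.0 ** 2  # exp(-sqrt(w/w2)) ~ e^-60
    val, _ = integrate.quad(integrand, 0.0, wmax, limit=400)
    return val / np.pi


@dataclass(frozen=True)
class DiscretizedBath:
    """Per-site discretized bath modes.

    ``omega`` and ``d`` are (n_sites, modes_per_site) arrays of mode
    wavenumbers (cm^-1) and dimensionless coupling constants; frequencies
    are strictly positive and sorted along the mode axis.
    """

    omega: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        w = np.atleast_2d(np.asarray(self.omega, dtype=float))
        d = np.atleast_2d(np.asarray(self.d, dtype=float))
        if w.shape != d.shape:
            raise ValueError("omega and d shapes differ")
        if np.any(w <= 0):
            raise ValueError("mode frequencies must be strictly positive")
        if np.any(np.diff(w, axis=1) < 0):
            raise ValueError("mode frequencies must be sorted")
        object.__setattr__(self, "omega", w)
        object.__setattr__(self, "d", d)

    @property
    def n_sites(self) -> int:
        return self.omega.shape[0]

    @property
    def modes_per_site(self) -> int:
        return self.omega.shape[1]

    def reorganization(self) -> np.ndarray:
        """Per-site discrete reorganization energy sum_v w_v d_v^2 / 2."""
        return 0.5 * np.sum(self.omega * self.d ** 2, axis=1)


def _cumulative_inverse(params: SpectralDensityParams, fractions: np.ndarray):
    """Frequencies at which the cumulative reorganization integral reaches
    the given fractions of the continuum lambda."""
    if params.kind == "debye":
        g = params.gamma_cm
        return g * np.tan(0.5 * np.pi * fractions)
    # B777: numeric inversion on a dense grid
    wmax = B777_OMEGA[1] * 50.0 ** 2
    grid = np.linspace(1e-6, wmax, 200_000)
    dens = spectral_density(params, grid) / grid / np.pi
    cum = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
    cum /= cum[-1]
    return np.interp(fractions, cum, grid)


def discretize_bath(params: SpectralDensityParams, modes_per_site: int,
                    n_sites: int, scheme: str = "quantile",
                    coverage: float = 0.999) -> DiscretizedBath:
    """Discretize J(w) into ``modes_per_site`` modes per site.

    scheme="quantile" (default) places nodes at equal increments of the
    cumulative reorganization integral, so every mode carries the same
    reorganization weight ``coverage * lambda / K``; the discrete
    reorganization energy then equals ``coverage * lambda`` exactly.
    scheme="linear" uses equally spaced frequencies up to the coverage
    cutoff with weights from J(w) at each node.
    """
    if modes_per_site < 1:
        raise ValueError("modes_per_site must be >= 1")
    K = int(modes_per_site)
    lam = params.reorganization
    if lam == 0.0:
        w = np.tile(np.linspace(1.0, float(K), K), (n_sites, 1))
        return DiscretizedBath(omega=w, d=np.zeros_like(w))
    if scheme == "quantile":
        fr = (np.arange(K) + 0.5) / K * coverage
        w = _cumulative_inverse(params, fr)
        lam_per_mode = coverage * lam / K
        d = np.sqrt(2.0 * lam_per_mode / w)
    elif scheme == "linear":
        wc = float(_cumulative_inverse(params, np.array([coverage]))[0])
        dw = wc / K
        w = (np.arange(K) + 0.5) * dw
        jw = spectral_density(params, w)
        d = np.sqrt(2.0 * jw * dw / (np.pi * w ** 2))
        # midpoint weights under-resolve sharply peaked lambda densities;
        # rescale so the discrete reorganization matches the covered
        # fraction exactly (the closure invariant is the contract)
        lam_disc = 0.5 * np.sum(w * d ** 2)
        if lam_disc > 0:
            d *= np.sqrt(coverage * lam / lam_disc)
    else:
        raise ValueError(f"unknown discretization scheme {scheme!r}")
    omega = np.tile(w, (n_sites, 1))
    dd = np.tile(d, (n_sites, 1))
    return DiscretizedBath(omega=omega, d=dd)
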