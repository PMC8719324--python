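"""Monte-Carlo initial conditions.

Bath oscillators are drawn from the thermal Wigner distribution of a
harmonic mode, which for dimensionless (R, P) is a product of Gaussians
of variance coth(beta*w/2)/2 per variable -- the zero-point value 1/2 at
T -> 0 and the classical kT/w at high temperature.

The mapping description represents each electronic state by a fictitious
harmonic oscillator with phase-space variables (q, p).  The forward-
backward trajectory solution (FBTS) carries two copies (q, p) and
(q', p'); the Poisson-bracket mapping equation family carries one.  Both
are sampled from the coherent-state Gaussian measure in which every
mapping variable is i.i.d. standard normal (hbar = 1); the estimator
weight functions in :mod:`qclines.engines` are normalized against this
measure so that propagating the identity operator returns the identity.

Reproducibility contract: trajectory ``i`` of a run with master seed
``s`` always draws from ``np.random.SeedSequence(s).spawn`` child ``i``,
independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .bath import DiscretizedBath
from .units import KB_CM

__all__ = [
    "BathPhasePoint",
    "MappingVariables",
    "trajectory_rng",
    "wigner_sigma",
    "sample_bath_wigner",
    "sample_mapping",
]


@dataclass
class BathPhasePoint:
    """Dimensionless bath coordinates and momenta, (n_sites, K) each."""

    Q: np.ndarray
    P: np.ndarray


@dataclass
class MappingVariables:
    """Per-electronic-state mapping oscillator variables.

    ``q``/``p`` are the (forward) variables; ``qb``/``pb`` the backward
    copy, present only for FBTS.
    """

    q: np.ndarray
    p: np.ndarray
    qb: Optional[np.ndarray] = None
    pb: Optional[np.ndarray] = None

    @property
    def c(self) -> np.ndarray:
        return self.q + 1j * self.p

    @property
    def cb(self) -> Optional[np.ndarray]:
        if self.qb is None:
            return None
        return self.qb + 1j * self.pb


def trajectory_rng(master_seed: int, trajectory_index: int) -> np.random.Generator:
    """Counter-based per-trajectory substream: identical (seed, index)
    yields identical draws regardless of scheduling."""
    seq = np.random.SeedSequence(entropy=int(master_seed),
                                 spawn_key=(int(trajectory_index),))
    return np.random.Generator(np.random.PCG64(seq))


def wigner_sigma(bath: DiscretizedBath, temperature: float) -> np.ndarray:
    """Standard deviation of Q (and P) per mode under the thermal Wigner
    distribution: sigma^2 = coth(beta*w/2) / 2."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    x = bath.omega / (2.0 * KB_CM * temperature)
    return np.sqrt(0.5 / np.tanh(x))


def sample_bath_wigner(bath: DiscretizedBath, temperature: float,
                       rng: np.random.Generator) -> BathPhasePoint:
    """Draw (Q, P) for every mode from the thermal Wigner distribution."""
    sig = wigner_sigma(bath, temperature)
    Q = rng.normal(size=bath.omega.shape) * sig
    P = rng.normal(size=bath.omega.shape) * sig
    return BathPhasePoint(Q=Q, P=P)


def sample_mapping(method: str, n_states: int,
                   rng: np.random.Generator) -> MappingVariables:
    """Draw mapping variables for the given method.

    ``fbts`` returns forward and backward copies; ``pbme_nh`` (and the
    diagnostics-only ``pbme``) a single copy.  All variables are standard
    normal under the documented coherent-state measure.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if method == "fbts":
        q, p, qb, pb = rng.normal(size=(4, n_states))
        return MappingVariables(q=q, p=p, qb=qb, pb=pb)
    if method in ("pbme_nh", "pbme"):
        q, p = rng.normal(size=(2, n_states))
        return MappingVariables(q=q, p=p)
    raise ValueError(f"unknown method {method!r}")
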