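"""Unit conventions used throughout the package.

Energies and frequencies are wavenumbers (cm^-1), time is femtoseconds,
transition dipoles are debye.  The reduced Planck constant is set to one,
so a wavenumber ``w`` corresponds to the angular frequency ``2*pi*c*w``
with ``c`` in cm/fs.  Bath oscillator coordinates and momenta are
dimensionless.
"""

import numpy as np

#: speed of light in cm/fs
C_CM_FS = 2.99792458e-5

#: Boltzmann constant in cm^-1 / K
KB_CM = 0.695034800

#: rad/fs per cm^-1
ANG_PER_CM = 2.0 * np.pi * C_CM_FS


def angular(wavenumber):
    """Angular frequency (rad/fs) for a wavenumber (cm^-1)."""
    return ANG_PER_CM * np.asarray(wavenumber, dtype=float)


def wavenumber_from_time(t_fs):
    """Wavenumber (cm^-1) whose angular period equals ``2*pi*t_fs``."""
    return 1.0 / (ANG_PER_CM * t_fs)


def beta_cm(temperature):
    """Inverse thermal energy 1/(kB*T) in (cm^-1)^-1."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return 1.0 / (KB_CM * temperature)
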