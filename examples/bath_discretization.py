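"""Spectral densities and their discretization.

Shows the Debye and B777 spectral densities, verifies that the
discretized per-site modes reproduce the continuum reorganization energy
(the closure invariant of the sampler), and prints the thermal Wigner
widths of a few modes.
"""

import numpy as np

import qclines as q

debye = q.SpectralDensityParams(kind="debye", lam=60.0, gamma_fs=100.0)
b777 = q.SpectralDensityParams(kind="b777", huang_rhys=0.5)

print(f"Debye:  J(gamma) = {q.spectral_density(debye, debye.gamma_cm):.2f} "
      f"cm^-1 (= lambda), lambda = {q.reorganization_energy(debye):.2f}")
print(f"B777 :  S = 0.5  ->  lambda = {q.reorganization_energy(b777):.2f} "
      "cm^-1 (closed form "
      f"{b777.reorganization:.2f})")

for params in (debye, b777):
    bath = q.discretize_bath(params, modes_per_site=100, n_sites=1)
    lam = params.reorganization
    rec = bath.reorganization()[0]
    print(f"{params.kind}: 100 modes recover lambda = {rec:.2f} cm^-1 "
          f"({100 * abs(rec - lam) / lam:.2f}% closure error)")

bath = q.discretize_bath(debye, 100, 1)
sig = q.wigner_sigma(bath, 77.0)
print("thermal Wigner widths <Q^2>^1/2 at 77 K: "
      f"lowest mode ({bath.omega[0, 0]:.1f} cm^-1): {sig[0, 0]:.2f}, "
      f"highest mode ({bath.omega[0, -1]:.0f} cm^-1): {sig[0, -1]:.3f} "
      "(zero-point limit 1/sqrt(2) = 0.707)")
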