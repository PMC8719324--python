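"""Absorption lineshape of the default molecular dimer.

Builds the two-site benchmark system (energy gap 100 cm^-1, resonance
coupling 100 cm^-1, perpendicular unit dipoles), couples each site to a
Debye bath (lambda = 60 cm^-1, gamma^-1 = 100 fs) at 300 K, runs the
FBTS engine over a small Monte-Carlo ensemble, and prints the band
maxima of the normalized spectrum.
"""

import numpy as np

import qclines as q

system, sd, temperature = q.dimer_default()
bath = q.discretize_bath(sd, modes_per_site=100, n_sites=system.n_sites)

config = q.EngineConfig(method="fbts", dt=1.0, t_max=500.0, record_every=2)
record = q.absorption_correlation(system, bath, temperature, config,
                                  n_traj=5000, seed=1)
print(f"C(0) = {record.values[0].real:.4f}  "
      f"(isotropic average (1/3) sum |mu|^2 = "
      f"{system.dipole_strength() / 3:.4f})")
print(f"|C(t_max)|/|C(0)| = "
      f"{abs(record.values[-1]) / abs(record.values[0]):.3f} "
      "(decay of the optical response)")

spectrum = q.spectrum_from_correlation(record,
                                       ground_offset=system.ground_offset)
for w, h in q.find_peaks(spectrum, min_rel_height=0.1)[:2]:
    print(f"band maximum at {w:8.1f} cm^-1, relative intensity {h:.3f}")
print("The two bands are the excitonic transitions of the coupled dimer; "
      "without the bath they would sit at 14938 and 15162 cm^-1 "
      "(subsystem eigenvalues plus the 15000 cm^-1 ground-state offset).")
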