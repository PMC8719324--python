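"""Plain-text and HDF5 output of spectra and correlation records."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .lineshape import CorrelationRecord, Spectrum

__all__ = ["write_spectrum_text", "read_spectrum_text", "write_bundle_h5"]


def write_spectrum_text(spectrum: Spectrum, path) -> None:
    """Two-column delimited text (wavenumber cm^-1, intensity) with the
    metadata as a JSON comment header."""
    path = Path(path)
    meta = {k: v for k, v in spectrum.meta.items()
            if isinstance(v, (str, int, float, bool, list, type(None)))}
    header = "# qclines spectrum\n# meta: " + json.dumps(meta, sort_keys=True)
    data = np.column_stack([spectrum.wavenumbers, spectrum.intensity])
    np.savetxt(path, data, fmt="%.8g", header=header, comments="",
               delimiter="\t")


def read_spectrum_text(path) -> Spectrum:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# meta: "):
                meta = json.loads(line[len("# meta: "):])
            if not line.startswith("#"):
                break
    data = np.loadtxt(path, comments="#", delimiter="\t")
    return Spectrum(data[:, 0], data[:, 1], meta)


def write_bundle_h5(path, record: CorrelationRecord,
                    spectrum: Spectrum) -> None:
    """Optional structured container bundling the correlation record,
    its errors and the derived spectrum."""
    import h5py

    with h5py.File(path, "w") as h5:
        g = h5.create_group("correlation")
        g.create_dataset("times_fs", data=record.times)
        g.create_dataset("values", data=record.values)
        g.create_dataset("stderr", data=record.stderr)
        g.attrs["kind"] = record.kind
        g.attrs["carrier_cm"] = record.carrier
        g.attrs["n_trajectories"] = record.n_trajectories
        s = h5.create_group("spectrum")
        s.create_dataset("wavenumbers_cm", data=spectrum.wavenumbers)
        s.create_dataset("intensity", data=spectrum.intensity)
        for grp, meta in ((g, record.meta), (s, spectrum.meta)):
            for k, v in meta.items():
                if isinstance(v, (str, int, float, bool)):
                    grp.attrs[k] = v
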