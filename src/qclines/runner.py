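"""Configuration-driven experiment orchestration.

A run is described by a plain-text YAML document with four blocks --
``system``, ``bath``, ``run`` and ``output`` -- validated before any
compute; unknown keys are rejected.  The same entry points back the
command-line interface.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bath import SpectralDensityParams, discretize_bath
from .engines import EngineConfig
from .equilibrium import equilibrate
from .lineshape import (absorption_correlation, apply_half_lambda_redshift,
                        default_grid, ensemble_average,
                        fluorescence_correlation, spectrum_from_correlation)
from .systems import (DisorderSpec, ExcitonSystem, FMO_SEVEN_SITE_FRACTION,
                      build_dimer, build_fmo, DIMER_DEFAULTS)

log = logging.getLogger("qclines")

__all__ = ["load_config", "validate_config", "run_absorption",
           "run_fluorescence", "fixture_config"]

_ALLOWED = {
    "system": {"fixture", "energy_gap", "coupling", "ground_offset",
               "site_energies", "couplings", "dipoles", "disorder"},
    "bath": {"kind", "lambda", "gamma_fs", "huang_rhys", "modes_per_site",
             "scheme", "coverage"},
    "run": {"method", "temperature", "n_traj", "seed", "dt", "t_max",
            "record_every", "t1", "start", "integrator", "disorder"},
    "output": {"prefix", "normalize", "omega_prefactor", "omega_cubed",
               "apodization_fs", "grid_halfwidth", "grid_spacing",
               "hdf5"},
}

_METHODS = ("fbts", "pbme_nh", "fbts_jeff", "pbme_nh_jeff")


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    for block, keys in cfg.items():
        if block not in _ALLOWED:
            raise ValueError(f"unknown config block {block!r}")
        unknown = set(keys) - _ALLOWED[block]
        if unknown:
            raise ValueError(f"unknown keys in {block!r}: {sorted(unknown)}")
    method = cfg.get("run", {}).get("method", "fbts")
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from "
                         f"{_METHODS}")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def config_hash(cfg: dict) -> str:
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _build_systems(cfg: dict):
    """Returns a list of (label, system, disorder_spec, weight)."""
    sc = dict(cfg.get("system", {}))
    fixture = sc.get("fixture")
    if fixture in ("fmo7", "fmo8"):
        system, dis = build_fmo(7 if fixture == "fmo7" else 8)
        return [(fixture, system, dis, 1.0)]
    if fixture == "fmo_mixture":
        out = []
        w7 = FMO_SEVEN_SITE_FRACTION
        for n, w in ((7, w7), (8, 1.0 - w7)):
            system, dis = build_fmo(n)
            out.append((f"fmo{n}", system, dis, w))
        return out
    if fixture == "dimer" or (fixture is None and "site_energies" not in sc):
        system = build_dimer(
            sc.get("energy_gap", DIMER_DEFAULTS["energy_gap"]),
            sc.get("coupling", DIMER_DEFAULTS["coupling"]),
            sc.get("ground_offset", DIMER_DEFAULTS["ground_offset"]))
        dis = None
        if "disorder" in sc:
            dis = DisorderSpec(np.asarray(sc["disorder"], dtype=float))
        return [("dimer", system, dis, 1.0)]
    system = ExcitonSystem(
        site_energies=np.asarray(sc["site_energies"], dtype=float),
        couplings=np.asarray(sc["couplings"], dtype=float),
        dipoles=np.asarray(sc["dipoles"], dtype=float),
        ground_offset=float(sc.get("ground_offset", 0.0)))
    dis = None
    if "disorder" in sc:
        dis = DisorderSpec(np.asarray(sc["disorder"], dtype=float))
    return [("custom", system, dis, 1.0)]


def _bath_params(cfg: dict) -> SpectralDensityParams:
    bc = dict(cfg.get("bath", {}))
    return SpectralDensityParams(
        kind=bc.get("kind", "debye"),
        lam=float(bc.get("lambda", 60.0)),
        gamma_fs=float(bc.get("gamma_fs", 100.0)),
        huang_rhys=float(bc.get("huang_rhys", 0.5)))


def _discretize(cfg: dict, params: SpectralDensityParams, n_sites: int):
    bc = dict(cfg.get("bath", {}))
    default_modes = 200 if params.kind == "b777" else 100
    return discretize_bath(
        params, int(bc.get("modes_per_site", default_modes)), n_sites,
        scheme=bc.get("scheme", "quantile"),
        coverage=float(bc.get("coverage", 0.999)))


def _engine_config(cfg: dict, method: str) -> EngineConfig:
    rc = dict(cfg.get("run", {}))
    gamma_fs = float(cfg.get("bath", {}).get("gamma_fs", 100.0))
    default_dt = 0.25 if gamma_fs <= 35.0 else 1.0
    return EngineConfig(
        method=method,
        dt=float(rc.get("dt", default_dt)),
        t_max=float(rc.get("t_max", 500.0)),
        record_every=int(rc.get("record_every", 1)),
        integrator=rc.get("integrator", "yoshida4"))


def _spectrum_opts(cfg: dict):
    oc = dict(cfg.get("output", {}))
    return dict(
        normalize=bool(oc.get("normalize", True)),
        omega_prefactor=bool(oc.get("omega_prefactor", False)),
        omega_cubed=bool(oc.get("omega_cubed", False)),
        apodization_fs=oc.get("apodization_fs"),
        halfwidth=float(oc.get("grid_halfwidth", 1200.0)),
        spacing=float(oc.get("grid_spacing", 2.0)))


def _write(cfg: dict, spectrum, record, label, kind):
    from .io import write_bundle_h5, write_spectrum_text

    oc = dict(cfg.get("output", {}))
    prefix = oc.get("prefix")
    if prefix is None:
        return None
    path = Path(f"{prefix}_{label}_{kind}.dat")
    path.parent.mkdir(parents=True, exist_ok=True)
    spectrum.meta.setdefault("qclines_version", __version__)
    spectrum.meta.setdefault("config_hash", config_hash(cfg))
    write_spectrum_text(spectrum, path)
    if oc.get("hdf5") and record is not None:
        write_bundle_h5(path.with_suffix(".h5"), record, spectrum)
    return path


def run_absorption(cfg: dict):
    """End-to-end absorption run; returns the final Spectrum (the
    mixture-weighted one when the fixture is ``fmo_mixture``)."""
    validate_config(cfg)
    rc = dict(cfg.get("run", {}))
    method = rc.get("method", "fbts")
    if method.endswith("_jeff"):
        raise ValueError("Jeff hybrids apply to fluorescence only")
    n_traj = int(rc.get("n_traj", 10_000))
    seed = int(rc.get("seed", 1))
    temperature = float(rc.get("temperature", 300.0))
    use_disorder = bool(rc.get("disorder", False))
    params = _bath_params(cfg)
    opts = _spectrum_opts(cfg)
    t0 = time.time()

    spectra, labels, weights = [], [], []
    record = None
    grid = None
    for label, system, dis, weight in _build_systems(cfg):
        bath = _discretize(cfg, params, system.n_sites)
        engine = _engine_config(cfg, method)
        record = absorption_correlation(
            system, bath, temperature, engine, n_traj, seed,
            disorder=dis if use_disorder else None)
        decay = float(np.abs(record.values[-1]) / np.abs(record.values[0]))
        log.info("absorption %s: method=%s n_traj=%d seed=%d dropped=%d "
                 "|C(tmax)|/|C(0)|=%.3f", label, method, n_traj, seed,
                 record.meta["n_dropped"], decay)
        if grid is None:
            grid = default_grid(record, system.ground_offset,
                                opts["halfwidth"], opts["spacing"])
        spec = spectrum_from_correlation(
            record, grid, ground_offset=system.ground_offset,
            omega_prefactor=opts["omega_prefactor"],
            normalize=False, apodization_fs=opts["apodization_fs"])
        spec.meta["method"] = method
        spectra.append(spec)
        labels.append(label)
        weights.append(weight)

    if len(spectra) > 1:
        total = ensemble_average(spectra, weights)
        label = "mixture"
    else:
        total, label = spectra[0], labels[0]
    if opts["normalize"]:
        total = total.normalized()
    total.meta["wall_s"] = round(time.time() - t0, 2)
    _write(cfg, total, record, label, "absorption")
    return total


def run_fluorescence(cfg: dict):
    """Two-phase fluorescence run (equilibrate, then emit); returns
    (Spectrum, EquilibriumState)."""
    validate_config(cfg)
    rc = dict(cfg.get("run", {}))
    method = rc.get("method", "pbme_nh_jeff")
    base = method.replace("_jeff", "")
    jeff = method.endswith("_jeff")
    n_traj = int(rc.get("n_traj", 10_000))
    seed = int(rc.get("seed", 1))
    temperature = float(rc.get("temperature", 300.0))
    params = _bath_params(cfg)
    opts = _spectrum_opts(cfg)
    t0 = time.time()

    label, system, dis, _weight = _build_systems(cfg)[0]
    bath = _discretize(cfg, params, system.n_sites)
    engine = _engine_config(cfg, base)
    t1 = float(rc.get("t1", 2000.0 if system.n_sites > 2 else 1000.0))
    eq = equilibrate(system, bath, temperature, engine,
                     mode="jeff" if jeff else "dynamical", t1=t1,
                     n_traj=n_traj, seed=seed,
                     start=rc.get("start", "dipole"))
    drift = eq.diagnostics.get("plateau_drift", 0.0)
    if not jeff and drift > 0.05:
        raise RuntimeError(
            f"equilibrium populations still drift {drift:.1%} at t1={t1} fs")
    record = fluorescence_correlation(system, bath, eq, engine, seed,
                                      reuse_mapping=jeff)
    grid = default_grid(record, system.ground_offset,
                        opts["halfwidth"], opts["spacing"])
    spec = spectrum_from_correlation(
        record, grid, ground_offset=system.ground_offset,
        omega_cubed=opts["omega_cubed"], normalize=opts["normalize"],
        apodization_fs=opts["apodization_fs"])
    spec.meta["method"] = method
    if base == "pbme_nh":
        lam = params.reorganization
        spec = apply_half_lambda_redshift(spec, lam)
        log.info("applied lambda/2 red shift of %.1f cm^-1", 0.5 * lam)
    spec.meta["t1_fs"] = t1
    spec.meta["plateau_drift"] = drift
    spec.meta["wall_s"] = round(time.time() - t0, 2)
    log.info("fluorescence %s: method=%s n_traj=%d seed=%d t1=%g fs "
             "drift=%.2f%%", label, method, n_traj, seed, t1, 100 * drift)
    _write(cfg, spec, record, label, "fluorescence")

    # population-vs-time equilibration diagnostics as delimited text
    prefix = cfg.get("output", {}).get("prefix")
    if prefix is not None:
        diag = eq.diagnostics
        pops = np.real(np.stack([np.diag(r) for r in diag["rho_t"]]))
        data = np.column_stack([diag["times"], pops, diag["bath_energy"]])
        hdr = "t_fs\t" + "\t".join(f"pop_site{i+1}"
                                   for i in range(pops.shape[1])) \
            + "\tbath_energy_cm"
        np.savetxt(f"{prefix}_{label}_populations.dat", data, fmt="%.8g",
                   header=hdr, delimiter="\t")
    return spec, eq


def fixture_config(name: str) -> dict:
    """Ready-made configs for the built-in model systems."""
    if name == "dimer":
        return {
            "system": {"fixture": "dimer",
                       "energy_gap": DIMER_DEFAULTS["energy_gap"],
                       "coupling": DIMER_DEFAULTS["coupling"],
                       "ground_offset": DIMER_DEFAULTS["ground_offset"]},
            "bath": {"kind": "debye", "lambda": DIMER_DEFAULTS["lambda"],
                     "gamma_fs": DIMER_DEFAULTS["gamma_fs"],
                     "modes_per_site": 100},
            "run": {"method": "fbts", "temperature":
                    DIMER_DEFAULTS["temperature"], "n_traj": 10_000,
                    "seed": 1, "t_max": 500.0},
            "output": {"normalize": True},
        }
    if name in ("fmo7", "fmo8", "fmo_mixture"):
        return {
            "system": {"fixture": name},
            "bath": {"kind": "debye", "lambda": 35.0, "gamma_fs": 100.0,
                     "modes_per_site": 100},
            "run": {"method": "pbme_nh_jeff", "temperature": 77.0,
                    "n_traj": 10_000, "seed": 1, "t_max": 800.0,
                    "t1": 2000.0, "record_every": 2},
            "output": {"normalize": True},
        }
    raise ValueError(f"unknown fixture {name!r}")
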