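import numpy as np
import pytest

import qclines as q
from qclines.units import ANG_PER_CM, C_CM_FS


def _analytic_record(tau_fs=50.0, t_max=500.0, dt=0.5, carrier=1000.0,
                     kind="absorption", values=None):
    t = np.arange(0.0, t_max + dt, dt)
    if values is None:
        values = np.exp(-t / tau_fs)
    return q.CorrelationRecord(times=t, values=values.astype(complex),
                               stderr=np.zeros_like(t), n_trajectories=1,
                               kind=kind, carrier=carrier)


def test_lorentzian_transform_closed_form():
    """C(t) = e^{-i w0 t - t/tau} transforms to a Lorentzian centered at
    w0 with half-width 1/tau (in angular units)."""
    tau = 50.0
    rec = _analytic_record(tau_fs=tau, t_max=2000.0)
    grid = np.linspace(rec.carrier - 300, rec.carrier + 300, 601)
    spec = q.spectrum_from_correlation(rec, grid, normalize=False)
    detune_ang = ANG_PER_CM * (grid - rec.carrier)
    expected = (1.0 / tau) / ((1.0 / tau) ** 2 + detune_ang ** 2)
    assert np.allclose(spec.intensity, expected, rtol=2e-3, atol=1e-3 * tau)
    # peak at w0, HWHM = 1/tau in angular units
    pk = q.find_peaks(spec)[0]
    assert pk[0] == pytest.approx(rec.carrier, abs=1.0)
    hwhm_cm = 1.0 / (tau * ANG_PER_CM)
    half = spec.intensity > 0.5 * spec.intensity.max()
    width = grid[half][-1] - grid[half][0]
    assert width == pytest.approx(2 * hwhm_cm, rel=0.05)


def test_absorption_sum_rule():
    """The integral of the unnormalized, prefactor-free absorption
    lineshape over wavenumber equals C(0)/(2c) in this convention
    (Gaussian envelope, so the integration window captures the tails)."""
    t = np.arange(0.0, 600.0, 0.25)
    vals = 1.7 * np.exp(-(t / 40.0) ** 2)
    rec = q.CorrelationRecord(times=t, values=vals.astype(complex),
                              stderr=np.zeros_like(t), n_trajectories=1,
                              kind="absorption", carrier=1000.0)
    grid = np.linspace(rec.carrier - 2000, rec.carrier + 2000, 4001)
    spec = q.spectrum_from_correlation(rec, grid, normalize=False)
    integral = np.trapezoid(spec.intensity, grid)
    assert integral == pytest.approx(abs(rec.values[0]) / (2 * C_CM_FS),
                                     rel=1e-3)


def test_fluorescence_sign_convention():
    """An emission correlation e^{+i dw t} (envelope about the carrier)
    must appear at carrier + dw under the emission transform."""
    t = np.arange(0.0, 2000.0, 0.5)
    dw = 80.0  # cm^-1 detuning above carrier
    vals = np.exp((1j * ANG_PER_CM * dw - 1 / 300.0) * t)
    rec = q.CorrelationRecord(times=t, values=vals,
                              stderr=np.zeros_like(t), n_trajectories=1,
                              kind="fluorescence", carrier=1000.0)
    spec = q.spectrum_from_correlation(rec)
    assert q.find_peaks(spec)[0][0] == pytest.approx(1080.0, abs=1.5)


def test_normalization_unit_maximum():
    rec = _analytic_record()
    spec = q.spectrum_from_correlation(rec, normalize=True)
    assert spec.intensity.max() == 1.0


def test_ground_offset_shifts_axis():
    rec = _analytic_record(carrier=100.0)
    spec = q.spectrum_from_correlation(rec, ground_offset=15000.0)
    assert q.find_peaks(spec)[0][0] == pytest.approx(15100.0, abs=1.5)


def test_decay_warning_for_truncated_correlation():
    rec = _analytic_record(tau_fs=5000.0, t_max=100.0)
    with pytest.warns(UserWarning, match="truncation"):
        q.spectrum_from_correlation(rec)


def test_negative_intensity_preserved():
    """Dispersive components produce negative regions that must survive
    untouched (no clipping)."""
    t = np.arange(0.0, 1000.0, 0.5)
    vals = (0.2 + 1j) * np.exp(-t / 80.0)
    rec = q.CorrelationRecord(times=t, values=vals,
                              stderr=np.zeros_like(t), n_trajectories=1,
                              kind="absorption", carrier=500.0)
    spec = q.spectrum_from_correlation(rec, normalize=True)
    assert spec.intensity.min() < -0.01


def test_correlation_initial_value(dimer_fixture):
    """C(0) equals the isotropic average (1/3) sum_n |mu_0n|^2."""
    system, sd, T = dimer_fixture
    bath = q.discretize_bath(sd, 20, 2)
    cfg = q.EngineConfig(method="fbts", dt=1.0, t_max=1.0)
    rec = q.absorption_correlation(system, bath, T, cfg, 4000, 21)
    target = system.dipole_strength() / 3.0
    assert abs(rec.values[0] - target) < 4 * rec.stderr[0] + 1e-12
    assert rec.stderr.shape == rec.values.shape


def test_dipole_cross_terms(dimer_fixture):
    """Absorption C(0) is always (1/3) sum |mu_n|^2 (the ground-state
    start carries no cross-site terms); fluorescence C(0) picks up
    mu_1.mu_2 cross terms only through equilibrium coherences, which the
    perpendicular-dipole dimer suppresses."""
    system, sd, T = dimer_fixture
    bath = q.discretize_bath(sd, 10, 2)
    cfg = q.EngineConfig(method="fbts", dt=1.0, t_max=1.0)
    rec_perp = q.absorption_correlation(system, bath, T, cfg, 6000, 31)
    assert abs(rec_perp.values[0] - 2 / 3) < 4 * rec_perp.stderr[0]
    # fluorescence from a coherent state: perpendicular dipoles kill the
    # rho_12 contribution, parallel dipoles double C(0)
    rho = np.full((2, 2), 0.5)
    for dipoles, c0 in (([[1.0, 0, 0], [0, 1.0, 0]], 1 / 3),
                        ([[1.0, 0, 0], [1.0, 0, 0]], 2 / 3)):
        sys_d = q.ExcitonSystem(site_energies=system.site_energies,
                                couplings=system.couplings,
                                dipoles=np.array(dipoles))
        eq = q.EquilibriumState(rho_site=rho, source="jeff",
                                ensemble=q.draw_ensemble(
                                    sys_d, bath, "fbts", T, 4000, 31,
                                    include_ground=False))
        rec = q.fluorescence_correlation(sys_d, bath, eq, cfg, 31)
        assert abs(rec.values[0] - c0) < 4 * rec.stderr[0] + 1e-12


def test_monomer_free_correlation_phase(monomer, zero_bath):
    """Single site, lambda = 0: C(t) = (1/3)|mu|^2 e^{-i eps t}."""
    cfg = q.EngineConfig(method="fbts", dt=1.0, t_max=100.0,
                         record_every=5)
    rec = q.absorption_correlation(monomer, zero_bath, 300.0, cfg,
                                   3000, 41)
    absolute = rec.values * np.exp(-1j * ANG_PER_CM * rec.carrier
                                   * rec.times)
    expected = (1.0 / 3.0) * np.exp(-1j * ANG_PER_CM * 100.0 * rec.times)
    assert np.abs(absolute - expected).max() < 5 * rec.stderr.max()


def test_monomer_stokes_shift(monomer):
    """For lambda > 0 the emission maximum lies below the absorption
    maximum (positive Stokes shift)."""
    system = q.ExcitonSystem(site_energies=monomer.site_energies,
                             couplings=monomer.couplings,
                             dipoles=monomer.dipoles,
                             ground_offset=15000.0)
    sd = q.SpectralDensityParams(kind="debye", lam=60.0, gamma_fs=100.0)
    bath = q.discretize_bath(sd, 40, 1)
    cfg = q.EngineConfig(method="pbme_nh", dt=1.0, t_max=400.0,
                         record_every=2)
    rec_a = q.absorption_correlation(system, bath, 300.0, cfg, 3000, 5)
    spec_a = q.spectrum_from_correlation(rec_a, ground_offset=15000.0)
    eq = q.equilibrate(system, bath, 300.0, cfg, mode="jeff", t1=800.0,
                       n_traj=3000, seed=5)
    rec_f = q.fluorescence_correlation(system, bath, eq, cfg, 5,
                                       reuse_mapping=True)
    spec_f = q.spectrum_from_correlation(rec_f, ground_offset=15000.0)
    spec_f.meta["method"] = "pbme_nh_jeff"
    spec_f = q.apply_half_lambda_redshift(spec_f, 60.0)
    assert q.find_peaks(spec_a)[0][0] > q.find_peaks(spec_f)[0][0]


def test_half_lambda_redshift_bookkeeping():
    rec = _analytic_record(kind="fluorescence", carrier=12000.0)
    spec = q.spectrum_from_correlation(rec)
    spec.meta["method"] = "pbme_nh_jeff"
    for lam, shift in ((60.0, 30.0), (35.0, 17.5), (0.0, 0.0)):
        shifted = q.apply_half_lambda_redshift(spec, lam)
        assert np.allclose(shifted.wavenumbers,
                           spec.wavenumbers - shift)
        assert shifted.meta["half_lambda_shift"] == shift
    with pytest.raises(ValueError, match="already applied"):
        q.apply_half_lambda_redshift(
            q.apply_half_lambda_redshift(spec, 60.0), 60.0)
    fbts_spec = q.spectrum_from_correlation(rec)
    fbts_spec.meta["method"] = "fbts"
    with pytest.raises(ValueError, match="PBME-nH"):
        q.apply_half_lambda_redshift(fbts_spec, 60.0)
    abs_spec = q.spectrum_from_correlation(
        _analytic_record(kind="absorption"))
    abs_spec.meta["method"] = "pbme_nh"
    with pytest.raises(ValueError, match="fluorescence"):
        q.apply_half_lambda_redshift(abs_spec, 60.0)


def test_ensemble_average_properties():
    rec = _analytic_record()
    s1 = q.spectrum_from_correlation(rec, normalize=False)
    s2 = q.Spectrum(s1.wavenumbers.copy(), 2.0 * s1.intensity)
    same = q.ensemble_average([s1], [1.0])
    assert np.array_equal(same.intensity, s1.intensity)
    mix = q.ensemble_average([s1, s2], [0.65, 0.35])
    assert np.allclose(mix.intensity,
                       0.65 * s1.intensity + 0.35 * s2.intensity)
    conv = q.ensemble_average([s1, q.Spectrum(s1.wavenumbers.copy(),
                                              s1.intensity.copy())],
                              [0.3, 0.7])
    assert np.allclose(conv.intensity, s1.intensity)
    with pytest.raises(ValueError):
        q.ensemble_average([s1, s2], [0.6, 0.6])
    with pytest.raises(ValueError):
        q.ensemble_average([s1], [0.5, 0.5])


def test_mc_error_scaling(dimer_fixture):
    """Spectrum error bands derive from correlation standard errors that
    shrink as 1/sqrt(n_traj) (checked at n and 4n)."""
    system, sd, T = dimer_fixture
    bath = q.discretize_bath(sd, 20, 2)
    cfg = q.EngineConfig(method="fbts", dt=1.0, t_max=100.0,
                         record_every=5)
    r1 = q.absorption_correlation(system, bath, T, cfg, 1000, 51)
    r4 = q.absorption_correlation(system, bath, T, cfg, 4000, 51)
    ratio = np.median(r1.stderr[1:] / r4.stderr[1:])
    assert ratio == pytest.approx(2.0, rel=0.2)
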