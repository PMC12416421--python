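"""Coupled solver: limits, conservation, convergence."""

import numpy as np
import pytest

from femtoplasma.solver import (SolverPolicy, build_system,
                                conservation_report, get_element_model,
                                run_simulation)
from femtoplasma.target import PulseProfile, TargetComposition


def test_zero_fluence_keeps_everything_neutral(cno_target):
    pulse = PulseProfile(photon_kev=9.0, fluence_per_um2=0.0, fwhm_fs=15.0)
    traj = run_simulation(cno_target, pulse, SolverPolicy(out_dt=2.0),
                          -3.0, 3.0)
    for sym in traj.element_symbols:
        assert np.all(np.abs(traj.charge_trace(sym)) < 1e-14)
    assert traj.samples[-1].free_density == 0.0
    rep = conservation_report(traj)
    assert rep["max_electron_drift"] == 0.0
    assert rep["max_energy_residual"] == 0.0


def test_all_processes_disabled_state_frozen(cno_target):
    pulse = PulseProfile(photon_kev=9.0, fluence_per_um2=1e12, fwhm_fs=15.0)
    pol = SolverPolicy(photo=False, auger=False, fluor=False, eii=False,
                       tbr=False, ee=False, out_dt=1.0)
    sys_ = build_system(cno_target, pulse, pol)
    y0 = sys_._pack().copy()
    traj = sys_.run(-2.0, 2.0)
    assert np.allclose(sys_._pack(), y0)
    assert np.all(traj.charge_trace("C") == 0.0)


def test_pure_photoionization_exponential_decay():
    """Constant flux on a one-subshell element: P(t) = exp(-sigma J t)."""
    tc = TargetComposition(counts={"H": 1000}, density_g_cm3=1.0)
    pulse = PulseProfile(photon_kev=1.0, fluence_per_um2=1e13,
                         shape="square", fwhm_fs=10.0)
    pol = SolverPolicy(ee=False, eii=False, tbr=False, out_dt=1.0)
    traj = run_simulation(tc, pulse, pol, -5.0, 5.0)
    em = get_element_model(1)
    line = em.photo_lines(em.ground_index)[0]
    sig = em.photo_sigma(line, 1000.0)
    J = 1e8 * 1e13 / 10.0
    for s in traj.samples:
        expected = 1.0 - np.exp(-sig * J * (s.t + 5.0))
        assert s.charges["H"] == pytest.approx(expected, abs=1e-4)


def test_inverted_window_rejected(cno_target):
    pulse = PulseProfile(photon_kev=9.0, fluence_per_um2=1e12)
    sys_ = build_system(cno_target, pulse)
    with pytest.raises(ValueError):
        sys_.run(3.0, -3.0)


def test_conservation_on_full_cno_run(cno_trajectory):
    """Bound+free electron count and the energy ledger close tightly."""
    rep = conservation_report(cno_trajectory)
    assert rep["max_electron_drift"] <= 1e-6
    assert rep["max_energy_residual"] <= 1e-3


def test_charges_monotone_under_pure_ionizing_pulse(cno_trajectory):
    c = cno_trajectory.charge_trace("C")
    assert c[0] == pytest.approx(0.0, abs=1e-12)
    assert c[-1] > 0.3
    # during illumination the charge rises monotonically
    t = cno_trajectory.times
    sel = (t > -15) & (t < 15)
    assert np.all(np.diff(c[sel]) > -1e-6)


def test_self_convergence_in_step_tolerance(cno_target):
    """Halving the integrator tolerance changes the carbon charge by
    well under a percent."""
    pulse = PulseProfile(photon_kev=9.0, fluence_per_um2=1e12, fwhm_fs=15.0)
    charges = []
    for rtol in (3e-4, 1.5e-4):
        traj = run_simulation(cno_target, pulse,
                              SolverPolicy(rtol=rtol, out_dt=2.0),
                              -18.0, -6.0)
        charges.append(traj.charge_trace("C")[-1])
    assert charges[0] == pytest.approx(charges[1], rel=0.01)


def test_free_electrons_thermalize_with_ee_only():
    """With EE alone (no pulse), an injected non-thermal distribution
    relaxes to a Maxwellian of the same density and energy."""
    tc = TargetComposition(counts={"H": 1000}, density_g_cm3=1.0)
    pulse = PulseProfile(photon_kev=1.0, fluence_per_um2=0.0)
    pol = SolverPolicy(photo=False, auger=False, fluor=False, eii=False,
                       tbr=False, out_dt=10.0, dt_max=2.0)
    sys_ = build_system(tc, pulse, pol)
    b = sys_.basis
    n0 = 2e21
    sys_.coef = (b.project_delta(30.0, 0.5 * n0)
                 + b.project_delta(120.0, 0.5 * n0))
    e0 = float(b.m1 @ sys_.coef)
    traj = sys_.run(0.0, 400.0)
    c = sys_.coef
    n1, e1 = b.moments(c)
    assert n1 == pytest.approx(n0, rel=1e-6)
    assert e1 == pytest.approx(e0, rel=1e-6)
    T = (2.0 / 3.0) * e1 / n1
    # Kullback-Leibler divergence to the analytic Maxwellian
    es = np.geomspace(0.5, 12 * T, 400)
    fm = n1 * 2 / np.sqrt(np.pi) * T**-1.5 * np.sqrt(es) * np.exp(-es / T)
    fv = np.maximum(b.evaluate(c, es), 1e-30 * n1)
    p = fv / np.trapezoid(fv, es)
    q = fm / np.trapezoid(fm, es)
    kl = float(np.trapezoid(p * np.log(p / q), es))
    assert kl < 1e-3
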