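"""Collision operators: bookkeeping exactness, equilibria, MC cross-check."""

import numpy as np
import pytest

from helpers import maxwellian


# ---------------------------------------------------------------------------
# EII operator
def test_eii_zero_distribution_zero_action(thermal_kinetics):
    kin = thermal_kinetics
    ops = kin.eii_ops(B=20.0, U=15.0, N=2.0)
    z = np.zeros(kin.basis.K)
    assert np.all(ops.gain @ z == 0.0)
    assert ops.rate_vec @ z == 0.0


def test_eii_event_bookkeeping(thermal_kinetics):
    """Per ionization event: one impactor out, two slower electrons in
    (net +1 electron), free kinetic energy drops by exactly B."""
    kin = thermal_kinetics
    b = kin.basis
    B = 20.0
    ops = kin.eii_ops(B=B, U=15.0, N=2.0)
    for c in (b.project_delta(500.0, 1.0),
              b.project_function(maxwellian(1e21, 40.0))):
        rate = float(ops.rate_vec @ c)
        assert rate > 0
        dc_gain = ops.gain @ c
        dc_loss = -b.solve_mass(b.Bq.T @ (kin.wm * ops.loss_q * (b.Bq @ c)))
        dn = b.m0 @ (dc_gain + dc_loss)
        de = b.m1 @ (dc_gain + dc_loss)
        assert dn == pytest.approx(rate, rel=1e-10)
        assert de == pytest.approx(-B * rate, rel=1e-8)


def test_eii_monoenergetic_number_gain(thermal_kinetics):
    """Monoenergetic electrons at 3B on a one-subshell gas: each loss
    event produces two slower electrons, net +1 per ionization."""
    kin = thermal_kinetics
    b = kin.basis
    B = 160.0
    ops = kin.eii_ops(B=B, U=100.0, N=1.0)
    c = b.project_delta(3 * B, 1.0)
    rate = float(ops.rate_vec @ c)
    dn_gain = float(b.m0 @ (ops.gain @ c))
    assert dn_gain == pytest.approx(2.0 * rate, rel=1e-9)


# ---------------------------------------------------------------------------
# TBR operator
def test_tbr_zero_and_bilinear(thermal_kinetics):
    kin = thermal_kinetics
    ops = kin.tbr_ops(B=20.0, U=15.0, N=1.0, g_lower=2.0, g_upper=1.0)
    z = np.zeros(kin.basis.K)
    dc, ev = kin.tbr_apply(ops, z)
    assert ev == 0.0 and np.all(dc == 0.0)
    c = kin.basis.project_function(maxwellian(1e21, 10.0))
    _, ev1 = kin.tbr_apply(ops, c)
    _, ev2 = kin.tbr_apply(ops, 2.0 * c)
    assert ev2 == pytest.approx(4.0 * ev1, rel=1e-10)


def test_tbr_event_bookkeeping(thermal_kinetics):
    """Each TBR event removes two electrons and re-emits one carrying
    the pair energy plus B."""
    kin = thermal_kinetics
    b = kin.basis
    B = 20.0
    ops = kin.tbr_ops(B=B, U=15.0, N=1.0, g_lower=2.0, g_upper=1.0)
    c = b.project_function(maxwellian(2e21, 8.0))
    dc, ev = kin.tbr_apply(ops, c)
    assert b.m0 @ dc == pytest.approx(-ev, rel=1e-10)
    # energy: -(e1+e2) removed, +(e1+e2+B) added => net +B per event
    assert b.m1 @ dc == pytest.approx(B * ev, rel=1e-8)


def test_saha_stationarity_of_discrete_operators(thermal_kinetics):
    """EII/TBR operator pair drives a closed two-state element to the
    Saha ratio: stationary ratio within 1% of the closed form."""
    kin = thermal_kinetics
    B, U, N = 20.0, 15.0, 1.0
    g_lo, g_up = 2.0, 1.0
    kT, n_e = 12.0, 2.0e21
    c = kin.basis.project_function(maxwellian(n_e, kT))
    eii = kin.eii_ops(B, U, N)
    tbr = kin.tbr_ops(B, U, N, g_lo, g_up)
    r_ion = float(eii.rate_vec @ c)
    _, r_rec = kin.tbr_apply(tbr, c)
    ratio = r_ion / r_rec
    hb = 4.787859e-15
    saha = (2 * g_up / g_lo) * (kT / hb)**1.5 * np.exp(-B / kT) / n_e
    assert ratio == pytest.approx(saha, rel=0.01)


# ---------------------------------------------------------------------------
# EE operator
def test_ee_maxwellian_stationary(thermal_kinetics):
    kin = thermal_kinetics
    b = kin.basis
    cm = b.project_function(maxwellian(1e21, 10.0))
    cb = b.project_function(lambda e: 0.5 * (maxwellian(1e21, 4.0)(e)
                                             + maxwellian(1e21, 16.0)(e)))
    def mnorm(v):
        return float(np.sqrt(v @ b.mass @ v))
    r_eq = mnorm(kin.ee_apply(cm))
    r_ne = mnorm(kin.ee_apply(cb))
    assert r_eq <= 1e-2 * r_ne


def test_ee_conserves_number_and_energy_over_many_applications(
        thermal_kinetics):
    kin = thermal_kinetics
    b = kin.basis
    c = b.project_function(lambda e: 0.5 * (maxwellian(1e21, 4.0)(e)
                                            + maxwellian(1e21, 16.0)(e)))
    n0, e0 = b.moments(c)
    dt = 1e-3
    for _ in range(10000):
        c = c + dt * kin.ee_apply(c)
    n1, e1 = b.moments(c)
    assert abs(n1 - n0) <= 1e-4 * n0
    assert abs(e1 - e0) <= 1e-4 * e0


def test_ee_bimodal_relaxes_to_energy_weighted_maxwellian(thermal_kinetics):
    """Two equal-density 4/16 eV populations relax to one Maxwellian at
    (4+16)/2 = 10 eV; the temperature is fixed by energy conservation."""
    kin = thermal_kinetics
    b = kin.basis
    n = 1e21
    c = b.project_function(lambda e: 0.5 * (maxwellian(n, 4.0)(e)
                                            + maxwellian(n, 16.0)(e)))
    n0, e0 = b.moments(c)
    I = np.eye(b.K)
    for _ in range(700):   # Crank-Nicolson, dt = 0.5 fs
        E = kin.ee_linear_matrix(c)
        c = np.linalg.solve(I - 0.25 * E, c + 0.25 * (E @ c))
        c = b.fix_moments(c, n0, e0)
    T_f = (2.0 / 3.0) * (b.m1 @ c) / (b.m0 @ c)
    assert T_f == pytest.approx(10.0, rel=0.01)
    # and the late-time shape follows exp(-e/T) over the thermal range
    es = np.linspace(2.0, 40.0, 40)
    fv = b.evaluate(c, es) / np.sqrt(es)
    slope = np.polyfit(es, np.log(fv), 1)[0]
    assert -1.0 / slope == pytest.approx(10.0, rel=0.1)


def test_ee_entropy_nondecreasing(thermal_kinetics):
    """Numerical H-theorem along the relaxation of a bimodal state."""
    kin = thermal_kinetics
    b = kin.basis
    n = 1e21
    c = b.project_function(lambda e: 0.5 * (maxwellian(n, 4.0)(e)
                                            + maxwellian(n, 16.0)(e)))
    n0, e0 = b.moments(c)
    I = np.eye(b.K)

    def entropy(coef):
        f = np.maximum(b.Bq @ coef, 1e-30)  # phi ~ F0 up to normalization
        return -float(np.sum(b.quad_wm * f * np.log(f)))

    s_prev = entropy(c)
    for _ in range(40):
        E = kin.ee_linear_matrix(c)
        c = np.linalg.solve(I - 0.25 * E, c + 0.25 * (E @ c))
        c = b.fix_moments(c, n0, e0)
        s = entropy(c)
        assert s >= s_prev - 1e-9 * abs(s_prev)
        s_prev = s
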