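"""Spline basis: partition of unity, projections, moments, regridding."""

import numpy as np
import pytest

from femtoplasma.splines import (FreeElectronDistribution, GridSpec,
                                 SplineBasis, build_basis, regrid)


from helpers import maxwellian


def test_partition_of_unity_random_points(thermal_basis):
    rng = np.random.default_rng(3)
    x = rng.uniform(*thermal_basis.domain, 100)
    s = thermal_basis.design(x).sum(axis=1)
    assert np.max(np.abs(s - 1.0)) < 1e-12


def test_mass_matrix_spd(thermal_basis):
    ev = np.linalg.eigvalsh(thermal_basis.mass)
    assert ev.min() > 0


def test_too_few_knots_rejected():
    with pytest.raises(ValueError):
        SplineBasis(np.array([0.0, 1.0, 2.0]), order=4)


def test_maxwellian_projection_accuracy(thermal_basis):
    """L2 relative error of a 10 eV Maxwellian on the thermal-dense grid."""
    f = maxwellian(1e21, 10.0)
    c = thermal_basis.project_function(f)
    xs = np.linspace(0.05, 150.0, 2000)
    num = thermal_basis.evaluate(c, xs)
    err = np.sqrt(np.trapezoid((num - f(xs))**2, xs)
                  / np.trapezoid(f(xs)**2, xs))
    assert err < 1e-3


def test_delta_projection_moments(thermal_basis):
    for e0, rate in [(500.0, 3.5), (12.0, 1e20), (1999.0, 0.1)]:
        dc = thermal_basis.project_delta(e0, rate)
        n, en = thermal_basis.moments(dc)
        assert n == pytest.approx(rate, rel=1e-10)
        assert en == pytest.approx(rate * e0, rel=1e-10)
    assert np.all(thermal_basis.project_delta(500.0, 0.0) == 0.0)


def test_delta_outside_domain_signals_regrid(thermal_basis):
    with pytest.raises(ValueError, match="regrid"):
        thermal_basis.project_delta(5000.0, 1.0)


def test_split_delta_converges_to_single(thermal_basis):
    """Two deltas at e0 +- d approach one delta at e0 as d -> 0."""
    e0, rate = 500.0, 2.0
    ref = thermal_basis.project_delta(e0, rate)
    prev = None
    for d in (16.0, 4.0, 1.0):
        two = (thermal_basis.project_delta(e0 - d, rate / 2)
               + thermal_basis.project_delta(e0 + d, rate / 2))
        err = np.linalg.norm(two - ref)
        if prev is not None:
            assert err < prev
        prev = err
    assert prev < 0.15 * np.linalg.norm(ref)


def test_peak_outside_domain_errors():
    with pytest.raises(ValueError):
        build_basis(GridSpec(emax=1000.0, peaks=(6800.0,)))


def test_regrid_identity_and_roundtrip(thermal_basis):
    f = maxwellian(1e21, 10.0)
    c = thermal_basis.project_function(f)
    same = regrid(c, thermal_basis, thermal_basis)
    assert np.allclose(same, c, rtol=1e-8, atol=1e-8 * np.abs(c).max())
    fine = build_basis(GridSpec(emax=2000.0, peaks=(500.0,),
                                thermal_max=300.0, n_log=112))
    c2 = regrid(c, thermal_basis, fine)
    c3 = regrid(c2, fine, thermal_basis)
    n0, e0 = thermal_basis.moments(c)
    n3, e3 = thermal_basis.moments(c3)
    assert n3 == pytest.approx(n0, rel=1e-10)
    assert e3 == pytest.approx(e0, rel=1e-10)


def test_regrid_refinement_reduces_pointwise_error(thermal_basis):
    f = maxwellian(1e21, 10.0)
    coarse = build_basis(GridSpec(emax=2000.0, thermal_max=300.0, n_log=24))
    c0 = coarse.project_function(f)
    fine = build_basis(GridSpec(emax=2000.0, thermal_max=300.0, n_log=96))
    xs = np.linspace(0.2, 120.0, 800)
    err_coarse = np.max(np.abs(coarse.evaluate(c0, xs) - f(xs)))
    c1 = regrid(c0, coarse, fine)
    # projecting the true function on the fine grid beats the coarse grid
    cf = fine.project_function(f)
    err_fine = np.max(np.abs(fine.evaluate(cf, xs) - f(xs)))
    assert err_fine < err_coarse
    # and the regridded representation preserves moments exactly
    assert fine.m0 @ c1 == pytest.approx(coarse.m0 @ c0, rel=1e-12)


def test_regrid_truncation_detected(thermal_basis):
    c = thermal_basis.project_delta(1500.0, 1.0)
    small = build_basis(GridSpec(emax=800.0, thermal_max=300.0, n_log=40))
    with pytest.raises(ValueError, match="truncate"):
        regrid(c, thermal_basis, small)


def test_distribution_container(thermal_basis):
    f = maxwellian(2e21, 8.0)
    fed = FreeElectronDistribution(thermal_basis,
                                   thermal_basis.project_function(f))
    assert fed.density() == pytest.approx(2e21, rel=1e-4)
    assert fed.temperature_estimate() == pytest.approx(8.0, rel=1e-3)
    assert fed(np.array([8.0]))[0] == pytest.approx(f(8.0), rel=1e-3)
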