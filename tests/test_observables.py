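"""Observables: charges, intensity averages, EDR, contrast, snapshots."""

import numpy as np
import pytest

from femtoplasma.observables import (average_charge_trace,
                                     compute_edr, distribution_snapshot,
                                     intensity_averaged,
                                     ionization_contrast,
                                     light_atom_charge_trace,
                                     occupancy_trace)
from femtoplasma.solver import (SolverPolicy, Trajectory, TrajectorySample,
                                build_system)
from femtoplasma.target import PulseProfile, TargetComposition


@pytest.fixture(scope="module")
def probe():
    return PulseProfile(photon_kev=7.112, fluence_per_um2=1e12,
                        fwhm_fs=15.0)


def _fake_trajectory(times, charges_by_symbol, basis, pulse):
    """Hand-built trajectory with prescribed charge traces."""
    symbols = list(charges_by_symbol)
    samples = []
    for i, t in enumerate(times):
        samples.append(TrajectorySample(
            t=float(t), coef=np.zeros(basis.K), populations={},
            charges={s: charges_by_symbol[s][i] for s in symbols},
            shell_occ={}, ledgers={"absorbed_ev": 0.0, "radiated_ev": 0.0},
            free_density=0.0, free_energy=0.0, bound_electrons_cm3=0.0,
            bound_energy_cm3=0.0))
    return Trajectory(samples=samples, basis=basis, target=None,
                      pulse=pulse, policy=SolverPolicy(),
                      element_symbols=symbols,
                      densities={s: 1.0 for s in symbols},
                      ground_bound={}, shell_labels={s: [] for s in symbols})


@pytest.fixture(scope="module")
def undamaged_gd_traj(probe):
    """Zero-fluence run of the Gd-holding target: everything neutral."""
    tc = TargetComposition(
        counts={"C": 20, "N": 10, "O": 10, "Gd": 1}, density_g_cm3=1.2)
    pulse = PulseProfile(photon_kev=7.112, fluence_per_um2=0.0,
                         fwhm_fs=15.0)
    pol = SolverPolicy(out_dt=5.0, heavy_mode="primary_only")
    sys_ = build_system(tc, pulse, pol)
    return sys_.run(-20.0, 20.0)


def test_intensity_average_of_constant_is_constant(probe, thermal_basis):
    t = np.linspace(-20, 20, 201)
    traj = _fake_trajectory(t, {"C": np.full(t.size, 3.3)}, thermal_basis,
                            probe)
    val = intensity_averaged(traj.times, traj.charge_trace("C"), probe)
    assert val == pytest.approx(3.3, rel=1e-12)


def test_intensity_average_linear_and_monotone(probe, thermal_basis):
    t = np.linspace(-20, 20, 201)
    x1 = 1.0 + 0.02 * (t + 20)
    x2 = x1 + 0.5
    a1 = intensity_averaged(t, x1, probe)
    a2 = intensity_averaged(t, x2, probe)
    assert a2 == pytest.approx(a1 + 0.5, rel=1e-10)       # linearity
    assert a2 > a1                                         # monotone
    # antisymmetric trace about the peak averages to its midpoint value
    anti = 2.0 + 0.1 * t
    assert intensity_averaged(t, anti, probe) == pytest.approx(2.0,
                                                               abs=1e-6)


def test_intensity_average_coverage_error(probe):
    t = np.linspace(-2, 2, 50)   # covers almost none of a 15 fs pulse
    with pytest.raises(ValueError, match="covers"):
        intensity_averaged(t, np.ones_like(t), probe)


def test_undamaged_edr_is_ratio_of_neutral_counts(undamaged_gd_traj, probe):
    res = compute_edr(undamaged_gd_traj, "Gd",
                      {"C": 20, "N": 10, "O": 10}, probe)
    assert res.ratio == pytest.approx(64.0 / 270.0, rel=1e-10)
    assert res.undamaged_ratio == pytest.approx(64.0 / 270.0, rel=1e-12)
    # reference = the heavy atom itself -> exactly 1
    res2 = compute_edr(undamaged_gd_traj, "Gd", {"Gd": 1}, probe)
    assert res2.ratio == pytest.approx(1.0, rel=1e-12)


def test_missing_element_raises(undamaged_gd_traj, probe):
    with pytest.raises(KeyError):
        compute_edr(undamaged_gd_traj, "Fe", {"C": 20}, probe)
    with pytest.raises(KeyError):
        average_charge_trace(undamaged_gd_traj, "Xe")


def test_ionization_contrast_synthetic(probe, thermal_basis):
    """Frozen light atoms + known Gd charge difference Delta: the
    uncorrected contrast returns Delta exactly; once light atoms ionize,
    the corrected (EDR-inferred) contrast drops below it."""
    t = np.linspace(-20, 20, 201)
    z = np.zeros(t.size)
    delta = 7.0
    frozen = {"C": z, "N": z, "O": z}
    hi = _fake_trajectory(t, {"Gd": np.full(t.size, delta), **frozen},
                          thermal_basis, probe)
    lo = _fake_trajectory(t, {"Gd": z, **frozen}, thermal_basis, probe)
    ref = {"C": 20, "N": 10, "O": 10}
    assert ionization_contrast(hi, lo, probe, "Gd", ref) == pytest.approx(
        delta, rel=1e-10)
    assert ionization_contrast(hi, lo, probe, "Gd", ref,
                               correct_light=True) == pytest.approx(
        delta, rel=1e-10)
    # now let the light atoms ionize in the high-fluence exposure
    light = {"C": np.full(t.size, 1.5), "N": np.full(t.size, 1.5),
             "O": np.full(t.size, 1.5)}
    hi2 = _fake_trajectory(t, {"Gd": np.full(t.size, delta), **light},
                           thermal_basis, probe)
    corr = ionization_contrast(hi2, lo, probe, "Gd", ref,
                               correct_light=True)
    uncorr = ionization_contrast(hi2, lo, probe, "Gd", ref)
    assert uncorr == pytest.approx(delta, rel=1e-10)
    assert corr < uncorr


def test_mismatched_targets_rejected(probe, thermal_basis):
    t = np.linspace(-20, 20, 51)
    a = _fake_trajectory(t, {"Gd": np.zeros(51), "C": np.zeros(51)},
                         thermal_basis, probe)
    b = _fake_trajectory(t, {"Gd": np.zeros(51), "N": np.zeros(51)},
                         thermal_basis, probe)
    with pytest.raises(ValueError):
        ionization_contrast(a, b, probe, "Gd", {"C": 20})


def test_snapshot_consistency_with_ledgers(cno_trajectory):
    s = cno_trajectory.samples[len(cno_trajectory.samples) // 2]
    snap = distribution_snapshot(cno_trajectory, s.t, n_points=800)
    dens = np.trapezoid(snap["f_cm3_eV"], snap["energy_eV"])
    assert dens == pytest.approx(s.free_density, rel=5e-3)
    assert snap.attrs["total_density_cm3"] == pytest.approx(
        s.free_density, rel=1e-9)
    with pytest.raises(ValueError):
        distribution_snapshot(cno_trajectory, 1e4)


def test_snapshot_before_ionization_is_zero(cno_trajectory):
    snap = distribution_snapshot(cno_trajectory,
                                 cno_trajectory.times[0])
    assert np.all(snap["f_cm3_eV"] == 0.0)


def test_occupancy_and_light_atom_traces(cno_trajectory):
    df = occupancy_trace(cno_trajectory, "C")
    assert set(df["shell"]) == {"1s", "2s", "2p"}
    start = df[(df.time_fs == df.time_fs.min())]
    occ0 = dict(zip(start["shell"], start["occupancy_e"]))
    assert occ0 == {"1s": 2.0, "2s": 2.0, "2p": 2.0}
    la = light_atom_charge_trace(cno_trajectory)
    traces = np.vstack([cno_trajectory.charge_trace(s)
                        for s in ("C", "N", "O")])
    assert np.all(la >= traces.min(axis=0) - 1e-12)
    assert np.all(la <= traces.max(axis=0) + 1e-12)
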