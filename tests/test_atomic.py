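"""Atomic structure: configurations, mean field, cross-sections, decay."""

import itertools

import numpy as np
import pytest
from mpmath import mp

from femtoplasma.atomic import (enumerate_configurations, solve_mean_field)
from femtoplasma.atomic.configurations import ionization_path
from femtoplasma.atomic.rates import (beb_cross_section, beb_sdcs,
                                      photo_cross_section, tbr_kernel)
from femtoplasma.constants import electron_speed_cm_fs
from femtoplasma.solver import get_element_model


# ---------------------------------------------------------------------------
# configuration enumeration
@pytest.mark.parametrize("Z,expected", [(1, 2), (6, 27), (8, 45), (16, 945)])
def test_configuration_counts(Z, expected):
    cs = enumerate_configurations(Z)
    assert len(cs) == expected
    # ground configuration is flagged and indices round-trip uniquely
    g = cs.ground_index
    assert cs.occ_of(g) == cs.ground_occ
    seen = {cs.index_of(cs.occ_of(i)) for i in range(min(len(cs), 200))}
    assert len(seen) == min(len(cs), 200)


def test_gadolinium_collapsed_count_matches_exhaustive():
    cs = enumerate_configurations(64)
    caps = [s.capacity for s in cs.shells]
    assert caps == [2, 8, 18, 25, 9, 2]
    assert len(cs) == 400140
    # independent exhaustive enumerator over the collapsed shell structure
    count = sum(1 for _ in itertools.product(
        *[range(c + 1) for c in caps]))
    assert count == len(cs)
    # spot-check index round trip at random points
    rng = np.random.default_rng(7)
    for _ in range(50):
        occ = tuple(rng.integers(0, c + 1) for c in caps)
        assert cs.occ_of(cs.index_of(occ)) == occ


def test_unsupported_element_rejected():
    with pytest.raises(ValueError):
        enumerate_configurations(93)
    with pytest.raises(ValueError):
        enumerate_configurations(0)


# ---------------------------------------------------------------------------
# mean field
def test_hydrogen_binding_exact():
    r = solve_mean_field(1, [(1, 0, 1)])
    assert r.binding_ev[0] == pytest.approx(13.6057, abs=0.001)


def test_hydrogenic_iron_scaling():
    r = solve_mean_field(26, [(1, 0, 1)])
    assert r.binding_ev[0] == pytest.approx(13.6057 * 26**2, rel=1e-6)


def test_bare_nucleus_is_not_an_error():
    r = solve_mean_field(6, [])
    assert r.total_energy_ev == 0.0
    assert r.eps_ev.size == 0


def test_carbon_k_edge_within_ten_percent(carbon_model):
    g = carbon_model.ground_index
    thr = carbon_model.ionization_threshold(g, 0)
    assert thr == pytest.approx(296.0, rel=0.10)


def test_kinetic_energies_positive(carbon_model):
    cd = carbon_model.config_data(carbon_model.ground_index)
    assert np.all(cd.shell_kinetic_ev > 0)
    assert np.all(cd.shell_binding_ev > 0)


@pytest.mark.parametrize("Z", [2, 6, 8, 13, 16])
def test_energy_monotone_along_ionization_paths(Z):
    """Removing an electron never lowers the total energy."""
    model = get_element_model(Z)
    for order in ("outer", "inner"):
        path = ionization_path(model.configs, order)
        energies = [model.config_data(model.configs.index_of(o)
                                      ).total_energy_ev for o in path]
        diffs = np.diff(energies)
        assert np.all(diffs > 0), f"Z={Z} order={order}: {diffs}"


# ---------------------------------------------------------------------------
# photoionization
def test_hydrogen_threshold_cross_section():
    b = 13.6057
    sig = photo_cross_section(b * 1.0000001, b, 1, 1)
    assert sig == pytest.approx(6.30e-18, rel=0.005)


def test_below_threshold_zero_and_negative_energy_error():
    assert photo_cross_section(100.0, 300.0, 1, 2) == 0.0
    assert photo_cross_section(100.0, 300.0, 1, 0) == 0.0  # empty subshell
    with pytest.raises(ValueError):
        photo_cross_section(-5.0, 300.0, 1, 2)


def test_k_shell_z5_scaling_at_8kev():
    """K-shell photoabsorption grows ~Z^5 at fixed photon energy."""
    zs, sigs = [], []
    for Z in (6, 7, 8, 14, 16):
        m = get_element_model(Z)
        line = m.photo_lines(m.ground_index)[0]
        zs.append(Z)
        sigs.append(m.photo_sigma(line, 8000.0))
    slope = np.polyfit(np.log(zs), np.log(sigs), 1)[0]
    assert 4.0 <= slope <= 6.0


# ---------------------------------------------------------------------------
# decay
def test_ground_state_has_no_decay(carbon_model):
    assert carbon_model.decay_lines(carbon_model.ground_index) == []


def test_single_spectator_hole_fluoresces_only(carbon_model):
    """K hole with a single electron above: Auger needs two."""
    idx = carbon_model.configs.index_of((1, 1, 0))
    lines = carbon_model.decay_lines(idx)
    assert lines, "expected radiative decay"
    assert all(dl.kind == "fluor" for dl in lines)


def test_carbon_k_hole_lifetime_several_fs(carbon_model):
    idx = carbon_model.configs.index_of((1, 2, 2))
    tot = sum(dl.rate_fs for dl in carbon_model.decay_lines(idx))
    assert 3.0 < 1.0 / tot < 12.0   # ~6.6 fs


@pytest.mark.parametrize("Z", [16, 17, 26, 30])
def test_heavy_k_hole_decays_within_about_a_femtosecond(Z):
    m = get_element_model(Z)
    occ = list(m.configs.ground_occ)
    occ[0] -= 1
    tot = sum(dl.rate_fs for dl in m.decay_lines(m.configs.index_of(occ)))
    assert 1.0 / tot <= 1.2


def test_auger_energy_positive(sulfur_model):
    occ = list(sulfur_model.configs.ground_occ)
    occ[0] -= 1
    for dl in sulfur_model.decay_lines(sulfur_model.configs.index_of(occ)):
        assert dl.energy_ev > 0


# ---------------------------------------------------------------------------
# electron-impact ionization (BEB)
def test_beb_threshold_and_closed_form():
    B = U = 13.6
    assert beb_cross_section(13.6, B, U, 1) == 0.0
    # independent arbitrary-precision evaluation of the closed form
    mp.dps = 40
    t = mp.mpf(50) / mp.mpf("13.6")
    u = mp.mpf(1)
    a0 = mp.mpf("0.529177210903e-8")
    S = 4 * mp.pi * a0**2 * (mp.mpf("13.605693122994") / mp.mpf("13.6"))**2
    ref = S / (t + u + 1) * (mp.log(t) / 2 * (1 - 1 / t**2)
                             + 1 - 1 / t - mp.log(t) / (t + 1))
    assert beb_cross_section(50.0, B, U, 1) == pytest.approx(
        float(ref), rel=1e-10)


def test_beb_unimodal_with_log_over_t_tail():
    B = U = 13.6
    T = np.geomspace(B * 1.001, B * 3000, 400)
    s = beb_cross_section(T, B, U, 1)
    imax = int(np.argmax(s))
    assert 0 < imax < 399
    assert np.all(np.diff(s[:imax + 1]) >= -1e-30)
    assert np.all(np.diff(s[imax:]) <= 1e-30)
    # asymptotic ~ ln T / T: the ratio stabilizes
    hi = T > 100 * B
    ratio = s[hi] / (np.log(T[hi] / B) / (T[hi] / B))
    assert np.std(ratio) / np.mean(ratio) < 0.12


def test_beb_invalid_parameters():
    with pytest.raises(ValueError):
        beb_cross_section(50.0, -1.0, 13.6, 1)
    with pytest.raises(ValueError):
        beb_sdcs(50.0, 5.0, 13.6, 0.0, 1)


def test_sdcs_integrates_to_total_and_is_symmetric():
    B, U, N = 13.6, 10.0, 2.0
    from scipy.integrate import quad
    for T in (40.0, 120.0, 900.0):
        val, _ = quad(lambda w: float(beb_sdcs(T, w, B, U, N)), 0,
                      (T - B) / 2, limit=300)
        assert val == pytest.approx(
            float(beb_cross_section(T, B, U, N)), rel=1e-6)
        w = 0.3 * (T - B)
        assert float(beb_sdcs(T, w, B, U, N)) == pytest.approx(
            float(beb_sdcs(T, T - B - w, B, U, N)), rel=1e-12)
    # outside the kinematic range
    assert beb_sdcs(40.0, 50.0, B, U, N) == 0.0


def test_sdcs_soft_secondaries_dominate_at_high_impact():
    B, U = 13.6, 10.0
    T = 100 * B
    w = np.linspace(0.0, (T - B) / 2, 200)
    d = beb_sdcs(T, w, B, U, 1.0)
    assert np.argmax(d) == 0


# ---------------------------------------------------------------------------
# three-body recombination kernel
def test_tbr_kernel_nonnegative_grid():
    e = np.linspace(0.05, 120.0, 50)
    K = tbr_kernel(e[:, None], e[None, :], 20.0, 15.0, 1.0, 2.0, 1.0)
    assert np.all(K >= 0)
    assert np.all(np.isfinite(K))


def test_tbr_kernel_zero_without_vacancy():
    K = tbr_kernel(10.0, 10.0, 20.0, 15.0, 0.0, 2.0, 1.0)
    assert np.all(K == 0.0)


def test_detailed_balance_reaches_saha_ratio():
    """Two-configuration toy in a fixed Maxwellian bath: the stationary
    population ratio implied by EII vs TBR rates equals the closed-form
    Saha ratio (same statistical-weight convention) to <1%."""
    B_i, U, N = 20.0, 15.0, 1.0
    g_lo, g_up = 2.0, 1.0
    kT, n_e = 10.0, 1.0e21
    C = 2.0 / np.sqrt(np.pi) * kT**-1.5

    def f(e):
        return n_e * C * np.sqrt(e) * np.exp(-e / kT)

    e = np.linspace(B_i * (1 + 1e-9), B_i + 40 * kT, 20000)
    r_ion = np.trapezoid(
        f(e) * electron_speed_cm_fs(e) * beb_cross_section(e, B_i, U, N), e)
    x = np.linspace(1e-6, 40 * kT, 900)
    E1, E2 = np.meshgrid(x, x, indexing="ij")
    Kk = tbr_kernel(E1, E2, B_i, U, N, g_lo, g_up)
    r_rec = np.trapezoid(np.trapezoid(f(E1) * f(E2) * Kk, x, axis=1), x)

    hbar2_2pi_over_m = 4.787859e-15  # eV cm^2
    saha = (2 * g_up / g_lo) * (kT / hbar2_2pi_over_m)**1.5 \
        * np.exp(-B_i / kT) / n_e
    assert r_ion / r_rec == pytest.approx(saha, rel=0.01)
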