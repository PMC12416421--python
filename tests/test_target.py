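"""Target compositions, solvent mixing, and pulse profiles."""

import numpy as np
import pytest

from femtoplasma.constants import AMU_G
from femtoplasma.target import (PulseProfile, TargetComposition, mix_solvent,
                                parse_target_spec)


LYSOZYME_WATER = """
# lysozyme in water, unit-cell contents
H 13942
C 5056
N 1576
O 4386
S 80
density 1.2
"""


def test_parse_lysozyme_in_water():
    tc = parse_target_spec(LYSOZYME_WATER)
    assert tc.counts == {"H": 13942, "C": 5056, "N": 1576, "O": 4386,
                         "S": 80}
    nd = tc.number_densities()
    assert nd["C"] == pytest.approx(5056 / tc.volume_cm3)
    # biomolecular density ~1.2 g/cm^3 puts the cell near 2.3e-19 cm^3
    assert tc.volume_cm3 == pytest.approx(2.34e-19, rel=0.02)


def test_parse_errors():
    with pytest.raises(ValueError):
        parse_target_spec("density 1.2\n")          # empty composition
    with pytest.raises(ValueError):
        parse_target_spec("C 10\n")                 # neither volume/density
    with pytest.raises(ValueError):
        parse_target_spec("C 10\ndensity 1\nvolume 100\n")  # both
    with pytest.raises(ValueError):
        parse_target_spec("Xx 10\ndensity 1\n")     # unknown element


def test_doped_target_densities():
    tc = parse_target_spec(
        "C 613\nN 193\nO 185\nZn2+ 10\ndensity 1.2\n")
    assert tc.charges == {"Zn": 2}
    nd = tc.number_densities()
    mass = (613 * 12.011 + 193 * 14.007 + 185 * 15.999 + 10 * 65.38) * AMU_G
    vol = mass / 1.2
    assert nd["Zn"] == pytest.approx(10 / vol, rel=1e-12)


def test_serialize_roundtrip():
    tc = parse_target_spec("C 613\nN 193\nO 185\nFe2+ 10\ndensity 1.2\n")
    tc2 = parse_target_spec(tc.serialize())
    assert tc2.counts == tc.counts
    assert tc2.charges == tc.charges
    assert tc2.number_densities() == tc.number_densities()


def test_mixing_endpoints_and_linearity():
    a = TargetComposition(counts={"C": 100, "O": 10}, density_g_cm3=1.3)
    b = TargetComposition(counts={"H": 200, "O": 100}, density_g_cm3=1.0)
    na, nb = a.number_densities(), b.number_densities()
    m0 = mix_solvent(a, b, 0.0).number_densities()
    m1 = mix_solvent(a, b, 1.0).number_densities()
    assert m0["C"] == pytest.approx(na["C"]) and "H" not in m0
    assert m1["H"] == pytest.approx(nb["H"]) and "C" not in m1
    x = 0.351
    mx = mix_solvent(a, b, x).number_densities()
    for s in mx:
        assert mx[s] == pytest.approx((1 - x) * na.get(s, 0.0)
                                      + x * nb.get(s, 0.0), rel=1e-12)
    with pytest.raises(ValueError):
        mix_solvent(a, b, 1.2)


def test_pulse_profiles_normalized():
    g = PulseProfile(photon_kev=7.112, fluence_per_um2=1.75e12,
                     shape="gaussian", fwhm_fs=15.0)
    t = np.linspace(-120, 120, 200001)
    assert np.trapezoid(g.flux(t), t) == pytest.approx(1.75e12, rel=1e-8)
    assert np.all(g.profile(t) >= 0)
    s = PulseProfile(photon_kev=7.112, fluence_per_um2=1.75e12,
                     shape="square", fwhm_fs=15.0)
    t2 = np.linspace(-7.5, 7.5, 20001)   # aligned with the window edges
    assert np.trapezoid(s.flux(t2), t2) == pytest.approx(1.75e12, rel=1e-8)
    assert s.flux(8.0) == 0.0


def test_gaussian_half_maximum_at_half_fwhm():
    p = PulseProfile(photon_kev=9.0, fluence_per_um2=1e12, fwhm_fs=15.0)
    assert p.profile(7.5) == pytest.approx(0.5 * p.profile(0.0), rel=1e-12)


def test_square_peak_flux_exceeds_gaussian():
    """Square/Gaussian peak flux = sigma sqrt(2 pi)/FWHM = 1.0645..."""
    g = PulseProfile(photon_kev=9.0, fluence_per_um2=1e12,
                     shape="gaussian", fwhm_fs=15.0)
    s = PulseProfile(photon_kev=9.0, fluence_per_um2=1e12,
                     shape="square", fwhm_fs=15.0)
    ratio = s.flux(0.0) / g.flux(0.0)
    expect = np.sqrt(2.0 * np.pi) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    assert ratio == pytest.approx(expect, rel=1e-12)
    assert ratio == pytest.approx(1.0645, abs=2e-4)
    assert s.flux(0.0) > g.flux(0.0)


def test_pulse_validation():
    with pytest.raises(ValueError):
        PulseProfile(photon_kev=9.0, fluence_per_um2=1e12, shape="sinc")
    with pytest.raises(ValueError):
        PulseProfile(photon_kev=-1.0, fluence_per_um2=1e12)
    with pytest.raises(ValueError):
        PulseProfile(photon_kev=9.0, fluence_per_um2=1e12, fwhm_fs=0.0)
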