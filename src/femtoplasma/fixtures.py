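"""Registry of reference targets and run configurations.

The compositions are the printed unit-cell contents of the
gadolinium-derivative lysozyme study system and its toy variants
(lysozyme.Gd in 0.1 M Gd / 10% NaCl solvent, lysozyme.Gd in 0.1 M Gd,
lysozyme in water, a light-atom control), plus the generic doped
C/N/O + X targets used for damage-landscape scans.
"""

from __future__ import annotations

from pathlib import Path

from .target import TargetComposition, parse_target_spec

# atom counts per unit cell (including disordered solvent)
_FIXTURES: dict[str, dict] = {
    "lysozyme_gd_full": {
        "counts": {"H": 13259, "C": 5153, "N": 1596, "O": 4009, "S": 80,
                   "Gd": 21, "Na": 93, "Cl": 87},
        "density": 1.2,
    },
    "lysozyme_gd_gd_solvent": {
        "counts": {"H": 13846, "C": 5143, "N": 1596, "O": 4300, "S": 80,
                   "Gd": 21},
        "density": 1.2,
    },
    "lysozyme_water": {
        "counts": {"H": 13942, "C": 5056, "N": 1576, "O": 4386, "S": 80},
        "density": 1.2,
    },
    "light_atom_control": {
        "counts": {"H": 13942, "C": 5056, "N": 1656, "O": 4386},
        "density": 1.2,
    },
    "cno": {
        "counts": {"C": 613, "N": 203, "O": 185},
        "density": 1.2,
    },
    "doped_cno": {   # dopant X swapped in via make_doped_target
        "counts": {"C": 613, "N": 193, "O": 185},
        "density": 1.2,
    },
    "toy_one_shell": {
        "counts": {"H": 1000},
        "density": 0.2,
    },
}

_CONFIG_TEMPLATE = """\
pulse:
  energy_keV: {energy}
  fluence_per_um2: {fluence}
  shape: {shape}
  fwhm_fs: {fwhm}
window:
  start_fs: {t0}
  end_fs: {t1}
toggles: {{}}
"""

_DEFAULT_PULSES = {
    "lysozyme_gd_full": dict(energy=7.112, fluence=1.75e12,
                             shape="gaussian", fwhm=15.0, t0=-18, t1=18),
    "lysozyme_gd_gd_solvent": dict(energy=7.112, fluence=1.75e12,
                                   shape="gaussian", fwhm=15.0, t0=-18,
                                   t1=18),
    "lysozyme_water": dict(energy=7.112, fluence=1.75e12,
                           shape="gaussian", fwhm=15.0, t0=-18, t1=18),
    "light_atom_control": dict(energy=7.112, fluence=1.75e12,
                               shape="gaussian", fwhm=15.0, t0=-18, t1=18),
    "cno": dict(energy=9.0, fluence=1e12, shape="gaussian", fwhm=15.0,
                t0=-18, t1=18),
    "doped_cno": dict(energy=9.0, fluence=1e12, shape="gaussian", fwhm=15.0,
                      t0=-18, t1=18),
    "toy_one_shell": dict(energy=1.0, fluence=1e11, shape="square",
                          fwhm=10.0, t0=-6, t1=6),
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def get_fixture(name: str) -> TargetComposition:
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {fixture_names()}")
    fx = _FIXTURES[name]
    return TargetComposition(counts=dict(fx["counts"]),
                             density_g_cm3=fx["density"],
                             charges=dict(fx.get("charges", {})))


def make_doped_target(dopant: str, charge: int = 0,
                      dopant_count: int = 10) -> TargetComposition:
    """C613 N193 O185 X10 at ~1.2 g/cm^3 with dopant X."""
    fx = _FIXTURES["doped_cno"]
    counts = dict(fx["counts"])
    counts[dopant] = counts.get(dopant, 0) + dopant_count
    charges = {dopant: charge} if charge else {}
    return TargetComposition(counts=counts, density_g_cm3=fx["density"],
                             charges=charges)


def make_fixture(name: str, out_dir) -> tuple[Path, Path]:
    """Write <name>.target and <name>.yaml into out_dir; returns paths.

    Round-trips through the plain-text parser so the written files are
    guaranteed to load.
    """
    tc = get_fixture(name)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tpath = out / f"{name}.target"
    tpath.write_text(tc.serialize())
    parse_target_spec(tpath.read_text())  # self-check
    cpath = out / f"{name}.yaml"
    cpath.write_text(_CONFIG_TEMPLATE.format(**_DEFAULT_PULSES[name]))
    return tpath, cpath
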