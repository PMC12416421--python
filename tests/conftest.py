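"""Shared fixtures.

Expensive objects (element models with their self-consistent-field
caches, reference trajectories) are session-scoped so the atomic data is
solved once per test session.
"""

from __future__ import annotations

import pytest

from femtoplasma.operators import Kinetics
from femtoplasma.solver import (SolverPolicy, get_element_model,
                                run_simulation)
from femtoplasma.splines import GridSpec, build_basis
from femtoplasma.target import PulseProfile, TargetComposition


@pytest.fixture(scope="session")
def carbon_model():
    return get_element_model(6)


@pytest.fixture(scope="session")
def sulfur_model():
    return get_element_model(16)


@pytest.fixture(scope="session")
def thermal_basis():
    """Basis resolving a ~10 eV thermal bulk plus a 500 eV peak."""
    return build_basis(GridSpec(emax=2000.0, peaks=(500.0,),
                                thermal_max=300.0, n_log=56))


@pytest.fixture(scope="session")
def thermal_kinetics(thermal_basis):
    return Kinetics(thermal_basis)


from helpers import maxwellian  # noqa: F401  (re-exported fixture helper)


@pytest.fixture(scope="session")
def cno_target():
    return TargetComposition(counts={"C": 613, "N": 203, "O": 185},
                             density_g_cm3=1.2)


@pytest.fixture(scope="session")
def cno_trajectory(cno_target):
    """Reference full-physics CNO run (9 keV, 1e12 ph/um^2, 15 fs)."""
    pulse = PulseProfile(photon_kev=9.0, fluence_per_um2=1e12,
                         shape="gaussian", fwhm_fs=15.0)
    return run_simulation(cno_target, pulse, SolverPolicy(out_dt=1.0),
                          -18.0, 18.0)
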