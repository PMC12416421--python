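"""Independent particle Monte Carlo oracle for impact-ionization cascades.

Tracks individual free electrons in a homogeneous gas of one-subshell
atoms with the same BEB total and differential cross-sections as the
deterministic solver.  Used to validate the time-resolved ionization
count of a monoenergetic cascade; the oracle shares only the
cross-section formulas, not the spline/operator machinery.
"""

from __future__ import annotations

import numpy as np

from femtoplasma.atomic.rates import beb_cross_section, beb_sdcs
from femtoplasma.constants import electron_speed_cm_fs


def sample_secondary(rng, T, B, U, N, ngrid=256):
    """Draw the slower outgoing electron energy from the BEB SDCS."""
    wmax = 0.5 * (T - B)
    w = np.linspace(0.0, wmax, ngrid)
    pdf = beb_sdcs(T, w, B, U, N)
    cdf = np.cumsum(pdf)
    if cdf[-1] <= 0:
        return 0.0
    cdf /= cdf[-1]
    return float(np.interp(rng.random(), cdf, w))


def run_cascade(rng, e0_ev, n_atoms_cm3, B, U, N, t_end_fs, t_grid):
    """One cascade realization; returns cumulative ionizations at t_grid."""
    # event-driven: each electron has rate lambda = n sigma v
    electrons = [(0.0, e0_ev)]   # (birth time, energy)
    events = []
    while electrons:
        t, e = electrons.pop()
        while True:
            sig = float(beb_cross_section(e, B, U, N))
            if sig <= 0.0:
                break
            lam = n_atoms_cm3 * sig * float(electron_speed_cm_fs(e))
            t = t + rng.exponential(1.0 / lam)
            if t >= t_end_fs:
                break
            w = sample_secondary(rng, e, B, U, N)
            events.append(t)
            electrons.append((t, w))
            e = e - B - w
    events = np.sort(np.array(events))
    return np.searchsorted(events, t_grid)


def mc_ionization_curve(seed, e0_ev, n_atoms_cm3, B, U, N, t_end_fs,
                        t_grid, trials=150):
    """Mean cumulative ionizations per initial electron with standard
    errors at the requested times."""
    rng = np.random.default_rng(seed)
    counts = np.array([
        run_cascade(rng, e0_ev, n_atoms_cm3, B, U, N, t_end_fs, t_grid)
        for _ in range(trials)], dtype=float)
    mean = counts.mean(axis=0)
    se = counts.std(axis=0, ddof=1) / np.sqrt(trials)
    return mean, se
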