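"""Observables computed from trajectories.

Charges and orbital occupancies per element, pulse-intensity-weighted
time averages, the electron density ratio (EDR) of a heavy site against
a light-atom reference region, the heavy-atom ionization contrast
between two exposures, and free-electron spectrum snapshots.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .solver import Trajectory
from .target import PulseProfile

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
def average_charge_trace(traj: Trajectory, symbol: str):
    """(times, mean charge) of one element; Z minus expected bound count."""
    if symbol not in traj.element_symbols:
        raise KeyError(f"element {symbol!r} not present in this trajectory")
    return traj.times, traj.charge_trace(symbol)


def occupancy_trace(traj: Trajectory, symbol: str) -> pd.DataFrame:
    """Average occupancy of each modeled shell vs time (tidy frame)."""
    if symbol not in traj.element_symbols:
        raise KeyError(f"element {symbol!r} not present in this trajectory")
    labels = traj.shell_labels[symbol]
    rows = []
    for s in traj.samples:
        occ = s.shell_occ[symbol]
        for lab, o in zip(labels, occ):
            rows.append({"time_fs": s.t, "element": symbol, "shell": lab,
                         "occupancy_e": float(o)})
    return pd.DataFrame(rows)


def intensity_averaged(times: np.ndarray, trace: np.ndarray,
                       pulse: PulseProfile, delay_fs: float = 0.0,
                       coverage: float = 0.99) -> float:
    """int Phi(t - delay) x(t) dt with the profile normalized on the
    trace's support; errors if the trace misses too much of the pulse."""
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if times.size < 2:
        raise ValueError("trace too short")
    phi = pulse.profile(times - delay_fs)
    norm = np.trapezoid(phi, times)
    if norm < coverage:
        raise ValueError(
            f"trace covers only {norm:.3f} of the pulse profile")
    return float(np.trapezoid(phi * trace, times) / norm)


def light_atom_charge_trace(traj: Trajectory,
                            species=("C", "N", "O")) -> np.ndarray:
    """Stoichiometry-weighted mean charge of the protein light atoms."""
    tot = 0.0
    acc = np.zeros(traj.times.size)
    for s in species:
        if s not in traj.element_symbols:
            continue
        w = traj.densities[s]
        acc += w * traj.charge_trace(s)
        tot += w
    if tot == 0:
        raise ValueError("no light-atom species present")
    return acc / tot


# ---------------------------------------------------------------------------
@dataclass
class EDRResult:
    """Electron density ratio of a heavy site vs a light reference."""

    heavy_symbol: str
    reference: dict
    delay_fs: float
    heavy_bound: float          # intensity-averaged bound e- of one heavy atom
    reference_bound: float      # intensity-averaged summed bound e- of region
    ratio: float
    undamaged_ratio: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def bound_trace(traj: Trajectory, symbol: str) -> np.ndarray:
    """Mean bound-electron count per atom of one element vs time."""
    from .constants import SYMBOL_TO_Z
    return SYMBOL_TO_Z[symbol] - traj.charge_trace(symbol)


def compute_edr(traj: Trajectory, heavy_symbol: str, reference: dict,
                probe: PulseProfile, delay_fs: float = 0.0) -> EDRResult:
    """EDR per Eq-style definition: probe-intensity-averaged bound
    electrons of one heavy atom over those of the reference region
    (element -> atom count, e.g. {"C": 20, "N": 10, "O": 10})."""
    from .constants import SYMBOL_TO_Z
    for s in (heavy_symbol, *reference):
        if s not in traj.element_symbols:
            raise KeyError(f"element {s!r} not simulated")
    t = traj.times
    heavy = intensity_averaged(t, bound_trace(traj, heavy_symbol), probe,
                               delay_fs)
    ref = 0.0
    ref0 = 0.0
    for s, cnt in reference.items():
        ref += cnt * intensity_averaged(t, bound_trace(traj, s), probe,
                                        delay_fs)
        ref0 += cnt * SYMBOL_TO_Z[s]
    if ref == 0:
        raise ZeroDivisionError("reference region has no bound electrons")
    return EDRResult(
        heavy_symbol=heavy_symbol, reference=dict(reference),
        delay_fs=delay_fs, heavy_bound=heavy, reference_bound=ref,
        ratio=heavy / ref,
        undamaged_ratio=SYMBOL_TO_Z[heavy_symbol] / ref0)


def ionization_contrast(traj_high: Trajectory, traj_low: Trajectory,
                        probe: PulseProfile, heavy_symbol: str,
                        reference: dict, correct_light: bool = False,
                        delay_fs: float = 0.0) -> float:
    """Heavy-atom ionization contrast between two exposures (electrons
    per heavy atom).

    Uncorrected: the true difference of intensity-averaged heavy bound
    counts (equivalently the EDR difference scaled by the undamaged
    reference count).  Corrected: what an EDR-based measurement infers
    when the simulated, time-dependent light-atom occupancies deplete
    the denominator of the ratio.
    """
    if set(traj_high.element_symbols) != set(traj_low.element_symbols):
        raise ValueError("trajectories simulate different targets")
    from .constants import SYMBOL_TO_Z
    ref0 = sum(cnt * SYMBOL_TO_Z[s] for s, cnt in reference.items())
    e_hi = compute_edr(traj_high, heavy_symbol, reference, probe, delay_fs)
    e_lo = compute_edr(traj_low, heavy_symbol, reference, probe, delay_fs)
    if correct_light:
        return (e_lo.ratio - e_hi.ratio) * ref0
    return e_lo.heavy_bound - e_hi.heavy_bound


# ---------------------------------------------------------------------------
def distribution_snapshot(traj: Trajectory, t_fs: float,
                          n_points: int = 400) -> pd.DataFrame:
    """f(eps) and eps f(eps) at time t on a log reporting grid.

    Coefficients are interpolated linearly between stored samples; small
    negative-density undershoots of the spline representation are
    clipped, with a warning if they exceed 1e-6 of the total.
    """
    ts = traj.times
    if not (ts[0] - 1e-9 <= t_fs <= ts[-1] + 1e-9):
        raise ValueError(f"time {t_fs} fs outside trajectory "
                         f"[{ts[0]}, {ts[-1]}]")
    i = int(np.searchsorted(ts, t_fs, side="right")) - 1
    i = min(max(i, 0), len(ts) - 2)
    w = (t_fs - ts[i]) / max(ts[i + 1] - ts[i], 1e-300)
    w = min(max(w, 0.0), 1.0)
    coef = (1 - w) * traj.samples[i].coef + w * traj.samples[i + 1].coef
    basis = traj.basis
    lo, hi = basis.domain
    eps = np.geomspace(max(lo, 1e-2), hi, n_points)
    f = basis.evaluate(coef, eps)
    neg = -np.minimum(f, 0.0)
    n_tot = float(basis.m0 @ coef)
    neg_frac = (np.trapezoid(neg, eps) / n_tot) if n_tot > 0 else 0.0
    if neg_frac > 1e-6:
        log.warning("clipping negative density fraction %.2e at t=%.2f fs",
                    neg_frac, t_fs)
    f = np.maximum(f, 0.0)
    df = pd.DataFrame({"energy_eV": eps, "f_cm3_eV": f,
                       "energy_density_eV_cm3_eV": eps * f})
    df.attrs["total_density_cm3"] = n_tot
    df.attrs["total_energy_eV_cm3"] = float(basis.m1 @ coef)
    df.attrs["time_fs"] = float(t_fs)
    return df


def thermal_bulk_density(traj: Trajectory, t_fs: float,
                         emax_ev: float = 100.0) -> float:
    """Free-electron density below emax_ev at time t (thermal bulk)."""
    snap = distribution_snapshot(traj, t_fs, n_points=600)
    m = snap["energy_eV"] <= emax_ev
    return float(np.trapezoid(snap["f_cm3_eV"][m], snap["energy_eV"][m]))


# ---------------------------------------------------------------------------
def traces_frame(traj: Trajectory) -> pd.DataFrame:
    """Tidy per-element charge traces with ledger columns."""
    rows = []
    for s in traj.samples:
        for sym in traj.element_symbols:
            rows.append({
                "time_fs": s.t, "element": sym,
                "mean_charge_e": s.charges[sym],
                "free_density_cm3": s.free_density,
                "free_energy_eV_cm3": s.free_energy,
                "absorbed_eV_cm3": s.ledgers["absorbed_ev"],
                "radiated_eV_cm3": s.ledgers["radiated_ev"],
            })
    return pd.DataFrame(rows)
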