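"""Damage-landscape scans over pulse parameters for doped targets.

Maps the carbon charge (intensity-averaged and at end of illumination,
+1.2 FWHM) over photon-energy x fluence or photon-energy x pulse-width
grids.  Heavy-atom secondary ionization is disabled for these scans
(primary-only mode), which barely affects light-atom ionization but
sharply reduces the configuration workload; the lowest-photoelectron-
energy (LPE) of the dopant's deepest ionizable shell (DIS) is reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import SYMBOL_TO_Z
from .observables import intensity_averaged
from .solver import SolverPolicy, build_system, get_element_model
from .target import PulseProfile, TargetComposition


@dataclass
class ScanSpec:
    """Scan request: one target, up to two free pulse axes."""

    target: TargetComposition
    photon_kev: tuple[float, ...] = (9.0,)
    fluence_per_um2: tuple[float, ...] = (1e12,)
    fwhm_fs: tuple[float, ...] = (15.0,)
    shape: str = "gaussian"
    dopant: str | None = None
    window_factor: float = 1.2          # run +-factor*FWHM
    policy: SolverPolicy = field(default_factory=lambda: SolverPolicy(
        heavy_mode="primary_only", hydrogen_ionization=False))

    def __post_init__(self):
        axes = [len(self.photon_kev) > 1, len(self.fluence_per_um2) > 1,
                len(self.fwhm_fs) > 1]
        if sum(axes) > 2:
            raise ValueError("at most two free axes per scan")
        for vals in (self.photon_kev, self.fluence_per_um2, self.fwhm_fs):
            if not vals:
                raise ValueError("empty scan grid")
            if any(v <= 0 for v in vals):
                raise ValueError("axis values must be positive")


def dis_threshold(dopant: str, photon_kev: float, charge: int = 0,
                  collapse_threshold: int = 30) -> float | None:
    """Binding energy (eV) of the dopant's deepest shell ionizable at
    this photon energy, or None if nothing is ionizable."""
    model = get_element_model(SYMBOL_TO_Z[dopant], collapse_threshold)
    idx = model.initial_index(charge)
    best = None
    for line in model.photo_lines(idx):
        if line.threshold_ev < photon_kev * 1e3:
            if best is None or line.threshold_ev > best:
                best = line.threshold_ev
    return best


def scan_landscape(spec: ScanSpec) -> pd.DataFrame:
    """One row per grid point; failed points are flagged, not fatal."""
    rows = []
    for om in spec.photon_kev:
        for fl in spec.fluence_per_um2:
            for fw in spec.fwhm_fs:
                pulse = PulseProfile(photon_kev=om, fluence_per_um2=fl,
                                     shape=spec.shape, fwhm_fs=fw)
                row = {"photon_keV": om, "fluence_per_um2": fl,
                       "fwhm_fs": fw, "ok": True, "error": ""}
                if spec.dopant:
                    thr = dis_threshold(
                        spec.dopant, om,
                        spec.target.charges.get(spec.dopant, 0),
                        spec.policy.collapse_threshold)
                    row["lpe_keV"] = (om - thr / 1e3) if thr else np.nan
                try:
                    sys_ = build_system(spec.target, pulse, spec.policy)
                    w = spec.window_factor * fw
                    traj = sys_.run(-w, w)
                    t = traj.times
                    c = traj.charge_trace("C")
                    row["carbon_final_e"] = float(c[-1])
                    row["carbon_intensity_avg_e"] = intensity_averaged(
                        t, c, pulse)
                except Exception as exc:   # noqa: BLE001 - flagged, not fatal
                    row["ok"] = False
                    row["error"] = str(exc)
                    row["carbon_final_e"] = np.nan
                    row["carbon_intensity_avg_e"] = np.nan
                rows.append(row)
    if not rows:
        raise ValueError("empty scan grid")
    return pd.DataFrame(rows)
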