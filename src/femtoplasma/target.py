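"""Target compositions and pulse profiles.

A target is a set of element counts per unit cell plus exactly one of
{unit-cell volume, mass density}, from which per-element number
densities follow.  Dopants may carry an initial ionic charge ("Zn2+").

Pulses are Gaussian or square temporal profiles parameterized by photon
energy (keV), fluence (photons/um^2) and FWHM (fs), with t = 0 at the
Gaussian peak or the square-window centre.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .constants import AMU_G, ATOMIC_MASS_AMU, SYMBOL_TO_Z

_GAUSS_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass
class TargetComposition:
    """Element counts per unit cell plus cell volume or mass density."""

    counts: dict[str, float]                  # symbol -> atoms per cell
    volume_A3: float | None = None
    density_g_cm3: float | None = None
    charges: dict[str, int] = field(default_factory=dict)  # initial ion charge

    def __post_init__(self):
        if not self.counts:
            raise ValueError("empty composition")
        for sym, cnt in self.counts.items():
            if sym not in SYMBOL_TO_Z:
                raise ValueError(f"unknown element symbol {sym!r}")
            if cnt < 0:
                raise ValueError(f"negative count for {sym}")
        if (self.volume_A3 is None) == (self.density_g_cm3 is None):
            raise ValueError(
                "exactly one of unit-cell volume or mass density required")
        if self.volume_A3 is not None and self.volume_A3 <= 0:
            raise ValueError("volume must be positive")
        if self.density_g_cm3 is not None and self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")

    # ------------------------------------------------------------------
    @property
    def mass_amu(self) -> float:
        return sum(ATOMIC_MASS_AMU[SYMBOL_TO_Z[s]] * c
                   for s, c in self.counts.items())

    @property
    def volume_cm3(self) -> float:
        if self.volume_A3 is not None:
            return self.volume_A3 * 1e-24
        return self.mass_amu * AMU_G / self.density_g_cm3

    def number_densities(self) -> dict[str, float]:
        """Atoms per cm^3 for each element."""
        v = self.volume_cm3
        return {s: c / v for s, c in self.counts.items() if c > 0}

    def implied_density(self) -> float:
        return self.mass_amu * AMU_G / self.volume_cm3

    # ------------------------------------------------------------------
    def serialize(self) -> str:
        lines = []
        for s, c in sorted(self.counts.items()):
            q = self.charges.get(s, 0)
            tag = s + (f"{q}+" if q else "")
            cs = f"{c:.10g}"
            lines.append(f"{tag} {cs}")
        if self.volume_A3 is not None:
            lines.append(f"volume {self.volume_A3:.10g}")
        else:
            lines.append(f"density {self.density_g_cm3:.10g}")
        return "\n".join(lines) + "\n"


_ION_RE = re.compile(r"^([A-Z][a-z]?)(?:(\d+)\+)?$")


def parse_target_spec(text: str) -> TargetComposition:
    """Parse a plain-text target description.

    One "Element count" per line (element optionally "Zn2+" for an
    initially charged dopant), plus one "density <g/cm3>" or
    "volume <A^3>" line.  '#' starts a comment.
    """
    counts: dict[str, float] = {}
    charges: dict[str, int] = {}
    volume = density = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed line: {raw!r}")
        key, val = parts
        if key.lower() in ("density", "rho"):
            density = float(val)
            continue
        if key.lower() in ("volume", "vol"):
            volume = float(val)
            continue
        m = _ION_RE.match(key)
        if not m or m.group(1) not in SYMBOL_TO_Z:
            raise ValueError(f"unknown element symbol {key!r}")
        sym = m.group(1)
        counts[sym] = counts.get(sym, 0.0) + float(val)
        if m.group(2):
            charges[sym] = int(m.group(2))
    return TargetComposition(counts=counts, volume_A3=volume,
                             density_g_cm3=density, charges=charges)


def mix_solvent(protein: TargetComposition, solvent: TargetComposition,
                solvent_fraction: float) -> TargetComposition:
    """Volume-weighted (v/v) combination of number densities.

    The result is expressed per cm^3 (volume = 1e24 A^3) so that mixing
    is exactly linear in the densities.
    """
    if not (0.0 <= solvent_fraction <= 1.0):
        raise ValueError("solvent fraction must be within [0, 1]")
    x = solvent_fraction
    na = protein.number_densities()
    nb = solvent.number_densities()
    out: dict[str, float] = {}
    for s in set(na) | set(nb):
        out[s] = (1.0 - x) * na.get(s, 0.0) + x * nb.get(s, 0.0)
    charges = dict(solvent.charges)
    charges.update(protein.charges)
    return TargetComposition(counts=out, volume_A3=1e24, charges=charges)


@dataclass
class PulseProfile:
    """Temporal pulse profile Phi(t) with int Phi dt = 1."""

    photon_kev: float
    fluence_per_um2: float          # photons / um^2
    shape: str = "gaussian"         # "gaussian" | "square"
    fwhm_fs: float = 15.0

    def __post_init__(self):
        if self.shape not in ("gaussian", "square"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")
        if self.fwhm_fs <= 0:
            raise ValueError("FWHM must be positive")
        if self.fluence_per_um2 < 0:
            raise ValueError("fluence must be non-negative")
        if self.photon_kev <= 0:
            raise ValueError("photon energy must be positive")

    @property
    def photon_ev(self) -> float:
        return self.photon_kev * 1e3

    def profile(self, t_fs) -> np.ndarray:
        """Normalized Phi(t) in fs^-1; t = 0 at peak / window centre."""
        t = np.asarray(t_fs, dtype=float)
        if self.shape == "gaussian":
            s = self.fwhm_fs * _GAUSS_SIGMA_PER_FWHM
            out = np.exp(-0.5 * (t / s) ** 2) / (s * np.sqrt(2.0 * np.pi))
        else:
            half = 0.5 * self.fwhm_fs
            out = np.where(np.abs(t) <= half, 1.0 / self.fwhm_fs, 0.0)
        return out if out.shape else float(out)

    def flux(self, t_fs):
        """Photon flux J(t) = F Phi(t) in photons um^-2 fs^-1."""
        return self.fluence_per_um2 * self.profile(t_fs)

    def flux_cm2(self, t_fs):
        """J(t) in photons cm^-2 fs^-1."""
        return 1e8 * self.flux(t_fs)

    def default_window(self, factor: float = 1.2) -> tuple[float, float]:
        """-factor*FWHM .. +factor*FWHM around the peak."""
        return (-factor * self.fwhm_fs, factor * self.fwhm_fs)
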