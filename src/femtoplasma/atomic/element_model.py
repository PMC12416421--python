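"""Per-element atomic data: configurations, mean-field data, transitions.

All quantities are computed lazily per configuration and cached, because
for collapsed heavy elements (Gd: 4 x 10^5 configurations) only a small
ionization-reachable subset is ever populated in a femtosecond run.

Process thresholds are total-energy differences between configurations
(Delta-SCF), which keeps the energy ledger of the kinetic equations
exactly consistent: every bound-free transition moves B = E(final) -
E(initial) between the bound and free energy pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import ELEMENT_SYMBOLS
from .configurations import ConfigurationSet, enumerate_configurations, \
    statistical_weight
from .rates import (beb_cross_section, fluorescence_yield, hole_width_ev,
                    photo_cross_section, width_to_rate_fs)
from .scf import solve_mean_field


@dataclass
class ConfigData:
    """Mean-field summary of one configuration at shell-level resolution."""

    index: int
    occ: tuple[int, ...]
    total_energy_ev: float
    shell_binding_ev: np.ndarray   # occupancy-weighted Koopmans binding / shell
    shell_kinetic_ev: np.ndarray   # mean orbital kinetic energy U / shell
    stat_weight: float


@dataclass(frozen=True)
class PhotoLine:
    shell: int
    dst: int
    threshold_ev: float
    n_qn: int
    occupancy: float
    kinetic_ev: float = 0.0  # orbital <T>; hydrogenic energy scale of sigma


@dataclass(frozen=True)
class DecayLine:
    kind: str        # "auger" | "fluor"
    dst: int
    rate_fs: float
    energy_ev: float  # ejected-electron (auger) or photon (fluor) energy


@dataclass(frozen=True)
class EIIChannel:
    shell: int
    dst: int          # configuration after ionization
    B_ev: float       # Delta-SCF threshold
    U_ev: float
    N: float          # occupancy of the ionized shell (source config)
    g_src: float
    g_dst: float


class ElementModel:
    """Atomic model of one element under a collapse policy."""

    def __init__(self, Z: int, collapse_threshold: int = 30,
                 scf_npts: int | None = None):
        self.Z = Z
        self.symbol = ELEMENT_SYMBOLS[Z]
        self.collapse_threshold = collapse_threshold
        self.configs: ConfigurationSet = enumerate_configurations(
            Z, collapse_threshold=collapse_threshold)
        self.shells = self.configs.shells
        self.collapsed = any(s.collapsed for s in self.shells)
        # large configuration sets are served from the quadratic
        # occupation-energy surface instead of one SCF per configuration
        self.use_surface = self.collapsed or len(self.configs) > 200
        self.scf_npts = scf_npts or (480 if Z < 30 else 440)
        self._data: dict[int, ConfigData] = {}
        self._decay: dict[int, list[DecayLine]] = {}
        self._photo: dict[int, list[PhotoLine]] = {}
        self._eii: dict[int, list[EIIChannel]] = {}
        self._vcache: dict[int, "object"] = {}  # n_elec -> converged V(r)

    # -- occupancy helpers -------------------------------------------------
    @property
    def ground_index(self) -> int:
        return self.configs.ground_index

    def initial_index(self, charge: int = 0) -> int:
        """Configuration index of the +charge ion (outermost-first removal)."""
        occ = list(self.configs.ground_occ)
        for _ in range(charge):
            pos = max(i for i, o in enumerate(occ) if o > 0)
            occ[pos] -= 1
        return self.configs.index_of(occ)

    def _nl_occupancies(self, occ) -> list[tuple[int, int, float]]:
        """Shell-level occupancies -> (n, l, occ) with collapsed shells
        filled proportionally to ground member occupancies."""
        out = []
        for spec, o in zip(self.shells, occ):
            if o <= 0:
                continue
            if not spec.collapsed:
                out.append((spec.n, spec.l, float(o)))
            else:
                tot = sum(go for _, _, go in spec.sub_nl)
                for n, l, go in spec.sub_nl:
                    frac = o * go / tot
                    if frac > 0:
                        out.append((n, l, frac))
        return out

    # -- mean field --------------------------------------------------------
    def _surface(self):
        """Quadratic shell-occupation energy surface (used for large
        configuration sets); built lazily from anchored SCF solutions."""
        surf = getattr(self, "_surf", None)
        if surf is None:
            from .surface import ShellEnergySurface

            def solve(occ):
                cd = self._config_data_scf(occ)
                return (cd.total_energy_ev, cd.shell_binding_ev,
                        cd.shell_kinetic_ev)

            step = max(2, self.Z // 7)
            charges = tuple(range(0, self.Z - 1, step))
            surf = ShellEnergySurface(solve, self.configs.ground_occ,
                                      anchor_charges=charges)
            self._surf = surf
        return surf

    def config_data(self, idx: int) -> ConfigData:
        cd = self._data.get(idx)
        if cd is not None:
            return cd
        occ = self.configs.occ_of(idx)
        if self.use_surface:
            surf = self._surface()
            B, U = surf.shell_data(occ)
            cd = ConfigData(idx, occ, surf.energy(occ), B, U,
                            statistical_weight(self.shells, occ))
            self._data[idx] = cd
            return cd
        cd = self._config_data_scf(occ, idx)
        self._data[idx] = cd
        return cd

    def _config_data_scf(self, occ, idx: int = -1) -> ConfigData:
        nl = self._nl_occupancies(occ)
        ne = sum(occ)
        v0 = None
        for key in (ne, ne + 1, ne - 1):
            if key in self._vcache:
                v0 = self._vcache[key]
                break
        mf = solve_mean_field(self.Z, nl, npts=self.scf_npts, v_init=v0)
        if mf.potential is not None:
            self._vcache[ne] = mf.potential
        nsh = len(self.shells)
        B = np.zeros(nsh)
        U = np.zeros(nsh)
        # collapse back to shell level: occupancy-weighted means
        pos_of = {}
        for i, spec in enumerate(self.shells):
            for n, l, _ in spec.sub_nl:
                pos_of[(n, l)] = i
        wsum = np.zeros(nsh)
        for (n, l, o), b, u in zip(mf.occ_nl, mf.binding_ev, mf.kinetic_ev):
            i = pos_of[(n, l)]
            B[i] += o * b
            U[i] += o * u
            wsum[i] += o
        nz = wsum > 0
        B[nz] /= wsum[nz]
        U[nz] /= wsum[nz]
        return ConfigData(idx, tuple(occ), mf.total_energy_ev, B, U,
                          statistical_weight(self.shells, occ))

    def ionization_threshold(self, idx: int, shell: int) -> float:
        """Delta-SCF energy to remove one electron from `shell`."""
        cd = self.config_data(idx)
        occ = list(cd.occ)
        if occ[shell] <= 0:
            raise ValueError("shell is empty")
        occ[shell] -= 1
        dst = self.configs.index_of(occ)
        return self.config_data(dst).total_energy_ev - cd.total_energy_ev

    # -- transitions -------------------------------------------------------
    def photo_lines(self, idx: int) -> list[PhotoLine]:
        cached = self._photo.get(idx)
        if cached is not None:
            return cached
        cd = self.config_data(idx)
        lines = []
        for s, spec in enumerate(self.shells):
            if cd.occ[s] <= 0:
                continue
            occ = list(cd.occ)
            occ[s] -= 1
            dst = self.configs.index_of(occ)
            thr = self.config_data(dst).total_energy_ev - cd.total_energy_ev
            if thr <= 0:
                continue
            lines.append(PhotoLine(shell=s, dst=dst, threshold_ev=thr,
                                   n_qn=spec.n, occupancy=float(cd.occ[s]),
                                   kinetic_ev=float(cd.shell_kinetic_ev[s])))
        self._photo[idx] = lines
        return lines

    def photo_sigma(self, line: PhotoLine, photon_ev: float) -> float:
        return float(photo_cross_section(
            photon_ev, line.threshold_ev, line.n_qn, line.occupancy,
            scale_ev=max(line.kinetic_ev, line.threshold_ev)))

    def decay_lines(self, idx: int) -> list[DecayLine]:
        cached = self._decay.get(idx)
        if cached is not None:
            return cached
        cd = self.config_data(idx)
        occ = cd.occ
        caps = self.configs.ground_occ
        out: list[DecayLine] = []
        for h, spec in enumerate(self.shells):
            n_holes = caps[h] - occ[h]
            if n_holes <= 0:
                continue
            # any occupied shell above h can participate
            above = [j for j in range(h + 1, len(self.shells)) if occ[j] > 0]
            if not above:
                continue
            width = hole_width_ev(self.Z, spec.n)
            if width <= 0:
                continue
            omega = fluorescence_yield(self.Z, spec.n)
            rate_tot = width_to_rate_fs(width) * n_holes
            # --- Auger: j fills the hole, k is ejected
            pairs = []
            for j in above:
                for k in above:
                    if k < j:
                        continue
                    w = occ[j] * (occ[k] - (1 if k == j else 0))
                    if w <= 0:
                        continue
                    pairs.append((j, k, float(w)))
            pairs_neutral = 0.0
            for j in above:
                for k in above:
                    if k < j:
                        continue
                    w = caps[j] * (caps[k] - (1 if k == j else 0))
                    pairs_neutral += w
            if pairs and pairs_neutral > 0:
                scale = sum(w for _, _, w in pairs) / pairs_neutral
                total_auger = rate_tot * (1.0 - omega) * scale
                wsum = sum(w for _, _, w in pairs)
                for j, k, w in pairs:
                    new = list(occ)
                    new[h] += 1
                    new[j] -= 1
                    new[k] -= 1
                    dst = self.configs.index_of(new)
                    de = cd.total_energy_ev - self.config_data(dst).total_energy_ev
                    if de <= 0:
                        continue  # energetically closed; suppressed
                    out.append(DecayLine("auger", dst,
                                         total_auger * w / wsum, de))
            # --- fluorescence: j fills the hole radiatively
            n_avail = sum(occ[j] for j in above)
            n_neutral = sum(caps[j] for j in above)
            if omega > 0 and n_avail > 0:
                total_fluor = rate_tot * omega * (n_avail / n_neutral)
                for j in above:
                    if occ[j] <= 0:
                        continue
                    new = list(occ)
                    new[h] += 1
                    new[j] -= 1
                    dst = self.configs.index_of(new)
                    de = cd.total_energy_ev - self.config_data(dst).total_energy_ev
                    if de <= 0:
                        continue
                    out.append(DecayLine("fluor", dst,
                                         total_fluor * occ[j] / n_avail, de))
        self._decay[idx] = out
        return out

    def eii_channels(self, idx: int) -> list[EIIChannel]:
        cached = self._eii.get(idx)
        if cached is not None:
            return cached
        cd = self.config_data(idx)
        chans = []
        for s in range(len(self.shells)):
            if cd.occ[s] <= 0:
                continue
            occ = list(cd.occ)
            occ[s] -= 1
            dst = self.configs.index_of(occ)
            dcd = self.config_data(dst)
            B = dcd.total_energy_ev - cd.total_energy_ev
            if B <= 0:
                continue
            U = max(cd.shell_kinetic_ev[s], 1e-3)
            chans.append(EIIChannel(shell=s, dst=dst, B_ev=B, U_ev=U,
                                    N=float(cd.occ[s]), g_src=cd.stat_weight,
                                    g_dst=dcd.stat_weight))
        self._eii[idx] = chans
        return chans

    def eii_sigma(self, ch: EIIChannel, T_ev) -> np.ndarray:
        return beb_cross_section(T_ev, ch.B_ev, ch.U_ev, ch.N)

    def tbr_channels(self, idx: int) -> list[EIIChannel]:
        """Recombination channels of config idx: the inverses of the EII
        channels of each one-more-electron neighbor.  The returned
        EIIChannel describes the *forward* (ionizing) channel whose dst
        is idx; TBR runs it backwards."""
        cd = self.config_data(idx)
        caps = self.configs.ground_occ
        out = []
        for s in range(len(self.shells)):
            if cd.occ[s] >= caps[s]:
                continue
            occ = list(cd.occ)
            occ[s] += 1
            lower = self.configs.index_of(occ)
            lcd = self.config_data(lower)
            B = cd.total_energy_ev - lcd.total_energy_ev
            if B <= 0:
                continue
            U = max(lcd.shell_kinetic_ev[s], 1e-3)
            out.append(EIIChannel(shell=s, dst=idx, B_ev=B, U_ev=U,
                                  N=float(lcd.occ[s]), g_src=lcd.stat_weight,
                                  g_dst=cd.stat_weight))
        return out

    # -- convenience -------------------------------------------------------
    def deepest_ionizable_shell(self, photon_ev: float,
                                idx: int | None = None) -> int | None:
        """Index of the deepest shell whose ionization threshold lies
        below the photon energy (the DIS), or None."""
        idx = self.ground_index if idx is None else idx
        for line in self.photo_lines(idx):
            if line.threshold_ev < photon_ev:
                return line.shell
        return None

    def mean_bound_electrons(self, populations: np.ndarray | dict) -> float:
        if isinstance(populations, dict):
            return sum(p * sum(self.configs.occ_of(i))
                       for i, p in populations.items())
        raise TypeError("expected {index: population} mapping")
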