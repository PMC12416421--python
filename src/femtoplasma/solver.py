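"""Coupled solver for the configuration populations P_xi(t) and the
free-electron distribution f(eps, t).

dP/dt = Gamma(f, t) P          (photo, Auger, fluorescence, EII, TBR)
df/dt = Q[P, f]                (sources, EII, TBR, EE)

Time stepping: adaptive embedded Runge-Kutta (Bogacki-Shampine 2(3)) for
all processes except electron-electron collisions, which are advanced by
linearly implicit Crank-Nicolson half-steps on either side (Strang
splitting) because the thermalized bulk makes them stiff.  Every
right-hand-side evaluation balances its bound/free bookkeeping exactly,
so total electron number and total energy (absorbed = Delta bound +
free kinetic + radiated) are conserved to round-off by construction.

Configurations are activated lazily: transition tables are built when a
configuration's population first exceeds a threshold, and the heavier
spline-space EII/TBR operators only for configurations that carry
non-negligible population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .atomic.element_model import ElementModel
from .operators import Kinetics
from .splines import FreeElectronDistribution, GridSpec, SplineBasis, \
    build_basis
from .target import PulseProfile, TargetComposition
from .constants import SYMBOL_TO_Z

log = logging.getLogger(__name__)

_LEDGER_NAMES = ("absorbed_ev", "radiated_ev", "photo_events",
                 "auger_events", "eii_events", "tbr_events")


@dataclass
class SolverPolicy:
    """Step control, thresholds and process toggles."""

    rtol: float = 3e-4
    atol_pop: float = 1e-9
    dt_init: float = 5e-3
    dt_max: float = 0.25
    dt_min: float = 1e-7
    out_dt: float = 0.5

    activate_threshold: float = 1e-10   # population to build transitions
    op_threshold: float = 1e-5          # population to build EII spline ops
    heavy_op_threshold: float = 1e-4    # same, for heavy (Z >= heavy_z_min)
    tbr_threshold: float = 1e-4         # population to build TBR ops
    tbr_bmax_ev: float = 500.0          # no TBR into deeper holes

    photo: bool = True
    auger: bool = True
    fluor: bool = True
    eii: bool = True
    tbr: bool = True
    ee: bool = True

    heavy_z_min: int = 11               # Z >= this counts as a heavy atom
    heavy_mode: str = "all"             # all | primary_only | none
    hydrogen_ionization: bool = True

    # grid construction
    extra_peaks: tuple = ()             # extra energies to resolve (eV)
    n_log: int = 64
    thermal_max_ev: float = 400.0
    tbr_nodes: int = 18
    tbr_max_ev: float = 400.0
    collapse_threshold: int = 30

    def element_mode(self, Z: int) -> str:
        if Z == 1 and not self.hydrogen_ionization:
            return "none"
        if Z >= self.heavy_z_min:
            return self.heavy_mode
        return "all"


# cache of ElementModel instances shared across systems in one process
_MODEL_CACHE: dict[tuple, ElementModel] = {}


def get_element_model(Z: int, collapse_threshold: int = 30) -> ElementModel:
    key = (Z, collapse_threshold)
    if key not in _MODEL_CACHE:
        _MODEL_CACHE[key] = ElementModel(
            Z, collapse_threshold=collapse_threshold)
    return _MODEL_CACHE[key]


class ElementRuntime:
    """Per-element lazy state: active configurations and transitions."""

    def __init__(self, model: ElementModel, symbol: str, n_cm3: float,
                 init_charge: int, mode: str, kin: Kinetics,
                 policy: SolverPolicy, photon_ev: float):
        self.model = model
        self.symbol = symbol
        self.n = n_cm3
        self.mode = mode
        self.kin = kin
        self.policy = policy
        self.omega = photon_ev

        self.idx: list[int] = []          # config index per position
        self.pos: dict[int, int] = {}     # config index -> position
        self.P = np.zeros(0)
        self.active: set[int] = set()     # positions with transitions built
        self.op_active: set[int] = set()  # positions with EII spline ops
        self.tbr_active: set[int] = set()

        # stacked transition arrays (rebuilt on activation)
        self._dirty = True
        self.ph_src = self.ph_dst = np.zeros(0, dtype=int)
        self.ph_sigma = self.ph_eject = np.zeros(0)
        self.ph_deltas = np.zeros((0, kin.basis.K))
        self.dc_src = self.dc_dst = np.zeros(0, dtype=int)
        self.dc_rate = self.dc_energy = np.zeros(0)
        self.dc_is_auger = np.zeros(0, dtype=bool)
        self.dc_deltas = np.zeros((0, kin.basis.K))
        self.eii_src = self.eii_dst = np.zeros(0, dtype=int)
        self.eii_rate_vecs = np.zeros((0, kin.basis.K))
        self.eii_loss = np.zeros((0, kin.eq.size))
        self.eii_gain = np.zeros((0, kin.basis.K))  # stacked (nch*K, K)
        self._eii_list = []   # (src_pos, dst_pos, EIIChannelOps)
        self._tbr_list = []   # (upper_pos, lower_pos, TBRChannelOps)
        self._delta_cache: dict[float, np.ndarray] = {}
        self._row_cache: dict[int, tuple] = {}
        self._defer = 0
        self._built_n = 0

        start = model.initial_index(init_charge)
        self._ensure_position(start)
        self.P[self.pos[start]] = 1.0
        if mode != "none":
            self._activate(self.pos[start])

    # ------------------------------------------------------------------
    def _ensure_position(self, cfg_idx: int) -> int:
        p = self.pos.get(cfg_idx)
        if p is not None:
            return p
        p = len(self.idx)
        self.idx.append(cfg_idx)
        self.pos[cfg_idx] = p
        self.P = np.append(self.P, 0.0)
        return p

    def _activate(self, p: int):
        """Build photo/decay transitions out of configuration at pos p."""
        if p in self.active or self.mode == "none":
            return
        self.active.add(p)
        self._dirty = True

    def _build_ops(self, p: int):
        if p in self.op_active or self.mode in ("none", "primary_only"):
            return
        cfg = self.idx[p]
        for ch in self.model.eii_channels(cfg):
            ops = self.kin.eii_ops(ch.B_ev, ch.U_ev, ch.N)
            dp = self._ensure_position(ch.dst)
            self._eii_list.append((p, dp, ops))
        self.op_active.add(p)
        self._dirty = True

    def _build_tbr(self, p: int):
        if p in self.tbr_active or self.mode in ("none", "primary_only"):
            return
        cfg = self.idx[p]
        for ch in self.model.tbr_channels(cfg):
            if ch.B_ev > self.policy.tbr_bmax_ev:
                continue
            ops = self.kin.tbr_ops(ch.B_ev, ch.U_ev, ch.N,
                                   ch.g_src, ch.g_dst)
            # lower config: one more electron in ch.shell
            occ = list(self.model.configs.occ_of(cfg))
            occ[ch.shell] += 1
            lp = self._ensure_position(self.model.configs.index_of(occ))
            self._tbr_list.append((p, lp, ops))
        self.tbr_active.add(p)
        self._dirty = True

    def refresh_activations(self):
        """Grow the active sets from the current populations."""
        pol = self.policy
        if self.mode == "none":
            return
        for p in np.nonzero(self.P > pol.activate_threshold)[0]:
            if p not in self.active:
                self._activate(int(p))
        if pol.eii and self.mode == "all":
            thr = (pol.heavy_op_threshold
                   if self.model.Z >= pol.heavy_z_min else pol.op_threshold)
            for p in np.nonzero(self.P > thr)[0]:
                if p not in self.op_active:
                    self._build_ops(int(p))
        if pol.tbr and self.mode == "all":
            for p in np.nonzero(self.P > pol.tbr_threshold)[0]:
                if p not in self.tbr_active:
                    self._build_tbr(int(p))
        if self._dirty:
            # amortize: freshly activated configurations carry ~1e-10
            # population, so folding them into the stacked arrays can
            # lag a few steps without observable effect
            self._defer += 1
            if self._defer >= 6 or len(self.active) - self._built_n >= 30 \
                    or self._built_n == 0:
                self._rebuild()

    # ------------------------------------------------------------------
    def _delta(self, e: float) -> np.ndarray:
        d = self._delta_cache.get(e)
        if d is None:
            d = self.kin.basis.project_delta(e, 1.0)
            self._delta_cache[e] = d
        return d

    def _config_rows(self, p: int):
        """Transition rows out of configuration at position p, computed
        once at activation time (cross-sections included)."""
        rows = self._row_cache.get(p)
        if rows is not None:
            return rows
        kin, model = self.kin, self.model
        pol = self.policy
        zero = np.zeros(kin.basis.K)
        hi = kin.basis.domain[1]
        cfg = self.idx[p]
        ph = []
        if pol.photo:
            for line in model.photo_lines(cfg):
                sig = model.photo_sigma(line, self.omega)
                if sig <= 0:
                    continue
                ej = self.omega - line.threshold_ev
                dp = self._ensure_position(line.dst)
                ph.append((dp, sig, ej, self._delta(min(ej, hi))))
        dc = []
        if pol.auger or pol.fluor:
            for dl in model.decay_lines(cfg):
                if dl.kind == "auger" and not pol.auger:
                    continue
                if dl.kind == "fluor" and not pol.fluor:
                    continue
                dp = self._ensure_position(dl.dst)
                is_a = dl.kind == "auger"
                dc.append((dp, dl.rate_fs, dl.energy_ev, is_a,
                           self._delta(min(dl.energy_ev, hi))
                           if is_a else zero))
        rows = (ph, dc)
        self._row_cache[p] = rows
        return rows

    def _rebuild(self):
        kin = self.kin
        ph_src, ph_dst, ph_sig, ph_ej, ph_d = [], [], [], [], []
        dc_src, dc_dst, dc_r, dc_e, dc_a, dc_d = [], [], [], [], [], []
        for p in sorted(self.active):
            ph, dc = self._config_rows(p)
            for dp, sig, ej, d in ph:
                ph_src.append(p)
                ph_dst.append(dp)
                ph_sig.append(sig)
                ph_ej.append(ej)
                ph_d.append(d)
            for dp, rate, en, is_a, d in dc:
                dc_src.append(p)
                dc_dst.append(dp)
                dc_r.append(rate)
                dc_e.append(en)
                dc_a.append(is_a)
                dc_d.append(d)
        K = kin.basis.K
        self.ph_src = np.array(ph_src, dtype=int)
        self.ph_dst = np.array(ph_dst, dtype=int)
        self.ph_sigma = np.array(ph_sig)
        self.ph_eject = np.array(ph_ej)
        self.ph_deltas = (np.vstack(ph_d) if ph_d
                          else np.zeros((0, K)))
        self.dc_src = np.array(dc_src, dtype=int)
        self.dc_dst = np.array(dc_dst, dtype=int)
        self.dc_rate = np.array(dc_r)
        self.dc_energy = np.array(dc_e)
        self.dc_is_auger = np.array(dc_a, dtype=bool)
        self.dc_deltas = (np.vstack(dc_d) if dc_d else np.zeros((0, K)))
        self._defer = 0
        self._built_n = len(self.active)
        nch = len(self._eii_list)
        self.eii_src = np.array([s for s, _, _ in self._eii_list], dtype=int)
        self.eii_dst = np.array([d for _, d, _ in self._eii_list], dtype=int)
        if nch:
            self.eii_rate_vecs = np.vstack(
                [o.rate_vec for _, _, o in self._eii_list])
            self.eii_loss = np.vstack(
                [o.loss_q for _, _, o in self._eii_list])
            self.eii_gain = np.vstack(
                [o.gain for _, _, o in self._eii_list])
        else:
            self.eii_rate_vecs = np.zeros((0, K))
            self.eii_loss = np.zeros((0, kin.eq.size))
            self.eii_gain = np.zeros((0, K))
        # TBR channel stacks for batched evaluation
        ntb = len(self._tbr_list)
        nt = kin.tbr_e.size
        self.tbr_src = np.array([s for s, _, _ in self._tbr_list], dtype=int)
        self.tbr_dst = np.array([d for _, d, _ in self._tbr_list], dtype=int)
        if ntb:
            self.tbr_kmats = np.stack([o.kmat for _, _, o in self._tbr_list])
            self.tbr_deltas = np.stack(
                [o.deltas.reshape(K, nt, nt) for _, _, o in self._tbr_list])
        else:
            self.tbr_kmats = np.zeros((0, nt, nt))
            self.tbr_deltas = np.zeros((0, K, nt, nt))
        self._dirty = False

    # ------------------------------------------------------------------
    def mean_bound(self, P=None) -> float:
        P = self.P if P is None else P
        occs = np.array([sum(self.model.configs.occ_of(i)) for i in self.idx])
        return float(occs @ P)

    def mean_shell_occ(self, P=None) -> np.ndarray:
        P = self.P if P is None else P
        occs = np.array([self.model.configs.occ_of(i) for i in self.idx],
                        dtype=float)
        if occs.size == 0:
            return np.zeros(len(self.model.shells))
        return occs.T @ P

    def bound_energy(self, P=None) -> float:
        P = self.P if P is None else P
        es = np.array([self.model.config_data(i).total_energy_ev
                       for i in self.idx])
        return float(es @ P)


# ---------------------------------------------------------------------------


@dataclass
class TrajectorySample:
    t: float
    coef: np.ndarray
    populations: dict[str, dict[int, float]]
    charges: dict[str, float]
    shell_occ: dict[str, np.ndarray]
    ledgers: dict[str, float]
    free_density: float
    free_energy: float
    bound_electrons_cm3: float
    bound_energy_cm3: float
    partition_density: dict[str, float] | None = None
    partition_coefs: dict[str, np.ndarray] | None = None


@dataclass
class Trajectory:
    samples: list[TrajectorySample]
    basis: SplineBasis
    target: TargetComposition
    pulse: PulseProfile
    policy: SolverPolicy
    element_symbols: list[str]
    densities: dict[str, float]
    ground_bound: dict[str, int]
    shell_labels: dict[str, list[str]]

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples])

    def charge_trace(self, symbol: str) -> np.ndarray:
        if symbol not in self.element_symbols:
            raise KeyError(f"element {symbol} not simulated")
        return np.array([s.charges[symbol] for s in self.samples])

    def distribution(self, i: int) -> FreeElectronDistribution:
        return FreeElectronDistribution(self.basis, self.samples[i].coef)


def conservation_report(traj: Trajectory) -> dict:
    """Per-sample drifts of particle number and the energy ledger."""
    s0 = traj.samples[0]
    n0 = s0.bound_electrons_cm3 + s0.free_density
    out = {"time": [], "electron_drift_rel": [], "energy_residual_rel": []}
    for s in traj.samples:
        n = s.bound_electrons_cm3 + s.free_density
        out["time"].append(s.t)
        out["electron_drift_rel"].append((n - n0) / n0)
        d_bound = s.bound_energy_cm3 - s0.bound_energy_cm3
        absorbed = s.ledgers["absorbed_ev"]
        resid = absorbed - (d_bound + s.free_energy
                            + s.ledgers["radiated_ev"])
        scale = max(absorbed, 1.0)
        out["energy_residual_rel"].append(resid / scale)
    out["max_electron_drift"] = float(np.max(np.abs(
        out["electron_drift_rel"])))
    out["max_energy_residual"] = float(np.max(np.abs(
        out["energy_residual_rel"])))
    return out


# ---------------------------------------------------------------------------


class System:
    """Assembled target + pulse + operators, ready to advance."""

    def __init__(self, target: TargetComposition, pulse: PulseProfile,
                 policy: SolverPolicy | None = None,
                 basis: SplineBasis | None = None):
        self.target = target
        self.pulse = pulse
        self.policy = policy or SolverPolicy()
        pol = self.policy

        dens = target.number_densities()
        for sym in dens:
            if SYMBOL_TO_Z[sym] > 92:
                raise ValueError(f"unsupported element {sym}")
        self.symbols = sorted(dens, key=lambda s: SYMBOL_TO_Z[s])
        self.densities = dens

        omega = pulse.photon_ev
        models = {s: get_element_model(SYMBOL_TO_Z[s],
                                       pol.collapse_threshold)
                  for s in self.symbols}

        if basis is None:
            basis = build_basis(self._grid_spec(models, omega))
        self.basis = basis
        self.kin = Kinetics(basis, tbr_nodes=pol.tbr_nodes,
                            tbr_max_ev=pol.tbr_max_ev)

        self.elements: list[ElementRuntime] = []
        for s in self.symbols:
            mode = pol.element_mode(SYMBOL_TO_Z[s])
            er = ElementRuntime(
                models[s], s, dens[s], target.charges.get(s, 0), mode,
                self.kin, pol, omega)
            self.elements.append(er)
        self.coef = np.zeros(basis.K)
        self.ledgers = dict.fromkeys(_LEDGER_NAMES, 0.0)
        self.time = 0.0
        self.cascade = None   # optional CascadePartition (see cascade.py)
        self._t_lo, self._t_hi = -np.inf, np.inf  # current smooth branch
        for er in self.elements:
            er.refresh_activations()

    # ------------------------------------------------------------------
    def _grid_spec(self, models, omega) -> GridSpec:
        pol = self.policy
        peaks = []
        bmax = 0.0
        for s in self.symbols:
            m = models[s]
            if pol.element_mode(m.Z) == "none":
                continue
            g = m.initial_index(self.target.charges.get(s, 0))
            for line in m.photo_lines(g):
                if line.threshold_ev < omega:
                    peaks.append(omega - line.threshold_ev)
                    bmax = max(bmax, line.threshold_ev)
            # dominant Auger energies of single-hole daughters
            for line in m.photo_lines(g):
                if line.threshold_ev >= omega or line.shell > 0:
                    continue
                dls = m.decay_lines(line.dst)
                if dls:
                    top = max((d for d in dls if d.kind == "auger"),
                              key=lambda d: d.rate_fs, default=None)
                    if top is not None:
                        peaks.append(top.energy_ev)
        peaks.extend(pol.extra_peaks)
        emax = omega + 2 * pol.tbr_max_ev + pol.tbr_bmax_ev + 100.0
        return GridSpec(emax=emax, peaks=tuple(sorted(set(peaks))),
                        thermal_max=pol.thermal_max_ev, n_log=pol.n_log)

    # ------------------------------------------------------------------
    # state packing
    def _pack(self) -> np.ndarray:
        parts = [self.coef]
        for er in self.elements:
            parts.append(er.P)
        parts.append(np.array([self.ledgers[k] for k in _LEDGER_NAMES]))
        if self.cascade is not None:
            parts.append(self.cascade.coefs.ravel())
        return np.concatenate(parts)

    def _unpack(self, y: np.ndarray):
        K = self.basis.K
        self.coef = y[:K].copy()
        off = K
        for er in self.elements:
            n = er.P.size
            er.P = y[off:off + n].copy()
            off += n
        for k, v in zip(_LEDGER_NAMES, y[off:off + len(_LEDGER_NAMES)]):
            self.ledgers[k] = float(v)
        off += len(_LEDGER_NAMES)
        if self.cascade is not None:
            nch = self.cascade.coefs.shape[0]
            self.cascade.coefs = y[off:off + nch * K].reshape(nch, K).copy()

    # ------------------------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        pol = self.policy
        K = self.basis.K
        kin = self.kin
        c = y[:K]
        phi_q = kin.basis.Bq @ c
        # clamp the flux argument into the current smooth branch so that
        # Runge-Kutta stages never straddle a profile discontinuity
        t_j = min(max(t, self._t_lo), self._t_hi)
        J = self.pulse.flux_cm2(t_j) if pol.photo else 0.0
        omega = self.pulse.photon_ev

        cas = self.cascade
        ncha = cas.coefs.shape[0] if cas is not None else 0
        phi_f_t_all = kin.tbr_design @ c
        if cas is not None:
            off_cas = y.size - ncha * K
            G = y[off_cas:].reshape(ncha, K)
            dG = np.zeros_like(G)
            # channel shares on the TBR node grid
            sh_t = np.empty((ncha, kin.tbr_e.size))
            good = np.abs(phi_f_t_all) > 1e-300
            for n in range(ncha):
                sh_t[n] = np.where(good, (kin.tbr_design @ G[n])
                                   / np.where(good, phi_f_t_all, 1.0),
                                   1.0 / ncha)

        dc = np.zeros(K)
        loss_tot = np.zeros(kin.eq.size)
        dy = np.zeros_like(y)
        led = np.zeros(len(_LEDGER_NAMES))
        off = K
        for er in self.elements:
            nP = er.P.size
            P = y[off:off + nP]
            dP = np.zeros(nP)
            nX = er.n
            if cas is not None and er.mode != "none":
                ch_ph = cas.channel(f"{er.symbol} photo")
                ch_au = cas.channel(f"{er.symbol} auger")
            if er.ph_src.size and J > 0:
                flows = J * er.ph_sigma * np.maximum(P[er.ph_src], 0.0)
                np.subtract.at(dP, er.ph_src, flows)
                np.add.at(dP, er.ph_dst, flows)
                src = (flows * nX) @ er.ph_deltas
                dc += src
                if cas is not None:
                    dG[ch_ph] += src
                tot = float(flows.sum())
                led[0] += nX * omega * tot
                led[2] += nX * tot
            if er.dc_src.size:
                flows = er.dc_rate * np.maximum(P[er.dc_src], 0.0)
                np.subtract.at(dP, er.dc_src, flows)
                np.add.at(dP, er.dc_dst, flows)
                aug = er.dc_is_auger
                src = (flows * nX) @ er.dc_deltas
                dc += src
                if cas is not None:
                    dG[ch_au] += src
                led[1] += nX * float((flows[~aug] * er.dc_energy[~aug]).sum())
                led[3] += nX * float(flows[aug].sum())
            if er.eii_src.size and pol.eii:
                rates = er.eii_rate_vecs @ c          # events/fs per atom
                np.maximum(rates, 0.0, out=rates)
                flows = rates * np.maximum(P[er.eii_src], 0.0)
                np.subtract.at(dP, er.eii_src, flows)
                np.add.at(dP, er.eii_dst, flows)
                w = nX * np.maximum(P[er.eii_src], 0.0)
                nch = er.eii_src.size
                Gc = (er.eii_gain @ c).reshape(nch, K)
                dc += w @ Gc
                loss_tot += w @ er.eii_loss
                led[4] += nX * float(flows.sum())
                if cas is not None:
                    # secondaries follow the impactor's channel (single
                    # BLAS call over all channels)
                    Gg = (er.eii_gain @ G.T).reshape(nch, K, ncha)
                    dG += np.einsum("c,ckn->nk", w, Gg, optimize=True)
            if er.tbr_src.size and pol.tbr:
                b = kin.basis
                Pu = np.maximum(P[er.tbr_src], 0.0)
                f_t = np.maximum(kin.tbr_sqrt * phi_f_t_all, 0.0)
                Fw = f_t * kin.tbr_w
                # per-channel event-rate densities (ordered pairs)
                Rs = er.tbr_kmats * Fw[None, :, None] * Fw[None, None, :]
                ev = Rs.sum(axis=(1, 2))             # events/fs per ion
                flows = ev * Pu
                np.subtract.at(dP, er.tbr_src, flows)
                np.add.at(dP, er.tbr_dst, flows)
                led[5] += nX * float(flows.sum())
                w = nX * Pu                          # weight per channel
                if np.any(w * ev > 0):
                    Rsum = Rs.sum(axis=2)            # ntb x nt
                    esum = (kin.tbr_e[:, None] + kin.tbr_e[None, :])
                    evE = (Rs * esum[None]).sum(axis=(1, 2))
                    # removal of both partners, aggregated over channels
                    rem = 2.0 * (w @ Rsum)
                    dcc = -b.solve_mass(kin.tbr_design.T @ rem)
                    dcc = b.fix_moments(dcc, -2.0 * float(w @ ev),
                                        -float(w @ evE))
                    # injection at the merged energies (moment-exact)
                    Tw = w[:, None, None] * Rs
                    dcc += np.einsum("ckij,cij->k", er.tbr_deltas, Tw,
                                     optimize=True)
                    dc += dcc
                    if cas is not None:
                        # channel removal follows each node's own share;
                        # the merged electron splits 50/50 between the
                        # two channels involved
                        WR = sh_t * rem[None, :]
                        d_all = -b.solve_mass(kin.tbr_design.T @ WR.T)
                        dn_t = -WR.sum(axis=1)
                        de_t = -(WR @ kin.tbr_e)
                        d_all = b.fix_moments_batch(d_all, dn_t, de_t)
                        u_rows = np.einsum("ckij,cij->ki", er.tbr_deltas,
                                           Tw, optimize=True)
                        u_cols = np.einsum("ckij,cij->kj", er.tbr_deltas,
                                           Tw, optimize=True)
                        d_all += 0.5 * (u_rows + u_cols) @ sh_t.T
                        dG += d_all.T
            dy[off:off + nP] = dP
            off += nP
        # artificial tracer sources (intensity-proportional mode)
        if cas is not None and J > 0:
            for i, tr in enumerate(cas.tracers):
                if tr.mode != "rate":
                    continue
                rate = tr.rate_factor * cas.tracer_sigma_ref * J
                d = kin.basis.project_delta(tr.energy_ev, rate)
                dc += d
                dG[cas.tracer_channel[i]] += d
                led[0] += rate * tr.energy_ev
        # aggregated EII loss (weak form, consistent with the rate vectors)
        if np.any(loss_tot):
            lw = kin.wm * loss_tot
            dc -= kin.basis.solve_mass(kin.basis.Bq.T @ (lw * phi_q))
            if cas is not None:
                for n in range(ncha):
                    dG[n] -= kin.basis.solve_mass(
                        kin.basis.Bq.T @ (lw * (kin.basis.Bq @ G[n])))
        dy[:K] = dc
        dy[off:off + len(_LEDGER_NAMES)] = led
        if cas is not None:
            dy[off_cas:] = dG.ravel()
        return dy

    # ------------------------------------------------------------------
    def _ee_halfstep(self, dt_half: float):
        """Crank-Nicolson EE update of f (and partition channels) in
        place; conserves f's density and energy exactly."""
        if not self.policy.ee:
            return
        c = self.coef
        n0, e0 = self.basis.moments(c)
        if n0 <= 0:
            return
        E = self.kin.ee_linear_matrix(c)
        A = np.eye(self.basis.K) - 0.5 * dt_half * E
        c_new = np.linalg.solve(A, c + 0.5 * dt_half * (E @ c))
        c_fixed = self.basis.fix_moments(c_new, n0, e0)
        self.coef = c_fixed
        if self.cascade is not None:
            G = self.cascade.coefs
            rhs = G.T + 0.5 * dt_half * (E @ G.T)
            G_new = np.linalg.solve(A, rhs).T
            # distribute the moment repair over channels by density share
            resid = c_fixed - G_new.sum(axis=0)
            shares = np.array([abs(self.basis.m0 @ g) for g in G_new])
            tot = shares.sum()
            shares = shares / tot if tot > 0 else np.full(len(G_new),
                                                          1.0 / len(G_new))
            G_new += shares[:, None] * resid[None, :]
            self.cascade.coefs = G_new

    def _max_rate(self) -> float:
        lam = 1.0
        for er in self.elements:
            if er.dc_rate.size:
                out = np.zeros(er.P.size)
                np.add.at(out, er.dc_src, er.dc_rate)
                lam = max(lam, float(out.max()))
        return lam

    def step(self, dt: float):
        """One adaptive attempt; returns (accepted, dt_next, err)."""
        pol = self.policy
        t = self.time
        coef_in = self.coef.copy()
        cas_in = (self.cascade.coefs.copy()
                  if self.cascade is not None else None)
        self._ee_halfstep(0.5 * dt)
        y0 = self._pack()

        k1 = self.rhs(t, y0)
        k2 = self.rhs(t + 0.5 * dt, y0 + 0.5 * dt * k1)
        k3 = self.rhs(t + 0.75 * dt, y0 + 0.75 * dt * k2)
        y1 = y0 + dt * (2.0 * k1 + 3.0 * k2 + 4.0 * k3) / 9.0
        k4 = self.rhs(t + dt, y1)
        err_vec = dt * (-5.0 * k1 / 72.0 + k2 / 12.0 + k3 / 9.0 - k4 / 8.0)

        # error norm: populations + free density/energy moments
        K = self.basis.K
        npop = sum(er.P.size for er in self.elements)
        perr = err_vec[K:K + npop]
        pval = np.abs(y1[K:K + npop])
        e_pop = np.max(np.abs(perr) / (pol.atol_pop + pol.rtol * pval)) \
            if perr.size else 0.0
        n_free = abs(self.basis.m0 @ y1[:K])
        e_free = abs(self.basis.m1 @ y1[:K])
        n_scale = pol.rtol * max(
            n_free, 1e-8 * sum(er.n for er in self.elements))
        e_scale = pol.rtol * max(e_free, n_scale * 10.0)
        e_n = abs(self.basis.m0 @ err_vec[:K]) / n_scale
        e_e = abs(self.basis.m1 @ err_vec[:K]) / e_scale
        err = max(e_pop, e_n, e_e)

        if not np.isfinite(err) or err > 1.0:
            # reject: restore pre-EE state
            self.coef = coef_in
            if cas_in is not None:
                self.cascade.coefs = cas_in
            if not np.isfinite(err):
                return False, max(dt * 0.2, pol.dt_min), np.inf
            fac = max(0.25, 0.85 * err**-(1.0 / 3.0))
            return False, max(dt * fac, pol.dt_min), err

        # accept: second EE half-step
        self._unpack(y1)
        self._ee_halfstep(0.5 * dt)
        self.time = t + dt
        fac = min(4.0, 0.9 * max(err, 1e-8)**-(1.0 / 3.0))
        dt_next = min(dt * fac, pol.dt_max, 1.5 / self._max_rate())
        return True, max(dt_next, pol.dt_min), err

    # ------------------------------------------------------------------
    def _sample(self) -> TrajectorySample:
        pops, charges, shells = {}, {}, {}
        bound_n = 0.0
        bound_e = 0.0
        for er in self.elements:
            pops[er.symbol] = {er.idx[p]: float(er.P[p])
                               for p in range(er.P.size)
                               if abs(er.P[p]) > 1e-14}
            nb = er.mean_bound()
            charges[er.symbol] = er.model.Z - nb
            shells[er.symbol] = er.mean_shell_occ()
            bound_n += er.n * nb
            bound_e += er.n * er.bound_energy()
        n_free, e_free = self.basis.moments(self.coef)
        part_d = part_c = None
        if self.cascade is not None:
            part_d = self.cascade.densities(self.basis)
            part_c = {lab: g.copy() for lab, g in
                      zip(self.cascade.labels, self.cascade.coefs)}
        return TrajectorySample(
            t=self.time, coef=self.coef.copy(), populations=pops,
            charges=charges, shell_occ=shells,
            ledgers=dict(self.ledgers), free_density=n_free,
            free_energy=e_free, bound_electrons_cm3=bound_n,
            bound_energy_cm3=bound_e, partition_density=part_d,
            partition_coefs=part_c)

    def _apply_impulse_tracers(self):
        cas = self.cascade
        if cas is None:
            return
        for i, tr in enumerate(cas.tracers):
            if tr.mode != "impulse" or i in cas._done_impulses:
                continue
            if self.time >= tr.t0_fs - 1e-7:
                n_free = float(self.basis.m0 @ self.coef)
                amount = tr.density_cm3 or 1e-8 * max(n_free, 1.0)
                d = self.basis.project_delta(tr.energy_ev, amount)
                self.coef = self.coef + d
                cas.coefs[cas.tracer_channel[i]] += d
                self.ledgers["absorbed_ev"] += amount * tr.energy_ev
                cas.injected[i] = amount
                cas._done_impulses.add(i)

    def _breakpoints(self, t_start, t_end) -> list[float]:
        """Times where the right-hand side is discontinuous; the
        integrator lands on these exactly instead of straddling them."""
        bps = []
        if self.pulse.shape == "square":
            h = 0.5 * self.pulse.fwhm_fs
            bps += [-h, h]
        if self.cascade is not None:
            bps += [tr.t0_fs for tr in self.cascade.tracers
                    if tr.mode == "impulse"]
        return sorted(b for b in set(bps) if t_start < b < t_end)

    def run(self, t_start: float, t_end: float,
            callbacks: list | None = None) -> Trajectory:
        """Advance from t_start to t_end, sampling every policy.out_dt."""
        if t_start >= t_end:
            raise ValueError("t_start must precede t_end")
        pol = self.policy
        self.time = t_start
        self._apply_impulse_tracers()
        samples = [self._sample()]
        next_out = t_start + pol.out_dt
        bps = self._breakpoints(t_start, t_end)
        dt = pol.dt_init
        rejects = 0
        eps_t = 1e-7
        while self.time < t_end - 1e-12:
            dt = min(dt, t_end - self.time, max(next_out - self.time, 1e-9))
            for b in bps:
                if self.time < b - eps_t:
                    dt = min(dt, b - self.time)
                    break
                if abs(self.time - b) <= eps_t:
                    # hop over the discontinuity (measure-zero sliver)
                    self.time = b + eps_t
                    self._apply_impulse_tracers()
            lo = max([t_start] + [b for b in bps if b <= self.time + eps_t])
            hi = min([t_end] + [b for b in bps if b > self.time + eps_t])
            self._t_lo, self._t_hi = lo + eps_t, hi - eps_t
            dt = max(dt, pol.dt_min)
            ok, dt_next, err = self.step(dt)
            if not ok:
                rejects += 1
                if dt <= pol.dt_min * 1.0001:
                    raise RuntimeError(
                        f"step-size underflow at t={self.time:.4f} fs "
                        f"(err={err:.3e}); system too stiff for policy")
                dt = dt_next
                continue
            dt = dt_next
            for er in self.elements:
                er.refresh_activations()
            if callbacks:
                for cb in callbacks:
                    cb(self)
            if self.time >= next_out - 1e-9:
                samples.append(self._sample())
                next_out += pol.out_dt
        if samples[-1].t < self.time - 1e-9:
            samples.append(self._sample())
        log.info("run finished: %d samples, %d rejected steps",
                 len(samples), rejects)
        return Trajectory(
            samples=samples, basis=self.basis, target=self.target,
            pulse=self.pulse, policy=pol, element_symbols=list(self.symbols),
            densities=dict(self.densities),
            ground_bound={er.symbol: er.model.Z - (0)   # neutral bound count
                          for er in self.elements},
            shell_labels={er.symbol: [s.label for s in er.model.shells]
                          for er in self.elements})


def build_system(target: TargetComposition, pulse: PulseProfile,
                 policy: SolverPolicy | None = None) -> System:
    """Assemble a simulation system (spec'd entry point)."""
    return System(target, pulse, policy)


def run_simulation(target: TargetComposition, pulse: PulseProfile,
                   policy: SolverPolicy | None = None,
                   t_start: float | None = None,
                   t_end: float | None = None) -> Trajectory:
    """Build and run over [t_start, t_end] (default +-1.2 FWHM)."""
    sys_ = build_system(target, pulse, policy)
    if t_start is None or t_end is None:
        w = pulse.default_window()
        t_start = w[0] if t_start is None else t_start
        t_end = w[1] if t_end is None else t_end
    return sys_.run(t_start, t_end)
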