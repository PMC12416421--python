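"""Discrete collision/source operators on the spline basis.

All operators are assembled in weak form against the basis of the smooth
part phi (f = sqrt(eps) phi) and returned in coefficient space (mass
matrix folded in).  Discrete bookkeeping is exact: each EII event
removes one electron at the impact energy and adds two at the secondary
energies (net +1 electron, -B kinetic energy); each TBR event does the
reverse; the electron-electron (EE) operator conserves number
structurally and energy via a minimal moment correction.  Because every
right-hand-side evaluation is exactly balanced, any Runge-Kutta
combination of evaluations conserves the linear invariants (total
electrons, total energy) to round-off.

EE model: isotropic energy-space Fokker-Planck operator for like
particles, reduced to three cumulative integrals of f,

    A1 = int_0^e f de',  A2 = int_0^e e' f de',  A3 = int_e^inf f/sqrt(e') de',

    df/dt = d/de { a [ 3 A1 F0 + 2 (A2 + e^{3/2} A3) F0' ] },  F0 = f/sqrt(e),

whose stationary solutions are Maxwellians (the drag/diffusion balance
A2 + e^{3/2} A3 = (3T/2) A1 holds identically for a Maxwellian) and
whose magnitude `a` is fixed by the high-velocity Landau drag limit
de/dt = -4 pi n e^4 ln(Lambda) / (m v).  In the phi representation F0 is
exactly the splined field, so Maxwellian stationarity survives
discretization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atomic.rates import _sdcs_at, beb_cross_section, tbr_kernel
from .constants import C_CM_PER_FS, ELECTRON_MASS_EV, electron_speed_cm_fs
from .splines import SplineBasis

_E2_EV_CM = 1.43996454e-7  # e^2 in eV cm (Gaussian units)
# a / lnLambda = (4 pi / 3) e^4 c / sqrt(2 m c^2)   [eV^{3/2} cm^3 / fs]
EE_PREF = (4.0 * np.pi / 3.0) * _E2_EV_CM**2 * C_CM_PER_FS / np.sqrt(
    2.0 * ELECTRON_MASS_EV)


def coulomb_log(n_cm3: float, T_ev: float, floor: float = 2.0) -> float:
    """NRL-style thermal electron-electron Coulomb logarithm, floored."""
    if n_cm3 <= 0 or T_ev <= 0:
        return floor
    lnT = np.log(T_ev)
    val = (23.5 - np.log(np.sqrt(n_cm3) * T_ev**-1.25)
           - np.sqrt(1e-5 + (lnT - 2.0) ** 2 / 16.0))
    return float(max(val, floor))


@dataclass
class EIIChannelOps:
    """Discrete operators of one EII channel (one subshell of one
    configuration)."""

    B: float
    loss_q: np.ndarray    # sigma(e) v(e) at quadrature nodes [cm^3/fs]
    rate_vec: np.ndarray  # K-vector: events/fs per atom = rate_vec @ c
    gain: np.ndarray      # K x K coefficient-space gain operator


@dataclass
class TBRChannelOps:
    """Discrete operators of one TBR channel (inverse of an EII channel)."""

    B: float
    kmat: np.ndarray      # kernel on the TBR node grid [cm^6/fs]
    deltas: np.ndarray    # K x (nt*nt): moment-exact injection coefficients


class Kinetics:
    """Operator factory bound to one spline basis."""

    def __init__(self, basis: SplineBasis, tbr_nodes: int = 18,
                 tbr_max_ev: float = 400.0, tbr_min_ev: float = 1e-3):
        self.basis = basis
        b = basis
        self.eq = b.quad_x
        self.wq = b.quad_w          # plain measure
        self.wm = b.quad_wm         # sqrt(e)-weighted measure
        self.vq = electron_speed_cm_fs(self.eq)
        self.c_one = b.solve_mass(b.m0)   # exact representation of phi=1
        self.c_eps = b.solve_mass(b.m1)   # exact representation of phi=e
        self.u_n = b._moment_dual[:, 0]
        self.u_e = b._moment_dual[:, 1]
        self._build_cumulative_matrices()
        self._build_tbr_grid(tbr_nodes, tbr_min_ev,
                             min(tbr_max_ev, b.domain[1]))

    # ------------------------------------------------------------------
    def _build_cumulative_matrices(self):
        """Matrices mapping coefficients to A1/A2/A3 at quadrature nodes.

        Integrands are f = sqrt(e) phi, e f, and f/sqrt(e) = phi, all
        smooth in phi.  Interval totals use the main quadrature; partial
        integrals from the interval start to each node use a 3-point
        sub-rule, so the maps are exact for phi in the spline space up
        to the sub-rule's degree.
        """
        b = self.basis
        bp = b.breakpoints
        nq = self.eq.size
        n_int = bp.size - 1
        per = b.quad_per_interval
        interval_of = np.repeat(np.arange(n_int), per)

        Bq = b.Bq
        F_rows = np.zeros((n_int, b.K))
        E_rows = np.zeros((n_int, b.K))
        H_rows = np.zeros((n_int, b.K))
        for i_int in range(n_int):
            sel = interval_of == i_int
            F_rows[i_int] = (self.wm[sel, None] * Bq[sel]).sum(0)
            E_rows[i_int] = (self.wm[sel, None] * self.eq[sel, None]
                             * Bq[sel]).sum(0)
            H_rows[i_int] = (self.wq[sel, None] * Bq[sel]).sum(0)

        pre_F = np.vstack([np.zeros(b.K), np.cumsum(F_rows, axis=0)])[:-1]
        pre_E = np.vstack([np.zeros(b.K), np.cumsum(E_rows, axis=0)])[:-1]
        post_H = np.vstack([np.cumsum(H_rows[::-1], axis=0)[::-1][1:],
                            np.zeros(b.K)])

        xg, wg = np.polynomial.legendre.leggauss(3)
        a_I = bp[interval_of]
        half = 0.5 * (self.eq - a_I)
        mid = 0.5 * (self.eq + a_I)
        sub_x = mid[:, None] + half[:, None] * xg[None, :]
        sub_w = half[:, None] * wg[None, :]
        Bsub = b.design(sub_x.ravel()).reshape(nq, 3, b.K)
        rt = np.sqrt(np.maximum(sub_x, 0.0))
        P_f = np.einsum("qs,qs,qsk->qk", sub_w, rt, Bsub)
        P_e = np.einsum("qs,qs,qsk->qk", sub_w, rt * sub_x, Bsub)
        P_h = np.einsum("qs,qsk->qk", sub_w, Bsub)

        self.A1mat = pre_F[interval_of] + P_f
        self.A2mat = pre_E[interval_of] + P_e
        self.A3mat = post_H[interval_of] + (H_rows[interval_of] - P_h)

    # ------------------------------------------------------------------
    def _build_tbr_grid(self, n_nodes, emin, emax):
        """Dedicated coarse log-Gauss grid for the TBR bilinear form."""
        xg, wg = np.polynomial.legendre.leggauss(n_nodes)
        lo, hi = np.log(emin), np.log(emax)
        u = 0.5 * (lo + hi) + 0.5 * (hi - lo) * xg
        self.tbr_e = np.exp(u)
        self.tbr_w = 0.5 * (hi - lo) * wg * self.tbr_e  # de = e du
        self.tbr_design = self.basis.design(self.tbr_e)
        self.tbr_sqrt = np.sqrt(self.tbr_e)

    # ------------------------------------------------------------------
    def eii_ops(self, B: float, U: float, N: float) -> EIIChannelOps:
        b = self.basis
        sig = beb_cross_section(self.eq, B, U, N)
        loss_q = sig * self.vq
        rate_vec = b.Bq.T @ (self.wm * loss_q)
        # secondary-pair spectrum per impact node (absolute density in
        # the outgoing energy).  Each column is moment-repaired *on its
        # own kinematic support* by a multiplicative linear tilt
        # (a + b eps) solved for exact number (2 sigma v) and energy
        # ((T - B) sigma v) moments; a global minimal-norm repair would
        # park the correction in the sparse multi-keV region of the
        # grid and seed spurious fast electrons.
        T_in = self.eq[None, :]
        W_out = self.eq[:, None]
        spec = _sdcs_at(T_in, W_out, B, U, N) * self.vq[None, :]  # nq x nq
        n_tgt = 2.0 * loss_q
        e_tgt = np.maximum(self.eq - B, 0.0) * loss_q
        m00 = self.wq @ spec
        m01 = (self.wq * self.eq) @ spec
        m11 = (self.wq * self.eq**2) @ spec
        det = m00 * m11 - m01 * m01
        scale = np.abs(m00 * m11) + m01 * m01
        good = (loss_q > 0) & (scale > 0) & (np.abs(det) > 1e-12 * scale)
        safe = np.where(good, det, 1.0)
        a = np.where(good, (n_tgt * m11 - e_tgt * m01) / safe, 0.0)
        bb = np.where(good, (e_tgt * m00 - n_tgt * m01) / safe, 0.0)
        # fallback for numerically empty columns: pure rescale
        resc = (~good) & (loss_q > 0) & (m00 > 0)
        a[resc] = (n_tgt[resc] / m00[resc])
        spec = spec * a[None, :] + (spec * self.eq[:, None]) * bb[None, :]
        spec[:, loss_q <= 0] = 0.0
        raw = b.solve_mass(b.Bq.T @ (self.wq[:, None] * spec))    # K x nq
        gain = raw @ (self.wm[:, None] * b.Bq)                    # K x K
        return EIIChannelOps(B=B, loss_q=loss_q, rate_vec=rate_vec, gain=gain)

    # ------------------------------------------------------------------
    def tbr_ops(self, B: float, U: float, N: float, g_lower: float,
                g_upper: float) -> TBRChannelOps:
        e = self.tbr_e
        kmat = tbr_kernel(e[:, None], e[None, :], B, U, N, g_lower, g_upper)
        etot = (e[:, None] + e[None, :] + B).ravel()
        deltas = self.basis.project_delta_batch(etot)
        return TBRChannelOps(B=B, kmat=kmat, deltas=deltas)

    def tbr_apply(self, ops: TBRChannelOps, coef: np.ndarray):
        """Evaluate one TBR channel.

        Returns (dc, events): dc is the coefficient rate per unit
        density of the recombining ion [df/dt += n_upper * dc]; events
        is the event rate per upper ion.
        """
        f_t = self.tbr_sqrt * (self.tbr_design @ coef)
        f_t = np.maximum(f_t, 0.0)
        Fw = f_t * self.tbr_w
        R = ops.kmat * np.outer(Fw, Fw)
        events = float(R.sum())
        if events <= 0.0:
            return np.zeros(self.basis.K), 0.0
        r_node = 2.0 * R.sum(axis=1) / np.maximum(self.tbr_w, 1e-300)
        dc = -self.basis.solve_mass(self.tbr_design.T @ (self.tbr_w * r_node))
        rm_e = float((R * (self.tbr_e[:, None] + self.tbr_e[None, :])).sum())
        dc = self.basis.fix_moments(dc, -2.0 * events, -rm_e)
        dc += ops.deltas @ R.ravel()
        return dc, events

    # ------------------------------------------------------------------
    # electron-electron collisions
    def ee_coefficients(self, coef: np.ndarray):
        """Nodal factors (alpha, beta) with frozen field integrals such
        that the EE flux is J = alpha phi + beta phi'."""
        b = self.basis
        n = float(b.m0 @ coef)
        if n <= 0:
            return None
        T = max((2.0 / 3.0) * float(b.m1 @ coef) / n, 1e-3)
        lnL = coulomb_log(n, T)
        a = EE_PREF * lnL
        A1 = self.A1mat @ coef
        A2 = self.A2mat @ coef
        A3 = self.A3mat @ coef
        e = self.eq
        D = 2.0 * (A2 + e * np.sqrt(e) * A3)
        alpha = a * 3.0 * A1
        beta = a * D
        return alpha, beta

    def ee_apply(self, coef: np.ndarray) -> np.ndarray:
        """dphi/dt from EE collisions, number- and energy-exact."""
        ab = self.ee_coefficients(coef)
        if ab is None:
            return np.zeros(self.basis.K)
        alpha, beta = ab
        b = self.basis
        J = alpha * (b.Bq @ coef) + beta * (b.dBq @ coef)
        dc = b.solve_mass(-(b.dBq.T @ (self.wq * J)))
        de = float(b.m1 @ dc)
        return dc - de * self.u_e

    def ee_linear_matrix(self, coef: np.ndarray) -> np.ndarray:
        """Coefficient-space linearization of EE with frozen field
        integrals (for implicit treatment of the stiff thermal bulk).

        Number conservation is structural (columns have zero density
        moment); the small energy-moment quadrature leak of the full
        distribution is repaired at the step level, not here, so that
        the matrix can also propagate partition channels, whose energy
        must genuinely flow between channels.
        """
        ab = self.ee_coefficients(coef)
        K = self.basis.K
        if ab is None:
            return np.zeros((K, K))
        alpha, beta = ab
        b = self.basis
        Wd = self.wq[:, None]
        rhs_mat = -(b.dBq.T @ (Wd * (alpha[:, None] * b.Bq
                                     + beta[:, None] * b.dBq)))
        return b.solve_mass(rhs_mat)
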