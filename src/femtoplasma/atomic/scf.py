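"""Configuration-average self-consistent mean field (Hartree-Fock-Slater).

Solves the radially averaged central-field problem for an arbitrary
occupancy vector: local (Xalpha) exchange, Latter tail correction, and a
logarithmic radial grid with Numerov integration.  Eigenvalues are found
by node-count bisection of the outward shooting solution, which is
robust for the Dirichlet problem on a finite grid.

Everything internal is in Hartree atomic units; the public result is in
eV.  One-electron configurations are treated analytically (the local
exchange does not cancel self-interaction, and the hydrogenic limit is
exact), and the bare nucleus returns a zero-orbital result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ..constants import HARTREE_EV

XALPHA = 0.7  # exchange parameter; Slater=1, Kohn-Sham=2/3, empirical ~0.7


class SCFError(RuntimeError):
    """Self-consistency failure; carries the last residual."""

    def __init__(self, msg: str, residual: float = np.nan):
        super().__init__(f"{msg} (last residual {residual:.3e})")
        self.residual = residual


@dataclass
class MeanFieldResult:
    """Orbital data for one configuration, energies in eV."""

    Z: int
    occ_nl: tuple[tuple[int, int, float], ...]  # (n, l, occupancy)
    eps_ev: np.ndarray       # orbital eigenvalues (negative, eV)
    binding_ev: np.ndarray   # -eps (Koopmans orbital binding, eV)
    kinetic_ev: np.ndarray   # mean orbital kinetic energy U (eV)
    total_energy_ev: float   # configuration-average total energy (eV)
    converged: bool = True
    potential: np.ndarray | None = None  # converged V(r) for warm starts


_G_CAP = 0.25  # h^2 g / 12 beyond this: sign-preserving exponential step


@njit(cache=True)
def _numerov_nodes(g, h):
    """Outward Numerov sweep of y'' = g y; returns interior node count.

    In strongly classically forbidden zones (h^2 g/12 large) the Numerov
    rational update is replaced by a monotone exponential step: the true
    solution cannot change sign there, and the rational form would flip
    sign spuriously when its denominator crosses zero.
    """
    n = g.size
    c = h * h / 12.0
    y0 = 1e-30
    y1 = 1e-30 * np.exp(h)
    nodes = 0
    for i in range(1, n - 1):
        if c * g[i + 1] > _G_CAP or c * g[i] > _G_CAP or c * g[i - 1] > _G_CAP:
            y2 = y1 * np.exp(h * np.sqrt(max(g[i], 1e-300)))
        else:
            y2 = (2.0 * y1 * (1.0 + 5.0 * c * g[i])
                  - y0 * (1.0 - c * g[i - 1])) / (1.0 - c * g[i + 1])
            if (y2 < 0.0 and y1 > 0.0) or (y2 > 0.0 and y1 < 0.0):
                nodes += 1
        if abs(y2) > 1e200:
            y1 *= 1e-200
            y2 *= 1e-200
        y0 = y1
        y1 = y2
    return nodes


@njit(cache=True)
def _numerov_outward(g, h, lhalf, x0, i_stop):
    """Outward sweep storing y up to index i_stop; start ~ r^(l+1/2)."""
    n = g.size
    c = h * h / 12.0
    y = np.zeros(n)
    y[0] = np.exp(lhalf * x0) * 1e-20
    y[1] = np.exp(lhalf * (x0 + h)) * 1e-20
    for i in range(1, min(i_stop + 1, n - 1)):
        if c * g[i + 1] > _G_CAP or c * g[i] > _G_CAP or c * g[i - 1] > _G_CAP:
            y[i + 1] = y[i] * np.exp(h * np.sqrt(max(g[i], 1e-300)))
        else:
            y[i + 1] = (2.0 * y[i] * (1.0 + 5.0 * c * g[i])
                        - y[i - 1] * (1.0 - c * g[i - 1])) / (1.0 - c * g[i + 1])
        if abs(y[i + 1]) > 1e200:
            for j in range(i + 2):
                y[j] *= 1e-200
    return y


@njit(cache=True)
def _numerov_inward(g, h, m):
    """Inward sweep from the outer boundary down to index m."""
    n = g.size
    c = h * h / 12.0
    y = np.zeros(n)
    y[n - 1] = 1e-30
    y[n - 2] = 1e-30 * 2.0
    for i in range(n - 2, m, -1):
        if c * g[i - 1] > _G_CAP or c * g[i] > _G_CAP or c * g[i + 1] > _G_CAP:
            y[i - 1] = y[i] * np.exp(h * np.sqrt(max(g[i], 1e-300)))
        else:
            y[i - 1] = (2.0 * y[i] * (1.0 + 5.0 * c * g[i])
                        - y[i + 1] * (1.0 - c * g[i + 1])) / (1.0 - c * g[i - 1])
        if abs(y[i - 1]) > 1e200:
            for j in range(i - 1, n):
                y[j] *= 1e-200
    return y


def _gfun(r, V, eps, l):
    return (l + 0.5) ** 2 + 2.0 * r * r * (V - eps)


def _solve_orbital(r, V, h, n_qn, l, x0, eps_lo, eps_hi=-1e-9, iters=46,
                   eps_guess=None):
    """Eigenvalue/eigenfunction of the radial problem by node-count
    bisection.  Returns (eps, u) with u normalized, u = sqrt(r) y."""
    target = n_qn - l - 1
    lo, hi = eps_lo, eps_hi
    if eps_guess is not None and eps_guess < 0:
        # tight bracket around the previous iteration's eigenvalue
        glo = eps_guess * 1.5 - 2.0
        ghi = min(eps_guess * 0.6 + 1.0, eps_hi)
        if (_numerov_nodes(_gfun(r, V, glo, l), h) <= target
                and _numerov_nodes(_gfun(r, V, ghi, l), h) > target):
            lo, hi = glo, ghi
    if lo == eps_lo:
        if _numerov_nodes(_gfun(r, V, lo, l), h) > target:
            lo = eps_lo * 4 - 10.0
            if _numerov_nodes(_gfun(r, V, lo, l), h) > target:
                raise SCFError(f"bracket failure for orbital n={n_qn} l={l}")
        if _numerov_nodes(_gfun(r, V, hi, l), h) <= target:
            raise SCFError(f"orbital n={n_qn} l={l} not bound on the grid")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if _numerov_nodes(_gfun(r, V, mid, l), h) <= target:
            lo = mid
        else:
            hi = mid
    eps = 0.5 * (lo + hi)
    g = _gfun(r, V, eps, l)
    # matching index: outermost classical turning point
    neg = np.nonzero(g < 0.0)[0]
    m = int(neg[-1]) if neg.size else r.size // 2
    m = min(max(m, 2), r.size - 3)
    y_out = _numerov_outward(g, h, l + 0.5, x0, m)
    y_in = _numerov_inward(g, h, m)
    if y_in[m] == 0.0 or y_out[m] == 0.0 or not np.isfinite(y_in[m]) \
            or not np.isfinite(y_out[m]):
        raise SCFError(f"matching failure n={n_qn} l={l}")
    y = np.empty_like(y_out)
    y[: m + 1] = y_out[: m + 1] / y_out[m]
    y[m:] = y_in[m:] / y_in[m]
    # normalize: int u^2 dr = int y^2 r^2 dx
    w = y * y * r * r
    norm = np.trapezoid(w, dx=h)
    if not (norm > 0 and np.isfinite(norm)):
        raise SCFError(f"normalization failure n={n_qn} l={l}")
    y /= np.sqrt(norm)
    u = y * np.sqrt(r)
    return eps, u, y


def _radial_grid(Z: int, npts: int):
    r_min = 1e-5 / Z
    r_max = 50.0
    x = np.linspace(np.log(r_min), np.log(r_max), npts)
    return np.exp(x), x[1] - x[0], x[0]


def _hartree_potential(r, h, w_density):
    """V_H from the radial density w(r) = sum occ u^2 (int w dr = N)."""
    wdr = w_density * r  # since dr = r dx
    q_in = np.concatenate(([0.0], np.cumsum(0.5 * (wdr[1:] + wdr[:-1]) * h)))
    over = wdr / r  # w/s ds -> (w/r) r dx = w dx
    i_out_rev = np.concatenate(([0.0], np.cumsum(0.5 * (over[1:] + over[:-1])[::-1] * h)))
    i_out = i_out_rev[::-1]
    return q_in / r + i_out


def solve_mean_field(Z: int, occ_nl, npts: int = 480, max_iter: int = 80,
                     mix: float = 0.4, tol: float = 1e-7,
                     v_init: np.ndarray | None = None) -> MeanFieldResult:
    """Solve the configuration-average HFS problem.

    occ_nl: iterable of (n, l, occupancy); occupancies may be fractional
    (collapsed-shell configurations distribute electrons over the merged
    subshells proportionally to their ground occupancies).  v_init warm
    starts the iteration from a nearby configuration's potential.
    """
    occ_nl = tuple((int(n), int(l), float(o)) for n, l, o in occ_nl if o > 0)
    n_elec = sum(o for _, _, o in occ_nl)
    if n_elec == 0:
        z = np.zeros(0)
        return MeanFieldResult(Z, (), z, z, z, 0.0)
    if abs(n_elec - 1.0) < 1e-12 and len(occ_nl) == 1:
        # exact hydrogenic one-electron limit
        n_qn = occ_nl[0][0]
        eps = -0.5 * Z * Z / n_qn**2 * HARTREE_EV
        return MeanFieldResult(
            Z, occ_nl, np.array([eps]), np.array([-eps]), np.array([-eps]),
            eps)

    r, h, x0 = _radial_grid(Z, npts)
    z_ion = Z - n_elec
    # screened initial potential with the right asymptote
    v_asym = -(z_ion + 1.0) / r
    if v_init is not None and v_init.size == r.size:
        V = np.minimum(v_init, v_asym)
    else:
        V = v_asym - (Z - z_ion - 1.0) * np.exp(
            -1.2 * Z ** (1.0 / 3.0) * r) / r

    eps_prev = None
    residual = np.inf
    alpha = XALPHA
    cx = -(3.0 * alpha / 2.0) * (3.0 / np.pi) ** (1.0 / 3.0)
    guesses = [None] * len(occ_nl)
    for it in range(max_iter):
        eps_list, u_list = [], []
        eps_lo = -0.7 * Z * Z - 5.0
        for iorb, (n_qn, l, occ) in enumerate(occ_nl):
            eps, u, _ = _solve_orbital(r, V, h, n_qn, l, x0, eps_lo,
                                       eps_guess=guesses[iorb])
            guesses[iorb] = eps
            eps_list.append(eps)
            u_list.append(u)
        eps_arr = np.array(eps_list)
        w_density = np.zeros_like(r)
        for (n_qn, l, occ), u in zip(occ_nl, u_list):
            w_density += occ * u * u
        vh = _hartree_potential(r, h, w_density)
        rho = w_density / (4.0 * np.pi * r * r)
        vx = cx * np.cbrt(rho)
        v_new = -Z / r + vh + vx
        v_new = np.minimum(v_new, v_asym)  # Latter correction
        if eps_prev is not None and eps_prev.size == eps_arr.size:
            residual = float(np.max(np.abs(eps_arr - eps_prev)
                                    / np.maximum(1.0, np.abs(eps_arr))))
            if residual < tol:
                V = (1.0 - mix) * V + mix * v_new
                break
        eps_prev = eps_arr
        V = (1.0 - mix) * V + mix * v_new
    else:
        raise SCFError(f"SCF did not converge for Z={Z} occ={occ_nl}",
                       residual)

    # converged observables
    kin = []
    for (n_qn, l, occ), eps, u in zip(occ_nl, eps_arr, u_list):
        v_exp = np.trapezoid(u * u * V * r, dx=h)
        kin.append(eps - v_exp)
    kin = np.array(kin)

    e_sum = float(np.sum(eps_arr * np.array([o for _, _, o in occ_nl])))
    e_hartree = 0.5 * float(np.trapezoid(w_density * vh * r, dx=h))
    int_rho_vx = float(np.trapezoid(w_density * vx * r, dx=h))
    e_x = -(9.0 * alpha / 8.0) * (3.0 / np.pi) ** (1.0 / 3.0) * float(
        np.trapezoid(4.0 * np.pi * r * r * rho ** (4.0 / 3.0) * r, dx=h))
    e_total = e_sum - e_hartree - int_rho_vx + e_x

    return MeanFieldResult(
        Z, occ_nl,
        eps_ev=eps_arr * HARTREE_EV,
        binding_ev=-eps_arr * HARTREE_EV,
        kinetic_ev=kin * HARTREE_EV,
        total_energy_ev=e_total * HARTREE_EV,
        potential=V,
    )
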