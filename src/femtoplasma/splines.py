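"""B-spline representation of the free-electron energy distribution.

The physical distribution f(eps, t) (number density per cm^3 per eV) is
represented as f(eps) = sqrt(eps) * phi(eps) with the smooth part phi
expanded in clamped cubic B-splines: phi = sum_k c_k B_k(eps).  Pulling
out the sqrt(eps) phase-space factor makes Maxwellians (and any
distribution regular at the origin) smooth in the basis, which is
essential for the electron-electron collision operator near eps = 0.

All Galerkin machinery uses the weighted inner product
<g, h> = int g h sqrt(eps) d eps with one fixed Gauss-Legendre rule per
knot interval.  Using the same rule for the mass matrix, the moments and
every weak form makes discrete number/energy bookkeeping identities hold
exactly (the basis reproduces phi = 1 and phi = eps exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

__all__ = ["GridSpec", "SplineBasis", "FreeElectronDistribution",
           "build_basis", "regrid"]


@dataclass
class GridSpec:
    """Knot layout request for the energy grid.

    emax        : top of the energy domain (eV); must exceed the highest
                  primary electron energy.
    peaks       : energies (eV) of expected narrow primary-ionization
                  peaks; knots are clustered around each.
    thermal_max : upper edge (eV) of the log-dense low-energy region that
                  resolves the thermal bulk.
    n_log       : number of log-spaced breakpoints in the backbone.
    eps_low     : first nonzero breakpoint (eV).
    peak_halfwidth_frac : cluster half-width as a fraction of the peak
                  energy (floored at 5 eV).
    """

    emax: float
    peaks: tuple[float, ...] = ()
    thermal_max: float = 400.0
    n_log: int = 48
    eps_low: float = 0.15
    peak_halfwidth_frac: float = 0.012
    order: int = 4  # cubic


class SplineBasis:
    """Clamped B-spline basis with sqrt(eps)-weighted Galerkin machinery."""

    def __init__(self, breakpoints: np.ndarray, order: int = 4,
                 quad_per_interval: int = 4):
        bp = np.asarray(sorted(set(float(b) for b in breakpoints)))
        if bp.size < 2:
            raise ValueError("need at least 2 distinct breakpoints")
        if bp.size < order + 1:
            raise ValueError(
                f"need at least order+1={order + 1} knots, got {bp.size}")
        if bp[0] < 0:
            raise ValueError("energy domain must be non-negative")
        self.breakpoints = bp
        self.order = order
        k = order - 1
        self.degree = k
        self.knots = np.concatenate([[bp[0]] * k, bp, [bp[-1]] * k])
        self.K = bp.size + k - 1
        self.quad_per_interval = quad_per_interval

        xg, wg = np.polynomial.legendre.leggauss(quad_per_interval)
        a, b = bp[:-1], bp[1:]
        mid = 0.5 * (a + b)
        half = 0.5 * (b - a)
        self.quad_x = (mid[:, None] + half[:, None] * xg[None, :]).ravel()
        self.quad_w = (half[:, None] * wg[None, :]).ravel()
        self.sqrt_e = np.sqrt(self.quad_x)
        self.quad_wm = self.quad_w * self.sqrt_e   # weighted measure

        dm = BSpline.design_matrix(self.quad_x, self.knots, k)
        self.Bq = dm.toarray()
        dB = np.empty_like(self.Bq)
        for j in range(self.K):
            c = np.zeros(self.K)
            c[j] = 1.0
            dB[:, j] = BSpline(self.knots, c, k).derivative()(self.quad_x)
        self.dBq = dB

        Wm = self.quad_wm
        self.mass = self.Bq.T @ (Wm[:, None] * self.Bq)
        self._mass_cho = cho_factor(self.mass)
        self.m0 = self.Bq.T @ Wm                     # int sqrt(e) B_k
        self.m1 = self.Bq.T @ (Wm * self.quad_x)     # int e sqrt(e) B_k

        A = np.vstack([self.m0, self.m1])
        MiAT = cho_solve(self._mass_cho, A.T)
        gram = A @ MiAT
        self._moment_dual = MiAT @ np.linalg.inv(gram)
        # coefficient representation of phi = eps (Greville abscissae);
        # used by the local multiplicative moment repair
        self.greville = cho_solve(self._mass_cho, self.m1)

    # -- basics -----------------------------------------------------------
    @property
    def domain(self) -> tuple[float, float]:
        return float(self.breakpoints[0]), float(self.breakpoints[-1])

    def evaluate_phi(self, coef: np.ndarray, x) -> np.ndarray:
        """The smooth part phi(eps)."""
        v = BSpline(self.knots, coef, self.degree, extrapolate=False)(
            np.asarray(x, dtype=float))
        return np.nan_to_num(v, nan=0.0)

    def evaluate(self, coef: np.ndarray, x) -> np.ndarray:
        """The physical distribution f(eps) = sqrt(eps) phi(eps)."""
        x = np.asarray(x, dtype=float)
        return np.sqrt(np.maximum(x, 0.0)) * self.evaluate_phi(coef, x)

    def design(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return BSpline.design_matrix(
            np.clip(x, *self.domain), self.knots, self.degree).toarray()

    def solve_mass(self, rhs: np.ndarray) -> np.ndarray:
        return cho_solve(self._mass_cho, rhs)

    # -- projections ------------------------------------------------------
    def project_function(self, fn) -> np.ndarray:
        """Weighted Galerkin projection of a physical density fn(eps):
        minimizes the sqrt(e)-weighted misfit of phi = fn / sqrt(e)."""
        vals = fn(self.quad_x)
        return self.solve_mass(self.Bq.T @ (self.quad_w * vals))

    def project_delta(self, e0: float, rate: float = 1.0) -> np.ndarray:
        """Weak-form projection of rate * delta(eps - e0) with exact
        zeroth and first moments (rate, rate * e0)."""
        lo, hi = self.domain
        if not (lo <= e0 <= hi):
            raise ValueError(
                f"point source at {e0} eV outside domain [{lo}, {hi}]; "
                "regrid required")
        if rate == 0.0:
            return np.zeros(self.K)
        b = self.design([e0])[0] * rate
        dc = self.solve_mass(b)
        return self.fix_moments(dc, rate, rate * e0)

    def project_delta_batch(self, energies: np.ndarray) -> np.ndarray:
        """Moment-exact unit point sources at several energies: returns
        (K, n) columns equivalent to project_delta(e, 1.0)."""
        e = np.clip(np.asarray(energies, dtype=float), *self.domain)
        dc = self.solve_mass(self.design(e).T)           # K x n
        return self.fix_moments_batch(dc, np.ones(e.size), e)

    def fix_moments(self, coef: np.ndarray, n_target: float,
                    e_target: float) -> np.ndarray:
        """Exact-moment repair by a multiplicative linear tilt.

        Returns (a + b*eps) * coef with (a, b) solved so that the
        density and energy moments match exactly.  The tilt keeps the
        correction *on the support of the shape being corrected* — a
        global minimal-norm correction instead relocates repair density
        into whatever energy region is cheap in the mass metric (the
        sparse multi-keV part of the grid), which injects spurious fast
        electrons.  Falls back to the global dual correction only when
        the shape is degenerate (e.g. a zero vector)."""
        tilted = coef * self.greville
        m00 = float(self.m0 @ coef)
        m01 = float(self.m0 @ tilted)
        m10 = float(self.m1 @ coef)
        m11 = float(self.m1 @ tilted)
        det = m00 * m11 - m01 * m10
        scale = abs(m00 * m11) + abs(m01 * m10)
        if scale > 0 and abs(det) > 1e-9 * scale:
            a = (n_target * m11 - e_target * m01) / det
            b = (e_target * m00 - n_target * m10) / det
            return a * coef + b * tilted
        dn = n_target - m00
        de = e_target - m10
        return coef + self._moment_dual @ np.array([dn, de])

    def fix_moments_batch(self, coefs: np.ndarray, n_targets: np.ndarray,
                          e_targets: np.ndarray) -> np.ndarray:
        """Columnwise fix_moments for a (K, n) block."""
        tilted = coefs * self.greville[:, None]
        m00 = self.m0 @ coefs
        m01 = self.m0 @ tilted
        m10 = self.m1 @ coefs
        m11 = self.m1 @ tilted
        det = m00 * m11 - m01 * m10
        scale = np.abs(m00 * m11) + np.abs(m01 * m10)
        good = (scale > 0) & (np.abs(det) > 1e-9 * scale)
        safe = np.where(good, det, 1.0)
        a = np.where(good, (n_targets * m11 - e_targets * m01) / safe, 1.0)
        b = np.where(good, (e_targets * m00 - n_targets * m10) / safe, 0.0)
        out = a[None, :] * coefs + b[None, :] * tilted
        if not np.all(good):
            bad = np.nonzero(~good)[0]
            corr = self._moment_dual @ np.vstack(
                [n_targets[bad] - m00[bad], e_targets[bad] - m10[bad]])
            out[:, bad] = coefs[:, bad] + corr
        return out

    def moments(self, coef: np.ndarray) -> tuple[float, float]:
        return float(self.m0 @ coef), float(self.m1 @ coef)


def build_basis(spec: GridSpec) -> SplineBasis:
    """Construct the adaptive energy basis from a grid request."""
    if spec.emax <= spec.eps_low:
        raise ValueError("emax must exceed eps_low")
    for p in spec.peaks:
        if not (0.0 <= p <= spec.emax):
            raise ValueError(
                f"requested peak at {p} eV outside domain [0, {spec.emax}]")
    n_th = max(int(0.6 * spec.n_log), 8)
    n_hi = max(spec.n_log - n_th, 8)
    th_top = min(spec.thermal_max, spec.emax)
    pts = [0.0]
    pts += list(np.geomspace(spec.eps_low, th_top, n_th))
    if th_top < spec.emax:
        pts += list(np.geomspace(th_top * 1.12, spec.emax, n_hi))
    for p in spec.peaks:
        if p <= 0:
            continue
        hw = max(5.0, spec.peak_halfwidth_frac * p)
        for q in (p - 2 * hw, p - 0.6 * hw, p, p + 0.6 * hw, p + 2 * hw):
            if 0.0 < q < spec.emax:
                pts.append(q)
    pts.append(spec.emax)
    pts = np.array(sorted(pts))
    keep = [pts[0]]
    for q in pts[1:]:
        if q - keep[-1] > max(0.02, 0.004 * q):
            keep.append(q)
    keep[-1] = spec.emax
    return SplineBasis(np.array(keep), order=spec.order)


@dataclass
class FreeElectronDistribution:
    """f(eps) = sqrt(eps) sum_k c_k B_k(eps), density per (cm^3 eV)."""

    basis: SplineBasis
    coef: np.ndarray = None

    def __post_init__(self):
        if self.coef is None:
            self.coef = np.zeros(self.basis.K)

    def density(self) -> float:
        return float(self.basis.m0 @ self.coef)

    def energy_density(self) -> float:
        return float(self.basis.m1 @ self.coef)

    def temperature_estimate(self) -> float:
        """Effective temperature 2/3 <eps>."""
        n = self.density()
        if n <= 0:
            return 0.0
        return (2.0 / 3.0) * self.energy_density() / n

    def __call__(self, x):
        return self.basis.evaluate(self.coef, x)

    def copy(self) -> "FreeElectronDistribution":
        return FreeElectronDistribution(self.basis, self.coef.copy())


def regrid(coef: np.ndarray, old: SplineBasis, new: SplineBasis,
           rel_tol: float = 1e-6) -> np.ndarray:
    """Project a distribution onto a new basis, preserving density and
    energy exactly; raises if the new domain would truncate support."""
    n0 = float(old.m0 @ coef)
    e0 = float(old.m1 @ coef)
    lo, hi = new.domain
    olo, ohi = old.domain
    if lo > olo + 1e-12 or hi < ohi - 1e-12:
        vals = old.Bq @ coef
        outside = (old.quad_x < lo) | (old.quad_x > hi)
        lost = float(np.sum(old.quad_wm[outside] * np.abs(vals[outside])))
        if lost > rel_tol * max(abs(n0), 1e-300):
            raise ValueError(
                f"regrid would truncate {lost:.3e} of the density")
    phi_new = old.evaluate_phi(coef, np.clip(new.quad_x, olo, ohi))
    c_new = new.solve_mass(new.Bq.T @ (new.quad_wm * phi_new))
    return new.fix_moments(c_new, n0, e0)
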