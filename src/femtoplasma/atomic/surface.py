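"""Piecewise-quadratic shell-occupation energy surface.

For collapsed heavy elements the ionization-reachable configuration set
is far too large for one self-consistent-field solution per visited
configuration.  Configuration-average total energies are, however,
smooth functions of the shell occupation numbers, so we expand them to
second order around reference configurations ("anchors") placed along
the proportional-stripping path:

    E(n) ~ E_ref + a . (n - n_ref) + 1/2 (n - n_ref)^T H (n - n_ref),

with the gradient a from central occupation differences and the Hessian
H from single- and pair-removal SCF samples at each anchor.  Per-shell
Koopmans bindings and mean kinetic energies are interpolated linearly
from the same samples.  Against direct Delta-SCF thresholds this
reproduces ionization energies to a few percent across charge states up
to ~+35, at the cost of a few hundred SCF solutions per element instead
of tens of thousands.
"""

from __future__ import annotations

import numpy as np


class ShellEnergySurface:
    """Quadratic-in-occupation energy model for one collapsed element."""

    def __init__(self, solve, ground_occ: np.ndarray,
                 anchor_charges=(0, 6, 12, 18, 24, 32, 40)):
        """solve(occ_tuple) must return (E_total, B[], U[]) from a direct
        mean-field solution at shell-level resolution."""
        self.g = np.asarray(ground_occ, dtype=int)
        self.ns = self.g.size
        ztot = int(self.g.sum())
        self.anchors = []
        eye = np.eye(self.ns, dtype=int)
        for q in anchor_charges:
            ne = ztot - q
            if ne < 2:
                continue
            ref = self._proportional(ne)
            E0, B0, U0 = solve(tuple(ref))
            a = np.zeros(self.ns)
            H = np.zeros((self.ns, self.ns))
            FB = np.zeros((self.ns, self.ns))   # dB_s/dn_t
            FU = np.zeros((self.ns, self.ns))
            Em = np.full(self.ns, np.nan)
            Ep = np.full(self.ns, np.nan)
            Bm = {}
            for s in range(self.ns):
                if ref[s] > 0:
                    Em[s], Bs, Us = solve(tuple(ref - eye[s]))
                    Bm[s] = (Bs, Us)
                if ref[s] < self.g[s]:
                    Ep[s], _, _ = solve(tuple(ref + eye[s]))
            for s in range(self.ns):
                if np.isfinite(Em[s]) and np.isfinite(Ep[s]):
                    a[s] = 0.5 * (Ep[s] - Em[s])
                    H[s, s] = Ep[s] + Em[s] - 2.0 * E0
                elif np.isfinite(Em[s]):
                    a[s] = E0 - Em[s]
                elif np.isfinite(Ep[s]):
                    a[s] = Ep[s] - E0
            for s in range(self.ns):
                for t in range(s + 1, self.ns):
                    if ref[s] > 0 and ref[t] > 0:
                        Est, _, _ = solve(tuple(ref - eye[s] - eye[t]))
                        H[s, t] = H[t, s] = Est - Em[s] - Em[t] + E0
            # binding/kinetic sensitivities from the removal samples
            for t, (Bs, Us) in Bm.items():
                for s in range(self.ns):
                    if Bs[s] > 0 and B0[s] > 0:
                        FB[s, t] = -(Bs[s] - B0[s])
                        FU[s, t] = -(Us[s] - U0[s])
            self.anchors.append(dict(q=q, ref=ref, E0=E0, a=a, H=H,
                                     B0=B0.copy(), U0=U0.copy(),
                                     FB=FB, FU=FU))
        if not self.anchors:
            raise ValueError("no usable anchors")

    def _proportional(self, ne: int) -> np.ndarray:
        raw = self.g * (ne / self.g.sum())
        base = np.floor(raw).astype(int)
        rem = raw - base
        for i in np.argsort(-rem)[: ne - int(base.sum())]:
            base[i] += 1
        return base

    def _anchor(self, occ):
        q = int(self.g.sum()) - int(sum(occ))
        return min(self.anchors, key=lambda A: abs(A["q"] - q))

    def energy(self, occ) -> float:
        A = self._anchor(occ)
        d = np.asarray(occ, dtype=float) - A["ref"]
        return float(A["E0"] + A["a"] @ d + 0.5 * d @ A["H"] @ d)

    def shell_data(self, occ):
        """(B[], U[]) per shell, linearly interpolated; positive-clipped."""
        A = self._anchor(occ)
        d = np.asarray(occ, dtype=float) - A["ref"]
        B = np.maximum(A["B0"] + A["FB"] @ d, 1.0)
        U = np.maximum(A["U0"] + A["FU"] @ d, 1.0)
        return B, U
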