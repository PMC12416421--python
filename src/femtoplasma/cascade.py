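"""Cascade partitioning of the free-electron distribution.

Auxiliary distributions g_n(eps, t) partition f = sum_n g_n by the
primary process that seeded each electron's lineage (e.g. "O photo",
"Gd auger", or an artificially injected tracer).  The decomposition
rule: photo/Auger sources feed their own channel; EII secondaries are
credited to the impactor's channel in proportion to its share
g_n(eps)/f(eps) of the impacting density; density arising from TBR
between different cascades is split evenly between the two channels
involved; EE transport moves each channel with the test-particle
linearization against the full f (which sums exactly to the nonlinear
EE operator, preserving the sum rule).

Channels are advanced inside the same Runge-Kutta stages as f itself,
so sum_n g_n = f is preserved to integrator accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TracerSchedule:
    """Injection schedule for an artificial tracer population.

    mode "impulse": a single injection of `density` (cm^-3) at t0.
    mode "rate": continuous injection proportional to the pulse
    intensity, at `rate_factor` times the total photoionization rate of
    the undamaged target (per unit volume) at the given intensity.
    """

    energy_ev: float
    mode: str = "impulse"          # "impulse" | "rate"
    t0_fs: float = 0.0
    density_cm3: float = 0.0
    rate_factor: float = 3.0

    def __post_init__(self):
        if self.mode not in ("impulse", "rate"):
            raise ValueError(f"unknown tracer mode {self.mode!r}")


@dataclass
class CascadePartition:
    """Channel labels and coefficient blocks (managed by the System)."""

    labels: list[str]
    coefs: np.ndarray                      # (n_channels, K)
    tracers: list[TracerSchedule] = field(default_factory=list)
    tracer_channel: dict[int, int] = field(default_factory=dict)
    tracer_sigma_ref: float = 0.0          # sum n_X sigma_X of undamaged target
    injected: dict[int, float] = field(default_factory=dict)  # cm^-3 per tracer
    _done_impulses: set = field(default_factory=set)

    def channel(self, label: str) -> int:
        return self.labels.index(label)

    def density(self, i: int, basis) -> float:
        return float(basis.m0 @ self.coefs[i])

    def densities(self, basis) -> dict[str, float]:
        return {lab: float(basis.m0 @ g)
                for lab, g in zip(self.labels, self.coefs)}

    def sum_coef(self) -> np.ndarray:
        return self.coefs.sum(axis=0)


def attach_partition(system, tracers: list[TracerSchedule] | None = None):
    """Enable cascade partitioning on a freshly built System.

    Creates one channel per (element, photo) and (element, auger) for
    every element with primary processes enabled, plus one channel per
    tracer.  Must be called before `run`, with f still empty (otherwise
    existing density could not be attributed).
    """
    if float(np.abs(system.coef).sum()) != 0.0:
        raise ValueError("partition must be attached before any density "
                         "exists; channels could not be attributed")
    labels = []
    for er in system.elements:
        if er.mode == "none":
            continue
        labels.append(f"{er.symbol} photo")
        labels.append(f"{er.symbol} auger")
    tracers = list(tracers or [])
    part = CascadePartition(
        labels=labels + [f"tracer@{tr.energy_ev:g}eV#{i}"
                         for i, tr in enumerate(tracers)],
        coefs=np.zeros((len(labels) + len(tracers), system.basis.K)),
        tracers=tracers,
    )
    for i in range(len(tracers)):
        part.tracer_channel[i] = len(labels) + i
        part.injected[i] = 0.0
    # reference photoionization rate of the undamaged target (per J)
    sig = 0.0
    for er in system.elements:
        if er.mode == "none":
            continue
        g = er.model.initial_index(system.target.charges.get(er.symbol, 0))
        for line in er.model.photo_lines(g):
            sig += er.n * er.model.photo_sigma(line, system.pulse.photon_ev)
    part.tracer_sigma_ref = sig
    system.cascade = part
    return part


def heavy_fraction(system_or_traj_sample, part_densities: dict[str, float],
                   heavy_symbols: set[str]) -> float:
    """Fraction of the partitioned free density seeded by heavy atoms."""
    tot = sum(part_densities.values())
    if tot <= 0:
        return 0.0
    heavy = sum(v for k, v in part_densities.items()
                if k.split()[0] in heavy_symbols)
    return heavy / tot
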