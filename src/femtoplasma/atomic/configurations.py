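"""Enumeration of ionic electron configurations.

A configuration is an occupancy vector over the modeled levels of an
element (true subshells for light elements, collapsed principal shells
for heavy ones).  The enumerated set is the ionization-reachable set:
each level ranges over 0..(ground occupancy).  Configurations are
indexed by a mixed-radix code so that very large sets (4 x 10^5 for Gd)
never need to be materialized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .shells import ShellSpec, shell_structure


@dataclass(frozen=True)
class Configuration:
    """An ionic electronic configuration ('xi' in the rate equations)."""

    Z: int
    occ: tuple[int, ...]
    index: int

    @property
    def n_electrons(self) -> int:
        return sum(self.occ)

    @property
    def charge(self) -> int:
        return self.Z - self.n_electrons


@dataclass
class ConfigurationSet:
    """Lazy, indexable set of all ionization-reachable configurations."""

    Z: int
    shells: list[ShellSpec]
    _radices: tuple[int, ...] = field(init=False)
    _strides: tuple[int, ...] = field(init=False)

    def __post_init__(self):
        caps = [s.capacity for s in self.shells]
        self._radices = tuple(c + 1 for c in caps)
        strides = []
        acc = 1
        for r in reversed(self._radices):
            strides.append(acc)
            acc *= r
        self._strides = tuple(reversed(strides))
        self._size = acc

    def __len__(self) -> int:
        return self._size

    @property
    def ground_occ(self) -> tuple[int, ...]:
        return tuple(s.capacity for s in self.shells)

    @property
    def ground_index(self) -> int:
        return self.index_of(self.ground_occ)

    def index_of(self, occ) -> int:
        occ = tuple(int(o) for o in occ)
        if len(occ) != len(self.shells):
            raise ValueError("occupancy vector length mismatch")
        idx = 0
        for o, r, s in zip(occ, self._radices, self._strides):
            if not (0 <= o < r):
                raise ValueError(f"occupancy {o} outside [0, {r - 1}]")
            idx += o * s
        return idx

    def occ_of(self, index: int) -> tuple[int, ...]:
        if not (0 <= index < self._size):
            raise IndexError(index)
        occ = []
        for r, s in zip(self._radices, self._strides):
            occ.append(index // s)
            index %= s
        return tuple(occ)

    def __getitem__(self, index: int) -> Configuration:
        return Configuration(self.Z, self.occ_of(index), index)

    def __iter__(self):
        for i in range(self._size):
            yield self[i]

    def neighbors_remove(self, occ) -> list[tuple[int, tuple[int, ...]]]:
        """Configurations reachable by removing one electron:
        list of (shell position, new occupancy vector)."""
        out = []
        for i, o in enumerate(occ):
            if o > 0:
                new = list(occ)
                new[i] -= 1
                out.append((i, tuple(new)))
        return out


def enumerate_configurations(Z: int, collapse_threshold: int = 30) -> ConfigurationSet:
    """Build the configuration set for element Z.

    collapse_threshold: atomic number at which principal-shell collapse
    begins (n >= 2 subshells merged per n).
    """
    shells = shell_structure(Z, collapse_threshold=collapse_threshold)
    return ConfigurationSet(Z=Z, shells=shells)


def statistical_weight(shells: list[ShellSpec], occ) -> float:
    """Configuration-average statistical weight: product over levels of
    C(full capacity, occupancy).

    For collapsed shells the full quantum capacity 2n^2 is used (not the
    ground-occupancy cap), which matters only for ratios of weights in
    detailed-balance factors.
    """
    g = 1.0
    for s, o in zip(shells, occ):
        full_cap = 2 * s.n**2 if s.collapsed else 2 * (2 * (s.l or 0) + 1)
        full_cap = max(full_cap, s.capacity)
        g *= math.comb(full_cap, int(o))
    return g


def ionization_path(cs: ConfigurationSet, order: str = "outer") -> list[tuple[int, ...]]:
    """A pure-ionization path from the ground configuration to the bare
    nucleus, removing one electron at a time (outermost-first by default).
    Used by energy-monotonicity checks."""
    occ = list(cs.ground_occ)
    path = [tuple(occ)]
    while sum(occ) > 0:
        pos = max(i for i, o in enumerate(occ) if o > 0) if order == "outer" else \
            min(i for i, o in enumerate(occ) if o > 0)
        occ[pos] -= 1
        path.append(tuple(occ))
    return path
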