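"""Ground-state shell structure of the elements.

Subshells are filled in Madelung order with the usual exceptions
(Cr, Cu, Nb, Mo, ..., Gd).  For heavy elements (Z >= 30 by default) all
subshells sharing a principal quantum number n >= 2 are merged into a
single collapsed level; the combinatorial size of the configuration set
otherwise grows factorially with the number of subshells.
"""

from __future__ import annotations

from dataclasses import dataclass

L_LABELS = "spdfghi"

# Madelung (n + l, then n) filling order as (n, l) pairs.
_MADELUNG = [
    (1, 0), (2, 0), (2, 1), (3, 0), (3, 1), (4, 0), (3, 2), (4, 1),
    (5, 0), (4, 2), (5, 1), (6, 0), (4, 3), (5, 2), (6, 1), (7, 0),
    (5, 3), (6, 2), (7, 1),
]

# Ground-state occupancy exceptions, as {(n, l): occupancy} overrides of
# plain Madelung filling.
_EXCEPTIONS = {
    24: {(4, 0): 1, (3, 2): 5},          # Cr
    29: {(4, 0): 1, (3, 2): 10},         # Cu
    41: {(5, 0): 1, (4, 2): 4},          # Nb
    42: {(5, 0): 1, (4, 2): 5},          # Mo
    44: {(5, 0): 1, (4, 2): 7},          # Ru
    45: {(5, 0): 1, (4, 2): 8},          # Rh
    46: {(5, 0): 0, (4, 2): 10},         # Pd
    47: {(5, 0): 1, (4, 2): 10},         # Ag
    57: {(4, 3): 0, (5, 2): 1},          # La
    58: {(4, 3): 1, (5, 2): 1},          # Ce
    64: {(4, 3): 7, (5, 2): 1},          # Gd
    78: {(6, 0): 1, (5, 2): 9},          # Pt
    79: {(6, 0): 1, (5, 2): 10},         # Au
}


def subshell_capacity(l: int) -> int:
    return 2 * (2 * l + 1)


def ground_subshells(Z: int) -> list[tuple[int, int, int]]:
    """Occupied ground-state subshells of element Z as (n, l, occupancy).

    Sorted by (n, l).  Raises ValueError outside 1 <= Z <= 92.
    """
    if not (1 <= Z <= 92):
        raise ValueError(f"unsupported element Z={Z}; supported range is 1..92")
    occ: dict[tuple[int, int], int] = {}
    remaining = Z
    for nl in _MADELUNG:
        if remaining <= 0:
            break
        cap = subshell_capacity(nl[1])
        take = min(cap, remaining)
        occ[nl] = take
        remaining -= take
    if remaining > 0:
        raise ValueError(f"unsupported element Z={Z}")
    for nl, o in _EXCEPTIONS.get(Z, {}).items():
        occ[nl] = o
    occ = {nl: o for nl, o in occ.items() if o > 0}
    assert sum(occ.values()) == Z
    return sorted(((n, l, o) for (n, l), o in occ.items()))


def subshell_label(n: int, l: int) -> str:
    return f"{n}{L_LABELS[l]}"


@dataclass(frozen=True)
class ShellSpec:
    """One modeled level: either a true (n, l) subshell or a collapsed
    principal shell holding every subshell of that n."""

    n: int
    l: int | None          # None for a collapsed shell
    capacity: int          # ground-state occupancy (enumeration cap)
    sub_nl: tuple[tuple[int, int, int], ...]  # (n, l, ground occ) members

    @property
    def label(self) -> str:
        if self.l is None:
            return f"n{self.n}"
        return subshell_label(self.n, self.l)

    @property
    def collapsed(self) -> bool:
        return self.l is None


def shell_structure(Z: int, collapse_threshold: int = 30) -> list[ShellSpec]:
    """Modeled level structure for element Z.

    For Z >= collapse_threshold, subshells with n >= 2 are merged per
    principal quantum number into a single level (the n = 1 shell is a
    single subshell anyway).  Levels are capped at their ground-state
    occupancy: ionization can only deplete them, and recombination in the
    rate model never over-fills a level past its initial occupancy.
    """
    subs = ground_subshells(Z)
    if Z < collapse_threshold:
        return [
            ShellSpec(n=n, l=l, capacity=o, sub_nl=((n, l, o),))
            for n, l, o in subs
        ]
    by_n: dict[int, list[tuple[int, int, int]]] = {}
    for n, l, o in subs:
        by_n.setdefault(n, []).append((n, l, o))
    out = []
    for n in sorted(by_n):
        members = tuple(sorted(by_n[n]))
        cap = sum(o for _, _, o in members)
        if len(members) == 1:
            n0, l0, o0 = members[0]
            out.append(ShellSpec(n=n0, l=l0, capacity=o0, sub_nl=members))
        else:
            out.append(ShellSpec(n=n, l=None, capacity=cap, sub_nl=members))
    return out
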