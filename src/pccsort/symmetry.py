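"""Occupancy combinatorics for the six ligand-binding sites of a D3 scaffold.

The complex is modelled as two stacked trimeric rings, giving six
equivalent binding sites.  Each site is either occupied or unoccupied, so
there are 2**6 = 64 occupancy configurations.  Configurations related by a
rotation of the point group describe the same physical species; the orbits
of the group action are the *oligomeric isomers*, and orbits sharing the
same occupancy count n form one *oligomeric formula* (alpha_n beta_6).

Site indexing convention
------------------------
``flat_index = 3 * layer + position`` with ``layer`` in {0, 1} (top/bottom
ring) and ``position`` in {0, 1, 2} within the ring.  The dihedral group is
generated by

* ``r`` — three-fold rotation: ``(layer, position) -> (layer, position + 1 mod 3)``
* ``f`` — two-fold flip:       ``(layer, position) -> (1 - layer, -position mod 3)``

Any conjugate choice of the two-fold axes yields identical orbit counts;
only this one convention is exposed so orbit representatives are stable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "N_SITES",
    "SiteLabel",
    "OccupancyConfig",
    "PointGroupAction",
    "IsomerOrbit",
    "IsomerCensus",
    "build_d3_action",
    "build_c3_action",
    "build_c2_action",
    "build_trivial_action",
    "enumerate_configs",
    "enumerate_orbits",
    "burnside_count",
]

N_SITES = 6

Permutation = tuple[int, ...]


@dataclass(frozen=True, order=True)
class SiteLabel:
    """One of the six binding sites, addressed by (layer, position)."""

    layer: int
    position: int

    def __post_init__(self) -> None:
        if self.layer not in (0, 1):
            raise ValueError(f"layer must be 0 or 1, got {self.layer}")
        if self.position not in (0, 1, 2):
            raise ValueError(f"position must be in 0..2, got {self.position}")

    @property
    def flat_index(self) -> int:
        return 3 * self.layer + self.position

    @classmethod
    def from_flat(cls, flat_index: int) -> "SiteLabel":
        if not 0 <= flat_index < N_SITES:
            raise ValueError(f"flat_index must be in 0..5, got {flat_index}")
        return cls(layer=flat_index // 3, position=flat_index % 3)


@dataclass(frozen=True, order=True)
class OccupancyConfig:
    """Binary occupancy state of the six sites, ordered by flat index."""

    bits: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != N_SITES:
            raise ValueError(f"expected {N_SITES} bits, got {len(self.bits)}")
        object.__setattr__(self, "bits", tuple(bool(b) for b in self.bits))

    @property
    def n_alpha(self) -> int:
        """Number of occupied sites (the n of alpha_n beta_6)."""
        return sum(self.bits)

    def permuted(self, perm: Permutation) -> "OccupancyConfig":
        """Image of this configuration under a site permutation.

        Site ``perm[i]`` of the image carries the occupancy of site ``i``.
        """
        new_bits = [False] * N_SITES
        for i, b in enumerate(self.bits):
            new_bits[perm[i]] = b
        return OccupancyConfig(tuple(new_bits))

    def complement(self) -> "OccupancyConfig":
        return OccupancyConfig(tuple(not b for b in self.bits))

    def as_string(self) -> str:
        """Compact '010110'-style representation (1 = occupied)."""
        return "".join("1" if b else "0" for b in self.bits)

    @classmethod
    def from_string(cls, s: str) -> "OccupancyConfig":
        if len(s) != N_SITES or set(s) - {"0", "1"}:
            raise ValueError(f"expected 6 chars of 0/1, got {s!r}")
        return cls(tuple(c == "1" for c in s))


def _compose(g: Permutation, h: Permutation) -> Permutation:
    """(g o h)(i) = g(h(i))."""
    return tuple(g[h[i]] for i in range(N_SITES))


def _invert(g: Permutation) -> Permutation:
    inv = [0] * N_SITES
    for i, j in enumerate(g):
        inv[j] = i
    return tuple(inv)


_IDENTITY: Permutation = tuple(range(N_SITES))


@dataclass(frozen=True)
class PointGroupAction:
    """A permutation group acting on the six site indices.

    The group is stored extensionally — every element as an explicit
    permutation — so closure and inverses are trivially checkable.
    """

    name: str
    permutations: frozenset[Permutation]

    def validate(self) -> None:
        """Raise ``ValueError`` unless ``permutations`` form a group."""
        perms = self.permutations
        if not perms:
            raise ValueError("empty permutation set is not a group")
        for p in perms:
            if sorted(p) != list(range(N_SITES)):
                raise ValueError(f"{p} is not a permutation of 0..5")
        if _IDENTITY not in perms:
            raise ValueError("group action is missing the identity")
        for g in perms:
            if _invert(g) not in perms:
                raise ValueError(f"group action not closed under inverse: {g}")
            for h in perms:
                if _compose(g, h) not in perms:
                    raise ValueError(
                        f"group action not closed under composition: {g} o {h}"
                    )

    @property
    def order(self) -> int:
        return len(self.permutations)

    def sorted_elements(self) -> list[Permutation]:
        return sorted(self.permutations)


def _layer_pos_perm(fn) -> Permutation:
    out = [0] * N_SITES
    for flat in range(N_SITES):
        layer, pos = flat // 3, flat % 3
        nl, np_ = fn(layer, pos)
        out[flat] = 3 * nl + np_ % 3
    return tuple(out)


_ROTATION = _layer_pos_perm(lambda l, p: (l, p + 1))
_FLIP = _layer_pos_perm(lambda l, p: (1 - l, -p))


def _closure(generators: list[Permutation]) -> frozenset[Permutation]:
    elements = {_IDENTITY}
    frontier = list(generators)
    while frontier:
        g = frontier.pop()
        if g in elements:
            continue
        elements.add(g)
        for h in list(elements):
            for prod in (_compose(g, h), _compose(h, g)):
                if prod not in elements:
                    frontier.append(prod)
    return frozenset(elements)


def build_d3_action() -> PointGroupAction:
    """The dihedral group of order 6: C3 rotations plus three ring-swapping
    two-fold axes."""
    group = _closure([_ROTATION, _FLIP])
    assert len(group) == 6
    return PointGroupAction(name="D3", permutations=group)


def build_c3_action() -> PointGroupAction:
    """The rotation-only subgroup of order 3."""
    return PointGroupAction(name="C3", permutations=_closure([_ROTATION]))


def build_c2_action() -> PointGroupAction:
    """The order-2 subgroup generated by one two-fold flip."""
    return PointGroupAction(name="C2", permutations=_closure([_FLIP]))


def build_trivial_action() -> PointGroupAction:
    """Identity-only group (no site identifications)."""
    return PointGroupAction(name="trivial", permutations=frozenset([_IDENTITY]))


ACTIONS = {
    "D3": build_d3_action,
    "C3": build_c3_action,
    "C2": build_c2_action,
    "trivial": build_trivial_action,
}


@dataclass(frozen=True)
class IsomerOrbit:
    """One oligomeric isomer: an orbit of configurations under the group."""

    representative: OccupancyConfig
    members: frozenset[OccupancyConfig]
    formula_n: int = field(init=False)

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member of its orbit")
        if self.representative != min(self.members):
            raise ValueError("representative must be the lex-minimal member")
        n_values = {m.n_alpha for m in self.members}
        if len(n_values) != 1:
            raise ValueError("orbit members must share n_alpha")
        object.__setattr__(self, "formula_n", self.representative.n_alpha)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class IsomerCensus:
    """All isomer orbits plus the per-formula isomer counts."""

    orbits: tuple[IsomerOrbit, ...]
    per_formula: dict[int, int]

    @property
    def n_isomers(self) -> int:
        return len(self.orbits)

    @property
    def n_configs(self) -> int:
        return sum(o.size for o in self.orbits)


def enumerate_configs() -> list[OccupancyConfig]:
    """All 64 occupancy configurations in lexicographic bit order."""
    return [
        OccupancyConfig(bits)
        for bits in itertools.product((False, True), repeat=N_SITES)
    ]


def enumerate_orbits(action: PointGroupAction) -> IsomerCensus:
    """Partition the 64 configurations into isomer orbits by brute force.

    Orbits are listed in lexicographic order of their canonical (minimal)
    representative, so two calls always return identical censuses.
    """
    action.validate()
    seen: set[OccupancyConfig] = set()
    orbits: list[IsomerOrbit] = []
    for config in enumerate_configs():
        if config in seen:
            continue
        members = frozenset(config.permuted(g) for g in action.permutations)
        seen.update(members)
        orbits.append(IsomerOrbit(representative=min(members), members=members))
    orbits.sort(key=lambda o: o.representative)
    per_formula: dict[int, int] = {n: 0 for n in range(N_SITES + 1)}
    for orbit in orbits:
        per_formula[orbit.formula_n] += 1
    return IsomerCensus(orbits=tuple(orbits), per_formula=per_formula)


def _cycle_count(perm: Permutation) -> int:
    seen = [False] * N_SITES
    cycles = 0
    for start in range(N_SITES):
        if seen[start]:
            continue
        cycles += 1
        i = start
        while not seen[i]:
            seen[i] = True
            i = perm[i]
    return cycles


def burnside_count(action: PointGroupAction) -> int:
    """Number of orbits via the orbit-counting theorem.

    Averages, over group elements, the number of configurations each
    element fixes; a permutation with c cycles on the sites fixes exactly
    2**c binary configurations.  Serves as an independent cross-check of
    :func:`enumerate_orbits`.
    """
    action.validate()
    total = sum(2 ** _cycle_count(g) for g in action.permutations)
    count, remainder = divmod(total, action.order)
    assert remainder == 0, "orbit-counting sum must be divisible by |G|"
    return count
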