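"""Active-space definition and exhaustive enumeration of spin-paired structures.

A structure distributes ``n_electrons`` over ``n`` orbitals as lone pairs
(doubly occupied), vacant orbitals, singlet-coupled pairs and unpaired
(radical) electrons, leaving exactly ``2S`` electrons unpaired.  Structures
sharing one placement of lone pairs/vacant orbitals form a *subspace*; all
ranking and independence machinery downstream operates per subspace.

Orbital indices are 1-based labels carried by the user; they need not be
contiguous.  All enumeration output is deterministic and canonically ordered
(sorted by subspace key, then pair list, then radical list).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "EmptySpaceError",
    "OrbitalInfo",
    "ActiveSpace",
    "VBStructure",
    "SubspaceKey",
    "twice_spin",
    "valid_double_counts",
    "n_pair_groupings",
    "count_total_structures",
    "enumerate_structures",
    "group_by_subspace",
    "covalent_subspaces",
    "canonical_sort",
]


class EmptySpaceError(ValueError):
    """Raised when no occupancy pattern can satisfy electron count, spin and parity."""


def twice_spin(spin: float | int) -> int:
    """Validate a non-negative half-integer spin and return 2S as an int."""
    t = round(2 * float(spin))
    if t < 0 or abs(2 * float(spin) - t) > 1e-9:
        raise ValueError(f"total spin must be a non-negative half-integer, got {spin!r}")
    return t


@dataclass(frozen=True)
class OrbitalInfo:
    """One active orbital: label, host atom and optional metadata."""

    index: int
    atom_id: str
    symmetry_label: str | None = None
    centre: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if int(self.index) != self.index:
            raise ValueError(f"orbital index must be an integer, got {self.index!r}")
        if not str(self.atom_id):
            raise ValueError(f"orbital {self.index}: atom_id must be non-empty")


@dataclass(frozen=True)
class VBStructure:
    """One spin-coupling structure.

    ``doubly_occupied``, ``vacant``, ``pairs`` and ``unpaired`` are pairwise
    disjoint and together cover the parent space's orbitals.  Pairs are stored
    as sorted 2-tuples; radicals as a sorted tuple.
    """

    doubly_occupied: frozenset[int]
    vacant: frozenset[int]
    pairs: frozenset[tuple[int, int]]
    unpaired: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "doubly_occupied", frozenset(int(i) for i in self.doubly_occupied))
        object.__setattr__(self, "vacant", frozenset(int(i) for i in self.vacant))
        norm_pairs = frozenset(tuple(sorted((int(a), int(b)))) for a, b in self.pairs)
        object.__setattr__(self, "pairs", norm_pairs)
        object.__setattr__(self, "unpaired", tuple(sorted(int(i) for i in self.unpaired)))
        paired: list[int] = [i for p in norm_pairs for i in p]
        if len(paired) != len(set(paired)):
            raise ValueError("an orbital appears in two singlet pairs")
        groups = [self.doubly_occupied, self.vacant, set(paired), set(self.unpaired)]
        if len(self.unpaired) != len(set(self.unpaired)):
            raise ValueError("duplicate radical orbital")
        total = sum(len(g) for g in groups)
        if len(frozenset().union(*groups)) != total:
            raise ValueError("orbital groups of a structure must be pairwise disjoint")

    @property
    def singly_occupied(self) -> frozenset[int]:
        return frozenset(i for p in self.pairs for i in p) | frozenset(self.unpaired)

    @property
    def n_electrons(self) -> int:
        return 2 * len(self.doubly_occupied) + 2 * len(self.pairs) + len(self.unpaired)

    @property
    def subspace_key(self) -> "SubspaceKey":
        return SubspaceKey(self.doubly_occupied, self.vacant)

    @property
    def sort_key(self) -> tuple:
        """Canonical ordering key: (subspace, pairs, radicals)."""
        return (
            tuple(sorted(self.doubly_occupied)),
            tuple(sorted(self.vacant)),
            tuple(sorted(self.pairs)),
            self.unpaired,
        )

    def validate_against(self, space: "ActiveSpace") -> None:
        """Check the structure's invariants relative to a parent space."""
        all_orbitals = self.doubly_occupied | self.vacant | self.singly_occupied
        if all_orbitals != frozenset(space.indices):
            missing = sorted(frozenset(space.indices) ^ all_orbitals)
            raise ValueError(f"structure does not cover the space's orbitals: {missing}")
        if self.n_electrons != space.n_electrons:
            raise ValueError(
                f"structure holds {self.n_electrons} electrons, space has {space.n_electrons}"
            )
        if len(self.unpaired) != space.twice_spin:
            raise ValueError(
                f"structure has {len(self.unpaired)} radicals, need 2S = {space.twice_spin}"
            )


@dataclass(frozen=True)
class SubspaceKey:
    """A placement of lone pairs and vacant orbitals, fixing one subspace."""

    doubly_occupied: frozenset[int]
    vacant: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "doubly_occupied", frozenset(int(i) for i in self.doubly_occupied))
        object.__setattr__(self, "vacant", frozenset(int(i) for i in self.vacant))
        if self.doubly_occupied & self.vacant:
            raise ValueError("a subspace orbital cannot be both doubly occupied and vacant")

    @property
    def sort_key(self) -> tuple:
        return (tuple(sorted(self.doubly_occupied)), tuple(sorted(self.vacant)))

    def singly_occupied(self, space: "ActiveSpace") -> tuple[int, ...]:
        """Singly occupied orbitals of this subspace, ascending."""
        return tuple(
            i for i in space.indices if i not in self.doubly_occupied and i not in self.vacant
        )


@dataclass(frozen=True)
class ActiveSpace:
    """An n-orbital / n_electron / spin-S problem definition.

    ``twice_spin`` stores 2S as an integer (half-integer spins are exact).
    ``inactive_orbitals`` is cosmetic metadata used only by the occupancy
    notation writer (orbitals outside the active space that are always
    doubly occupied).
    """

    orbitals: tuple[OrbitalInfo, ...]
    n_electrons: int
    twice_spin: int
    inactive_orbitals: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "orbitals", tuple(self.orbitals))
        object.__setattr__(self, "inactive_orbitals", tuple(self.inactive_orbitals))
        indices = [o.index for o in self.orbitals]
        if len(set(indices)) != len(indices):
            raise ValueError("orbital indices must be unique")
        if self.twice_spin < 0:
            raise ValueError("2S must be non-negative")
        if not 0 <= self.n_electrons <= 2 * self.n:
            raise ValueError(
                f"n_electrons={self.n_electrons} outside [0, {2 * self.n}] for n={self.n}"
            )
        if not valid_double_counts(self.n, self.n_electrons, self.twice_spin):
            raise EmptySpaceError(
                f"empty space: no occupancy pattern with n={self.n}, "
                f"n_electrons={self.n_electrons}, 2S={self.twice_spin} "
                "(spin too high or parity mismatch)"
            )

    @property
    def n(self) -> int:
        return len(self.orbitals)

    @property
    def total_spin(self) -> float:
        return self.twice_spin / 2.0

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(sorted(o.index for o in self.orbitals))

    def orbital(self, index: int) -> OrbitalInfo:
        for o in self.orbitals:
            if o.index == index:
                return o
        raise KeyError(f"no orbital with index {index}")

    @property
    def atom_map(self) -> dict[int, str]:
        return {o.index: o.atom_id for o in self.orbitals}

    @property
    def symmetry_map(self) -> dict[int, str | None]:
        return {o.index: o.symmetry_label for o in self.orbitals}

    @classmethod
    def create(
        cls,
        orbitals: Iterable[OrbitalInfo],
        n_electrons: int,
        spin: float,
        inactive_orbitals: Iterable[int] = (),
    ) -> "ActiveSpace":
        """Build a space from a half-integer spin S."""
        return cls(tuple(orbitals), n_electrons, twice_spin(spin), tuple(inactive_orbitals))


def valid_double_counts(n: int, n_electrons: int, twice_s: int) -> list[int]:
    """All lone-pair counts d compatible with the space's invariants.

    For each d, N = n_electrons - 2d orbitals are singly occupied and
    v = n - d - N are vacant; requires N >= 2S, v >= 0 and N = 2S (mod 2).
    """
    if (n_electrons - twice_s) % 2 != 0:
        return []
    out = []
    for d in range(0, n_electrons // 2 + 1):
        big_n = n_electrons - 2 * d
        v = n - d - big_n
        if big_n >= twice_s and v >= 0:
            out.append(d)
    return out


def n_pair_groupings(big_n: int, twice_s: int) -> int:
    """Number of ways to split N singly occupied orbitals into (N-2S)/2 pairs.

    N! / (2^p p! (2S)!) with p = (N - 2S)/2: choose disjoint pairs, the
    remaining 2S orbitals carry the unpaired (radical) electrons.
    """
    if big_n < twice_s or (big_n - twice_s) % 2 != 0:
        raise ValueError(f"invalid N={big_n} for 2S={twice_s}")
    p = (big_n - twice_s) // 2
    return math.factorial(big_n) // (2**p * math.factorial(p) * math.factorial(twice_s))


def count_total_structures(
    n: int, n_electrons: int, spin: float, n_double: int | None = None
) -> int:
    """Closed-form count of all spin-coupling structures of a space.

    Sums, over every valid lone-pair count d (or only ``n_double`` if given),
    the number of occupancy placements multinomial(n; d, v, N) times the
    number of pair groupings of the N singly occupied orbitals.  Equals
    ``len(enumerate_structures(...))``; the enumeration is the ground truth.
    """
    twice_s = twice_spin(spin)
    ds = valid_double_counts(n, n_electrons, twice_s)
    if not ds:
        raise EmptySpaceError(
            f"empty space: n={n}, n_electrons={n_electrons}, S={spin} admits no structure"
        )
    if n_double is not None:
        if n_double not in ds:
            raise EmptySpaceError(
                f"no structures with {n_double} lone pairs for n={n}, "
                f"n_electrons={n_electrons}, S={spin}"
            )
        ds = [n_double]
    total = 0
    for d in ds:
        big_n = n_electrons - 2 * d
        v = n - d - big_n
        placements = math.comb(n, d) * math.comb(n - d, v)
        total += placements * n_pair_groupings(big_n, twice_s)
    return total


def _couplings(
    elems: tuple[int, ...], n_pairs: int
) -> Iterator[tuple[tuple[tuple[int, int], ...], tuple[int, ...]]]:
    """Yield all (pairs, radicals) splittings of ``elems`` into n_pairs pairs."""
    if not elems:
        yield (), ()
        return
    a, rest = elems[0], elems[1:]
    if len(elems) - 2 * n_pairs > 0:  # a may stay unpaired
        for ps, us in _couplings(rest, n_pairs):
            yield ps, (a,) + us
    if n_pairs > 0:
        for i, b in enumerate(rest):
            remaining = rest[:i] + rest[i + 1 :]
            for ps, us in _couplings(remaining, n_pairs - 1):
                yield ((a, b),) + ps, us


def _subspace_structures(space: ActiveSpace, key: SubspaceKey) -> list[VBStructure]:
    singles = key.singly_occupied(space)
    big_n = len(singles)
    if 2 * len(key.doubly_occupied) + big_n != space.n_electrons:
        raise ValueError(
            f"subspace {key.sort_key} holds {2 * len(key.doubly_occupied) + big_n} "
            f"electrons, space has {space.n_electrons}"
        )
    if big_n < space.twice_spin or (big_n - space.twice_spin) % 2 != 0:
        raise ValueError(
            f"subspace {key.sort_key}: {big_n} singly occupied orbitals cannot "
            f"realize 2S = {space.twice_spin}"
        )
    n_pairs = (big_n - space.twice_spin) // 2
    out = [
        VBStructure(key.doubly_occupied, key.vacant, frozenset(ps), us)
        for ps, us in _couplings(singles, n_pairs)
    ]
    out.sort(key=lambda s: s.sort_key)
    return out


def enumerate_structures(
    space: ActiveSpace,
    subspace: SubspaceKey | None = None,
    n_double: int | None = None,
) -> list[VBStructure]:
    """Exhaustively enumerate structures, in canonical order.

    With ``subspace`` given, only that lone-pair/vacant placement is expanded.
    With ``n_double`` given, only occupancy patterns with that many lone pairs
    are considered.  Without either, every valid occupancy pattern is covered.
    """
    if subspace is not None:
        known = set(space.indices)
        for i in subspace.doubly_occupied | subspace.vacant:
            if i not in known:
                raise ValueError(f"subspace references unknown orbital {i}")
        return _subspace_structures(space, subspace)

    ds = valid_double_counts(space.n, space.n_electrons, space.twice_spin)
    if n_double is not None:
        if n_double not in ds:
            raise EmptySpaceError(
                f"no structures with {n_double} lone pairs in this space"
            )
        ds = [n_double]
    indices = space.indices
    out: list[VBStructure] = []
    for d in ds:
        big_n = space.n_electrons - 2 * d
        v = space.n - d - big_n
        for doubly in itertools.combinations(indices, d):
            rest = tuple(i for i in indices if i not in doubly)
            for vac in itertools.combinations(rest, v):
                key = SubspaceKey(frozenset(doubly), frozenset(vac))
                out.extend(_subspace_structures(space, key))
    out.sort(key=lambda s: s.sort_key)
    return out


def group_by_subspace(
    structures: Iterable[VBStructure],
) -> dict[SubspaceKey, list[VBStructure]]:
    """Partition structures by lone-pair/vacant placement (insertion order kept)."""
    groups: dict[SubspaceKey, list[VBStructure]] = {}
    for s in structures:
        groups.setdefault(s.subspace_key, []).append(s)
    return groups


def covalent_subspaces(space: ActiveSpace) -> list[SubspaceKey]:
    """Subspaces of the reference (covalent) occupancy.

    All non-singly-occupied orbitals are lone pairs when n_electrons > n,
    vacant when n_electrons < n; there are C(n, n - N) such placements.
    """
    d = max(0, space.n_electrons - space.n)
    if d not in valid_double_counts(space.n, space.n_electrons, space.twice_spin):
        raise EmptySpaceError(
            f"no covalent occupancy for n={space.n}, n_electrons={space.n_electrons}, "
            f"2S={space.twice_spin}"
        )
    big_n = space.n_electrons - 2 * d
    v = space.n - d - big_n
    indices = space.indices
    keys: list[SubspaceKey] = []
    for doubly in itertools.combinations(indices, d):
        rest = tuple(i for i in indices if i not in doubly)
        for vac in itertools.combinations(rest, v):
            keys.append(SubspaceKey(frozenset(doubly), frozenset(vac)))
    keys.sort(key=lambda k: k.sort_key)
    return keys


def canonical_sort(structures: Iterable[VBStructure]) -> list[VBStructure]:
    """Sort structures into the canonical deterministic order."""
    return sorted(structures, key=lambda s: s.sort_key)
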