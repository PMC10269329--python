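"""Rumer pictorial rules and Rumer-set combinatorics.

Singly occupied orbitals are placed on an imaginary circle in a chosen
order; one dummy center per unpaired electron is appended after the last
real orbital.  A structure is allowed when none of its chords cross, where
chords are the real singlet bonds plus one radical-to-dummy chord per
unpaired electron; dummy-dummy bonds are forbidden.  The allowed structures
of an ordering form a complete linearly independent set.

Distinct sets over all orderings are obtained by brute-force enumeration
with deduplication; the closed-form count N!/(2r) serves as a test oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .spin_algebra import DEFAULT_THRESHOLD, StructureSet
from .vb_space import ActiveSpace, SubspaceKey, VBStructure, enumerate_structures

__all__ = [
    "RumerOrdering",
    "is_noncrossing",
    "generate_rumer_set",
    "count_distinct_bonds",
    "count_rumer_sets",
    "iter_orderings",
    "enumerate_distinct_rumer_sets",
]

#: Enumerating all N! orderings is kept below this many real orbitals.
MAX_ENUMERATION_ORBITALS = 10


@dataclass(frozen=True)
class RumerOrdering:
    """An arrangement of the real orbitals around the Rumer circle.

    ``dummy_count`` (= 2S) dummy centers occupy the positions following the
    last real orbital, in sequential order; bonds between dummy centers are
    never formed.
    """

    cycle: tuple[int, ...]
    dummy_count: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cycle", tuple(int(i) for i in self.cycle))
        if len(set(self.cycle)) != len(self.cycle):
            raise ValueError("ordering must list each orbital exactly once")
        if self.dummy_count < 0:
            raise ValueError("dummy_count must be non-negative")

    @classmethod
    def sequential(cls, orbitals: Iterable[int], dummy_count: int = 0) -> "RumerOrdering":
        """Ascending-index ordering (the paper's default numbering)."""
        return cls(tuple(sorted(orbitals)), dummy_count)


def _chords(structure: VBStructure, ordering: RumerOrdering) -> list[tuple[int, int]]:
    """Circle chords of a structure: real bonds plus radical-dummy chords.

    Radicals are matched to the trailing dummy positions in the only
    mutually non-crossing way (ascending radical position <-> descending
    dummy position); any other matching crosses within itself, so it can be
    assumed without loss of generality.
    """
    pos = {o: i for i, o in enumerate(ordering.cycle)}
    missing = [o for o in structure.singly_occupied if o not in pos]
    if missing or len(ordering.cycle) != len(structure.singly_occupied):
        raise ValueError(
            f"ordering {ordering.cycle} does not match the structure's singly "
            f"occupied orbitals {tuple(sorted(structure.singly_occupied))}"
        )
    if len(structure.unpaired) != ordering.dummy_count:
        raise ValueError(
            f"structure has {len(structure.unpaired)} radicals but ordering "
            f"provides {ordering.dummy_count} dummy centers"
        )
    chords = [tuple(sorted((pos[a], pos[b]))) for a, b in structure.pairs]
    n_real = len(ordering.cycle)
    total = n_real + ordering.dummy_count
    for k, p in enumerate(sorted(pos[r] for r in structure.unpaired)):
        chords.append((p, total - 1 - k))
    return chords


def _cross(c1: tuple[int, int], c2: tuple[int, int]) -> bool:
    # endpoints sorted; chords cross iff exactly one endpoint of c2 is inside c1
    a, b = c1
    c, d = c2
    return (a < c < b) != (a < d < b)


def is_noncrossing(structure: VBStructure, ordering: RumerOrdering) -> bool:
    """True iff no two chords of the structure interleave on the circle."""
    chords = _chords(structure, ordering)
    return not any(
        _cross(c1, c2) for c1, c2 in itertools.combinations(chords, 2)
    )


def generate_rumer_set(
    space: ActiveSpace,
    ordering: RumerOrdering,
    subspace: SubspaceKey | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> StructureSet:
    """All non-crossing structures of one subspace under one ordering.

    The result is a complete linearly independent set: its size equals the
    branching-diagram count and it passes the Gramian test.
    """
    if subspace is None:
        subspace = SubspaceKey(frozenset(), frozenset())
    candidates = enumerate_structures(space, subspace)
    allowed = [s for s in candidates if is_noncrossing(s, ordering)]
    return StructureSet(allowed, subspace, ["rumer"] * len(allowed), threshold)


def count_distinct_bonds(structures: Iterable[VBStructure] | StructureSet) -> int:
    """Number of distinct real-orbital singlet bonds appearing across a set."""
    bonds: set[tuple[int, int]] = set()
    empty = True
    for s in structures:
        empty = False
        bonds.update(s.pairs)
    if empty:
        raise ValueError("cannot count bonds of an empty set")
    return len(bonds)


def count_rumer_sets(big_n: int, r: int) -> int:
    """Closed-form number of distinct Rumer sets: N!/(2r).

    ``r`` is the rotation order of the Rumer cycle's principal axis for even
    N, and 1 for odd N.  Multiply by C(n, n - N) when (n - N) lone pairs or
    vacant orbitals can be placed.  The degenerate N = 2 cycle (where the
    reflection coincides with the rotation) is clamped to the one existing
    set.
    """
    if big_n < 2:
        raise ValueError("need at least two orbitals on the circle")
    if r < 1:
        raise ValueError("rotation order must be at least 1")
    return max(1, math.factorial(big_n) // (2 * r))


def _noncrossing_position_matchings(
    n_real: int, n_dummy: int
) -> list[tuple[tuple[tuple[int, int], ...], tuple[int, ...]]]:
    """Non-crossing perfect matchings of circle positions, no dummy-dummy bonds.

    Positions 0..n_real-1 are real, the rest dummies.  Returns, per matching,
    the real-real position pairs and the radical positions (real positions
    bonded to a dummy) ordered by ascending dummy position.
    """
    total = n_real + n_dummy

    # pairing the first point with an odd-offset partner splits the circle into
    # two even arcs; recursing on each yields exactly the non-crossing matchings
    def matchings(points: tuple[int, ...]) -> Iterator[tuple[tuple[int, int], ...]]:
        if not points:
            yield ()
            return
        first = points[0]
        for i in range(1, len(points), 2):
            partner = points[i]
            inside = points[1:i]
            outside = points[i + 1 :]
            for m_in in matchings(inside):
                for m_out in matchings(outside):
                    yield ((first, partner),) + m_in + m_out

    results: list[tuple[tuple[tuple[int, int], ...], tuple[int, ...]]] = []
    for m in matchings(tuple(range(total))):
        pairs = []
        rad_by_dummy: dict[int, int] = {}
        ok = True
        for a, b in m:
            a_real, b_real = a < n_real, b < n_real
            if a_real and b_real:
                pairs.append((a, b))
            elif a_real or b_real:
                dummy, real = (b, a) if b >= n_real else (a, b)
                rad_by_dummy[dummy] = real
            else:
                ok = False
                break
        if ok:
            radicals = tuple(rad_by_dummy[d] for d in sorted(rad_by_dummy))
            results.append((tuple(pairs), radicals))
    return results


def iter_orderings(orbitals: Iterable[int]) -> Iterator[tuple[int, ...]]:
    """All orderings (permutations) of the given orbitals around the circle."""
    return itertools.permutations(sorted(orbitals))


def enumerate_distinct_rumer_sets(
    space: ActiveSpace,
    subspace: SubspaceKey | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[StructureSet]:
    """All distinct Rumer sets of one subspace, over every orbital ordering.

    Every N! ordering is expanded and the resulting structure sets are
    deduplicated by set identity (orderings related by rotation or
    reflection collapse automatically).  Guarded to N <= 10 real orbitals;
    beyond that, sample orderings with :func:`generate_rumer_set` instead.
    """
    if subspace is None:
        subspace = SubspaceKey(frozenset(), frozenset())
    singles = subspace.singly_occupied(space)
    big_n = len(singles)
    if big_n > MAX_ENUMERATION_ORBITALS:
        raise ValueError(
            f"N={big_n} orderings ({math.factorial(big_n)}) exceed the enumeration "
            f"guard ({MAX_ENUMERATION_ORBITALS} orbitals); sample orderings with "
            "generate_rumer_set instead"
        )
    n_dummy = space.twice_spin
    position_sets = _noncrossing_position_matchings(big_n, n_dummy)

    seen: dict[frozenset, tuple[tuple[int, ...], ...]] = {}
    order_of: dict[frozenset, int] = {}
    for perm in iter_orderings(singles):
        encoded = []
        for pairs, radicals in position_sets:
            bond_key = tuple(
                sorted(
                    (perm[a], perm[b]) if perm[a] < perm[b] else (perm[b], perm[a])
                    for a, b in pairs
                )
            )
            rad_key = tuple(sorted(perm[p] for p in radicals))
            encoded.append((bond_key, rad_key))
        key = frozenset(encoded)
        if key not in seen:
            seen[key] = tuple(sorted(encoded))
            order_of[key] = len(order_of)

    sets: list[StructureSet] = []
    for key, encoded in sorted(seen.items(), key=lambda kv: kv[1]):
        members = [
            VBStructure(
                subspace.doubly_occupied,
                subspace.vacant,
                frozenset(bond_key),
                rad_key,
            )
            for bond_key, rad_key in encoded
        ]
        sets.append(StructureSet(members, subspace, ["rumer"] * len(members), threshold))
    return sets
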