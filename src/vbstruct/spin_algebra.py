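"""Determinant expansions, Gramians, independence counting and structure weights.

Each structure is expanded at the highest spin projection (M_S = S) as a
signed sum of spin-orbital determinants: every singlet pair (a, b)
contributes a factor (a-up b-down - a-down b-up) and every radical is
assigned an up spin.  Structures of one subspace share a determinant basis,
so a structure becomes a vector of +/-1 coefficients and linear independence
reduces to the invertibility of the Gramian of the unit-normalized vectors.

Vectors are unit-normalized before the Gramian is formed so that the
eigenvalue threshold (default 1e-11) is scale-free; this normalization is a
convention of this implementation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np

from .vb_space import SubspaceKey, VBStructure

__all__ = [
    "DeterminantExpansion",
    "GramianReport",
    "StructureSet",
    "expand_structure",
    "structure_overlap",
    "normalized_overlap",
    "gramian",
    "count_independent",
    "chirgwin_coulson_weights",
]

#: Default Gramian eigenvalue threshold for the independence verdict.
DEFAULT_THRESHOLD = 1e-11

ALPHA = "a"
BETA = "b"


@dataclass(frozen=True, eq=True)
class DeterminantExpansion:
    """A structure as a signed combination of spin-orbital determinants.

    ``orbitals`` lists the singly occupied orbitals in determinant column
    order; ``terms`` maps a spin assignment (one 'a'/'b' per column) to its
    +/-1 coefficient.  Doubly occupied orbitals contribute a fixed
    alpha-beta factor and are not part of the key.
    """

    orbitals: tuple[int, ...]
    terms: Mapping[tuple[str, ...], int]

    __hash__ = None  # terms is a dict

    @property
    def norm(self) -> float:
        return math.sqrt(sum(c * c for c in self.terms.values()))


def expand_structure(
    structure: VBStructure, orbital_order: Sequence[int] | None = None
) -> DeterminantExpansion:
    """Expand a structure over spin-orbital determinants at M_S = S.

    ``orbital_order`` fixes the determinant column order (a permutation of at
    least the singly occupied orbitals); default is ascending index order.
    Pair factors are multiplied in ascending order of their smaller index --
    a consistent convention: any other one flips at most the overall sign of
    the vector, which never affects independence or eigenvalue magnitudes.
    """
    singles = structure.singly_occupied
    if orbital_order is None:
        columns = tuple(sorted(singles))
    else:
        columns = tuple(o for o in orbital_order if o in singles)
        if set(columns) != singles or len(columns) != len(singles):
            raise ValueError("orbital_order must contain each singly occupied orbital once")
    col_of = {o: i for i, o in enumerate(columns)}
    pairs = sorted(structure.pairs)
    base = [ALPHA] * len(columns)  # radicals are up-spin at M_S = S
    terms: dict[tuple[str, ...], int] = {}
    for choice in itertools.product((0, 1), repeat=len(pairs)):
        spins = base[:]
        sign = 1
        for flip, (a, b) in zip(choice, pairs):
            if flip:
                spins[col_of[a]] = BETA
                sign = -sign
            else:
                spins[col_of[b]] = BETA
        terms[tuple(spins)] = sign
    return DeterminantExpansion(columns, terms)


def structure_overlap(e1: DeterminantExpansion, e2: DeterminantExpansion) -> int:
    """Raw inner product of two expansions (sum of coefficient products)."""
    if e1.orbitals != e2.orbitals:
        raise ValueError(
            f"expansions live on different determinant bases: "
            f"{e1.orbitals} vs {e2.orbitals}"
        )
    if len(e1.terms) > len(e2.terms):
        e1, e2 = e2, e1
    return sum(c * e2.terms.get(key, 0) for key, c in e1.terms.items())


def normalized_overlap(e1: DeterminantExpansion, e2: DeterminantExpansion) -> float:
    """Inner product of the unit-normalized structure vectors."""
    return structure_overlap(e1, e2) / (e1.norm * e2.norm)


@dataclass(frozen=True)
class GramianReport:
    """Gramian of a structure list with its independence verdict."""

    matrix: np.ndarray
    min_abs_eigenvalue: float
    threshold: float
    independent: bool

    __hash__ = None


def gramian(
    structures: Sequence[VBStructure],
    threshold: float = DEFAULT_THRESHOLD,
    orbital_order: Sequence[int] | None = None,
) -> GramianReport:
    """Gramian of unit-normalized structure vectors, with independence verdict.

    The set is declared independent iff every |eigenvalue| of the Gramian
    exceeds ``threshold``.  All structures must belong to one subspace (their
    determinant bases coincide); mixing subspaces is an error.
    """
    structures = list(structures)
    if not structures:
        raise ValueError("gramian needs at least one structure")
    key = structures[0].subspace_key
    for s in structures[1:]:
        if s.subspace_key != key:
            raise ValueError(
                "structures from different lone-pair/vacant subspaces have "
                "different determinant bases and cannot share a Gramian"
            )
    expansions = [expand_structure(s, orbital_order) for s in structures]
    m = len(expansions)
    g = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            g[i, j] = g[j, i] = normalized_overlap(expansions[i], expansions[j])
    eigenvalues = np.linalg.eigvalsh(g)
    min_abs = float(np.min(np.abs(eigenvalues)))
    return GramianReport(g, min_abs, threshold, min_abs > threshold)


def count_independent(big_n: int, spin: float) -> int:
    """Number of linearly independent spin structures for N singles at spin S.

    The branching-diagram count C(N, N/2 - S) - C(N, N/2 - S - 1).  For a
    space with n > N orbitals the caller multiplies by the C(n, n - N)
    lone-pair/vacant placements.
    """
    from .vb_space import twice_spin as _ts

    twice_s = _ts(spin)
    if big_n < twice_s:
        raise ValueError(f"N={big_n} cannot carry 2S={twice_s} unpaired electrons")
    if (big_n - twice_s) % 2 != 0:
        raise ValueError(f"N={big_n} and 2S={twice_s} have different parity")
    p = (big_n - twice_s) // 2
    return math.comb(big_n, p) - (math.comb(big_n, p - 1) if p >= 1 else 0)


def chirgwin_coulson_weights(
    coefficients: Sequence[float], overlaps: np.ndarray
) -> np.ndarray:
    """Chirgwin-Coulson weights W_i = c_i (S c)_i / (c^T S c).

    Normalized so the weights sum to 1; individual weights may be negative
    in non-orthogonal expansions.
    """
    c = np.asarray(coefficients, dtype=float).ravel()
    s = np.asarray(overlaps, dtype=float)
    if s.shape != (c.size, c.size):
        raise ValueError(f"overlap matrix {s.shape} does not match {c.size} coefficients")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("overlap matrix must be symmetric")
    sc = s @ c
    total = float(c @ sc)
    if total <= 0:
        raise ValueError(f"c^T S c = {total:g} is not positive; cannot normalize weights")
    return c * sc / total


class StructureSet:
    """An ordered, tagged collection of structures from one subspace.

    ``provenance`` carries one tag per structure ("pinned", "selected" or
    "rumer").  The Gramian report is computed lazily and cached.
    """

    def __init__(
        self,
        structures: Sequence[VBStructure],
        subspace: SubspaceKey,
        provenance: Sequence[str] | None = None,
        threshold: float = DEFAULT_THRESHOLD,
    ) -> None:
        self.structures: tuple[VBStructure, ...] = tuple(structures)
        self.subspace = subspace
        if provenance is None:
            provenance = ["selected"] * len(self.structures)
        if len(provenance) != len(self.structures):
            raise ValueError("one provenance tag per structure required")
        self.provenance: tuple[str, ...] = tuple(provenance)
        self.threshold = threshold
        for s in self.structures:
            if s.subspace_key != subspace:
                raise ValueError(f"structure {s.sort_key} is not in subspace {subspace.sort_key}")

    @cached_property
    def gramian(self) -> GramianReport:
        return gramian(self.structures, self.threshold)

    def as_frozenset(self) -> frozenset[VBStructure]:
        return frozenset(self.structures)

    def __len__(self) -> int:
        return len(self.structures)

    def __iter__(self):
        return iter(self.structures)

    def __contains__(self, item: VBStructure) -> bool:
        return item in self.structures

    def __eq__(self, other) -> bool:
        if not isinstance(other, StructureSet):
            return NotImplemented
        return self.as_frozenset() == other.as_frozenset()

    def __repr__(self) -> str:
        return (
            f"StructureSet({len(self.structures)} structures, "
            f"subspace={self.subspace.sort_key})"
        )
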