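"""Chemical-quality scoring of structures and lexicographic score merging.

Five criteria score each structure with a positive integer where 1 is best:
user-defined bonds, user-defined radicals, intra-atomic bonds, bond length
(a dense rank of a bond-stretch measure) and orbital symmetry.  Scores are
merged pairwise in priority order via

    S_new = (S_n - 1) * max(S_m) + S_m

which reproduces exactly the lexicographic order of the per-criterion score
tuples.

The user-facing criterion names are ``user_bonds``, ``user_radicals``,
``intra_atomic``, ``bond_length`` and ``symmetry``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

from .vb_space import ActiveSpace, VBStructure

__all__ = [
    "CRITERIA",
    "CriteriaConfig",
    "RankedStructure",
    "score_user_bonds",
    "score_user_radicals",
    "score_intra_atomic",
    "score_symmetry",
    "bond_stretch_measure",
    "rank_by_bond_length",
    "merge_scores",
    "rank_structures",
]

CRITERIA = ("user_bonds", "user_radicals", "intra_atomic", "bond_length", "symmetry")

#: Criteria absent from a config's priority order are simply not computed.
DEFAULT_PRIORITY = ("user_bonds", "user_radicals", "intra_atomic", "symmetry", "bond_length")

WILDCARD_SYMMETRY = "__any__"


class GeometryLike(Protocol):
    """What the bond-length criterion needs from a geometry."""

    def distance(self, atom_a: str, atom_b: str) -> float: ...

    def covalent_sum(self, atom_a: str, atom_b: str) -> float: ...


@dataclass(frozen=True)
class CriteriaConfig:
    """Which criteria to apply, in which priority, and the user's preferences."""

    priority_order: tuple[str, ...]
    user_bonds: frozenset[tuple[int, int]] = frozenset()
    user_radicals: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "priority_order", tuple(self.priority_order))
        object.__setattr__(
            self,
            "user_bonds",
            frozenset(tuple(sorted((int(a), int(b)))) for a, b in self.user_bonds),
        )
        object.__setattr__(self, "user_radicals", frozenset(int(i) for i in self.user_radicals))
        if not self.priority_order:
            raise ValueError("priority_order must name at least one criterion")
        if len(set(self.priority_order)) != len(self.priority_order):
            raise ValueError("priority_order contains duplicates")
        unknown = [c for c in self.priority_order if c not in CRITERIA]
        if unknown:
            raise ValueError(f"unknown criteria {unknown}; valid: {CRITERIA}")
        if "user_bonds" in self.priority_order and not self.user_bonds:
            raise ValueError("user_bonds criterion requires a non-empty bond list")
        if "user_radicals" in self.priority_order and not self.user_radicals:
            raise ValueError("user_radicals criterion requires a non-empty radical list")


@dataclass(frozen=True)
class RankedStructure:
    """A structure with its per-criterion scores and merged quality score."""

    structure: VBStructure
    scores: Mapping[str, int]
    unified: int
    d_nab: float | None = None

    __hash__ = None


def score_user_bonds(structure: VBStructure, udb: Iterable[tuple[int, int]]) -> int:
    """N_B - N_UDB + 1: equals 1 iff every bond of the structure is user-defined."""
    udb_set = frozenset(tuple(sorted(p)) for p in udb)
    if not udb_set:
        raise ValueError("user-defined bond list is empty")
    n_b = len(structure.pairs)
    n_udb = len(structure.pairs & udb_set)
    return n_b - n_udb + 1


def score_user_radicals(structure: VBStructure, udr: Iterable[int]) -> int:
    """N_R - N_UDR + 1 over the structure's unpaired orbitals."""
    udr_set = frozenset(udr)
    if not udr_set:
        raise ValueError("user-defined radical list is empty")
    n_r = len(structure.unpaired)
    n_udr = len(set(structure.unpaired) & udr_set)
    return n_r - n_udr + 1


def score_intra_atomic(structure: VBStructure, atom_map: Mapping[int, str]) -> int:
    """N_IAB + 1, counting bonds whose two orbitals share an atom."""
    n_iab = sum(1 for a, b in structure.pairs if atom_map[a] == atom_map[b])
    return n_iab + 1


def score_symmetry(structure: VBStructure, labels: Mapping[int, str | None]) -> int:
    """N_SBB + 1, counting bonds between orbitals of different symmetry labels.

    Unlabeled orbitals share one wildcard label: same-symmetry with each
    other, different from any explicit label.
    """

    def label(i: int) -> str:
        value = labels.get(i)
        return WILDCARD_SYMMETRY if value is None else value

    n_sbb = sum(1 for a, b in structure.pairs if label(a) != label(b))
    return n_sbb + 1


def bond_stretch_measure(
    structure: VBStructure,
    geometry: GeometryLike,
    atom_map: Mapping[int, str],
) -> float:
    """D_NAB: summed relative stretch of the structure's inter-atomic bonds.

    Each bond between orbitals on atoms A, B contributes
    max(0, R(AB) - Rcov(AB)) / Rcov(AB); neighboring-atom bonds
    (R <= Rcov) and intra-atomic bonds contribute zero.  Only the induced
    ranking is consumed downstream.
    """
    total = 0.0
    for a, b in structure.pairs:
        atom_a, atom_b = atom_map[a], atom_map[b]
        if atom_a == atom_b:
            continue
        r = geometry.distance(atom_a, atom_b)
        r_cov = geometry.covalent_sum(atom_a, atom_b)
        total += max(0.0, r - r_cov) / r_cov
    return total


def rank_by_bond_length(
    structures: Sequence[VBStructure],
    geometry: GeometryLike,
    atom_map: Mapping[int, str],
) -> dict[VBStructure, int]:
    """Dense rank (1 = shortest bonds) of structures by their D_NAB measure.

    Ties share a rank so the score never depends on input order.
    """
    measures = {
        s: round(bond_stretch_measure(s, geometry, atom_map), 12) for s in structures
    }
    ordered = sorted(set(measures.values()))
    rank_of = {value: i + 1 for i, value in enumerate(ordered)}
    return {s: rank_of[m] for s, m in measures.items()}


def merge_scores(score_lists: Sequence[Sequence[int]]) -> list[int]:
    """Fold per-criterion scores into one vector, highest priority first.

    The resulting total order equals the lexicographic order of the score
    tuples.
    """
    if not score_lists:
        raise ValueError("need at least one score vector")
    length = len(score_lists[0])
    for vec in score_lists:
        if len(vec) != length:
            raise ValueError("score vectors must all have the same length")
        if any(s < 1 for s in vec):
            raise ValueError("scores must be >= 1")
    unified = list(score_lists[0])
    for nxt in score_lists[1:]:
        peak = max(nxt)
        unified = [(sn - 1) * peak + sm for sn, sm in zip(unified, nxt)]
    return unified


def rank_structures(
    space: ActiveSpace,
    structures: Sequence[VBStructure],
    config: CriteriaConfig,
    geometry: GeometryLike | None = None,
) -> list[RankedStructure]:
    """Score every structure by the configured criteria and merge the ranks.

    Output order follows the input order; selection sorts by the unified
    score itself.
    """
    structures = list(structures)
    if not structures:
        return []
    atom_map = space.atom_map
    vectors: list[list[int]] = []
    per_criterion: dict[str, list[int]] = {}
    d_nab: dict[VBStructure, float] | None = None
    for criterion in config.priority_order:
        if criterion == "user_bonds":
            vec = [score_user_bonds(s, config.user_bonds) for s in structures]
        elif criterion == "user_radicals":
            vec = [score_user_radicals(s, config.user_radicals) for s in structures]
        elif criterion == "intra_atomic":
            vec = [score_intra_atomic(s, atom_map) for s in structures]
        elif criterion == "symmetry":
            vec = [score_symmetry(s, space.symmetry_map) for s in structures]
        elif criterion == "bond_length":
            if geometry is None:
                raise ValueError("bond_length criterion requires a geometry")
            ranks = rank_by_bond_length(structures, geometry, atom_map)
            d_nab = {
                s: bond_stretch_measure(s, geometry, atom_map) for s in structures
            }
            vec = [ranks[s] for s in structures]
        else:  # pragma: no cover - CriteriaConfig already validates
            raise ValueError(f"unknown criterion {criterion!r}")
        per_criterion[criterion] = vec
        vectors.append(vec)
    unified = merge_scores(vectors)
    out = []
    for i, s in enumerate(structures):
        out.append(
            RankedStructure(
                structure=s,
                scores={c: per_criterion[c][i] for c in config.priority_order},
                unified=unified[i],
                d_nab=None if d_nab is None else d_nab[s],
            )
        )
    return out
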