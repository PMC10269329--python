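"""Greedy selection of a complete, independent, highest-quality structure set.

Candidates of one subspace are sorted by their unified quality score (ties
broken by the canonical structure order) and added greedily; a candidate is
rejected when adding it drops the Gramian's smallest |eigenvalue| to or
below the threshold.  User-pinned structures are placed first and the
remaining slots are filled from the globally sorted list.  Selection stops
once the branching-diagram count of independent structures is reached.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .ranking import CriteriaConfig, GeometryLike, rank_structures
from .spin_algebra import (
    DEFAULT_THRESHOLD,
    StructureSet,
    count_independent,
    gramian,
)
from .vb_space import (
    ActiveSpace,
    SubspaceKey,
    VBStructure,
    covalent_subspaces,
    enumerate_structures,
)

__all__ = ["StructureSet", "select_insightful_set", "select_all_subspaces"]

logger = logging.getLogger(__name__)


def _check_pinned(
    pinned: Sequence[VBStructure],
    subspace: SubspaceKey,
    space: ActiveSpace,
    threshold: float,
) -> None:
    for s in pinned:
        s.validate_against(space)
        if s.subspace_key != subspace:
            raise ValueError(
                f"pinned structure {s.sort_key} is not in subspace {subspace.sort_key}"
            )
    if len(set(pinned)) != len(pinned):
        raise ValueError("pinned structures contain duplicates")
    if len(pinned) >= 2:
        report = gramian(pinned, threshold)
        if not report.independent:
            keys = [s.sort_key for s in pinned]
            raise ValueError(
                f"pinned structures are linearly dependent "
                f"(min |eigenvalue| {report.min_abs_eigenvalue:.3e} <= {threshold:g}): {keys}"
            )


def select_insightful_set(
    space: ActiveSpace,
    subspace: SubspaceKey | None = None,
    config: CriteriaConfig | None = None,
    geometry: GeometryLike | None = None,
    pinned: Sequence[VBStructure] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> StructureSet:
    """Select a complete independent set of best-ranked structures.

    Pinned structures appear first (provenance ``"pinned"``); the rest are
    filled greedily from the score-sorted candidate list (provenance
    ``"selected"``).  The result always contains exactly the
    branching-diagram number of structures and passes the Gramian test.
    """
    if subspace is None:
        subspace = SubspaceKey(frozenset(), frozenset())
    if config is None:
        raise ValueError("a CriteriaConfig is required")
    pinned = list(pinned or [])
    _check_pinned(pinned, subspace, space, threshold)

    candidates = enumerate_structures(space, subspace)
    big_n = len(subspace.singly_occupied(space))
    target = count_independent(big_n, space.twice_spin / 2.0)
    if len(pinned) > target:
        raise ValueError(f"{len(pinned)} pinned structures exceed the set size {target}")

    ranked = rank_structures(space, candidates, config, geometry)
    order = sorted(range(len(candidates)), key=lambda i: (ranked[i].unified, i))
    logger.info(
        "subspace %s: %d candidates, target set size %d, %d pinned",
        subspace.sort_key,
        len(candidates),
        target,
        len(pinned),
    )

    chosen: list[VBStructure] = list(pinned)
    provenance: list[str] = ["pinned"] * len(pinned)
    rejected = 0
    for i in order:
        if len(chosen) == target:
            break
        candidate = candidates[i]
        if candidate in chosen:
            continue
        report = gramian(chosen + [candidate], threshold)
        if report.independent:
            chosen.append(candidate)
            provenance.append("selected")
        else:
            rejected += 1
            logger.debug(
                "rejected dependent candidate %s (min |eig| %.3e)",
                candidate.sort_key,
                report.min_abs_eigenvalue,
            )
    # the HLSP candidates always span the subspace, so the greedy scan
    # cannot run out before reaching the target for a valid space
    assert len(chosen) == target, "exhausted candidates before completing the set"
    result = StructureSet(chosen, subspace, provenance, threshold)
    logger.info(
        "subspace %s: selected %d structures (%d dependent candidates rejected), "
        "min |eigenvalue| %.3e",
        subspace.sort_key,
        len(chosen),
        rejected,
        result.gramian.min_abs_eigenvalue,
    )
    return result


def select_all_subspaces(
    space: ActiveSpace,
    config: CriteriaConfig,
    geometry: GeometryLike | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    subspaces: Sequence[SubspaceKey] | None = None,
) -> dict[SubspaceKey, StructureSet]:
    """Run the selection separately in every (by default covalent) subspace.

    The union of the returned sets has C(n, n - N) x N_IS structures.
    """
    if subspaces is None:
        subspaces = covalent_subspaces(space)
    return {
        key: select_insightful_set(
            space, key, config, geometry=geometry, threshold=threshold
        )
        for key in subspaces
    }
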