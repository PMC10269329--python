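import itertools

import pytest

from vbstruct.io_cli import builtin_system
from vbstruct.vb_space import ActiveSpace, OrbitalInfo


@pytest.fixture(scope="session")
def c5h5():
    return builtin_system("c5h5")


@pytest.fixture(scope="session")
def h_oh_ts():
    return builtin_system("h_oh_ts")


@pytest.fixture(scope="session")
def hnc_ts():
    return builtin_system("hnc_ts")


@pytest.fixture(scope="session")
def c2():
    return builtin_system("c2")


def make_space(n, n_electrons, spin, inactive=()):
    """A bare space with one orbital per pseudo-atom (no chemistry metadata)."""
    return ActiveSpace.create(
        [OrbitalInfo(i, f"A{i}") for i in range(1, n + 1)], n_electrons, spin, inactive
    )


# ---------------------------------------------------------------------------
# Independent brute-force oracle used by several test modules: enumerate every
# structure of a space by raw iteration over occupancies, radicals and
# pairings, with no reference to the package's enumeration code.

def oracle_structures(n, n_electrons, twice_s, n_double=None):
    orbitals = tuple(range(1, n + 1))
    out = set()
    for d in range(0, n_electrons // 2 + 1):
        if n_double is not None and d != n_double:
            continue
        big_n = n_electrons - 2 * d
        v = n - d - big_n
        if big_n < twice_s or v < 0 or (big_n - twice_s) % 2 != 0:
            continue
        for doubly in itertools.combinations(orbitals, d):
            rest = [o for o in orbitals if o not in doubly]
            for vac in itertools.combinations(rest, v):
                singles = tuple(o for o in rest if o not in vac)
                for unpaired in itertools.combinations(singles, twice_s):
                    to_pair = [o for o in singles if o not in unpaired]
                    for matching in oracle_matchings(tuple(to_pair)):
                        out.add((frozenset(doubly), frozenset(vac),
                                 frozenset(matching), tuple(sorted(unpaired))))
    return out


def oracle_matchings(elems):
    """All perfect matchings of an even-sized tuple, as frozensets of pairs."""
    if not elems:
        yield ()
        return
    a = elems[0]
    for i in range(1, len(elems)):
        b = elems[i]
        rest = elems[1:i] + elems[i + 1 :]
        for sub in oracle_matchings(rest):
            yield ((a, b),) + sub
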