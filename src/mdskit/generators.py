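"""Constructions of specific decycling / PCR sets.

The main construction embeds each k-mer into the complex plane through the
weight W(u) = sum_j u_{j+1} * omega^j with omega = exp(2*pi*i/k).  A left
rotation multiplies W by omega^(-1), so |W| is constant on a rotation orbit
and the k rotations of a full-period orbit occupy k evenly spaced arguments:
exactly one falls in the half-open sector [-2*pi/k, 0).  Picking that
rotation for every nonzero-weight orbit, and completing the zero-weight
orbits (homopolymers and all shorter-period orbits among them) by
lexicographic backtracking until the whole set decycles, yields a minimum
decycling set.  The result is verified (one k-mer per orbit + decycling)
before being returned, so any faithful variant of the classic construction
is acceptable behind this contract.
"""

from __future__ import annotations

import cmath
import math
import random

from .decycling import KmerSet, _acyclic_without, is_decycling
from .errors import ConstructionError, PreconditionError
from .kmerspace import KmerSpace
from .moves import apply_f_move, apply_i_move, valid_f_moves, valid_i_moves

_TOL = 1e-9


def embedding_weight(space: KmerSpace, u: int) -> complex:
    """W(u) = sum_{j=0}^{k-1} u_{j+1} * omega^j, omega = exp(2*pi*i/k)."""
    digits = space.digits(u)
    omega = cmath.exp(2j * math.pi / space.k)
    return sum(d * omega**j for j, d in enumerate(digits))


def _sector_pick(space: KmerSpace, orbit: tuple[int, ...]) -> int:
    """The unique rotation of a nonzero-weight orbit whose weight argument
    lies in the half-open sector [-2*pi/k, 0): the closed boundary is the
    sector's lower edge.  Left rotation steps the argument by exactly
    -2*pi/k, so exactly one of the k rotations qualifies."""
    two_pi = 2 * math.pi
    width = two_pi / space.k
    hits = []
    for u in orbit:
        # r = how far below 0 the argument sits, in [0, 2*pi)
        r = (-cmath.phase(embedding_weight(space, u))) % two_pi
        if _TOL < r < width + _TOL:
            hits.append(u)
    if len(hits) != 1:
        raise ConstructionError(
            f"sector membership not unique for orbit starting at {orbit[0]}: {hits}"
        )
    return hits[0]


def mykkeltveit_set(space: KmerSpace) -> KmerSet:
    """One k-mer per rotation orbit, chosen by the complex-embedding sector
    rule, with zero-weight orbits completed by backtracking; the returned
    set is verified to be a minimum decycling set."""
    space.check_enumerable()
    part = space.enumerate_pcrs()
    fixed: set[int] = set()
    zero_orbits: list[tuple[int, ...]] = []
    for orbit in part.orbits:
        if abs(embedding_weight(space, orbit[0])) < _TOL:
            zero_orbits.append(tuple(sorted(orbit)))
        else:
            fixed.add(_sector_pick(space, orbit))

    # Backtracking over the zero-weight orbits, members tried in
    # lexicographic order.  Prune a partial choice as soon as removing every
    # k-mer of all still-unassigned orbits cannot break the remaining cycles.
    rest_union: list[frozenset] = [frozenset()] * (len(zero_orbits) + 1)
    for i in range(len(zero_orbits) - 1, -1, -1):
        rest_union[i] = rest_union[i + 1] | frozenset(zero_orbits[i])
    base = frozenset(fixed)

    def search(i: int, chosen: frozenset) -> frozenset | None:
        if i == len(zero_orbits):
            return chosen if _acyclic_without(space, base | chosen) else None
        if not _acyclic_without(space, base | chosen | rest_union[i]):
            return None
        for cand in zero_orbits[i]:
            got = search(i + 1, chosen | {cand})
            if got is not None:
                return got
        return None

    completion = search(0, frozenset())
    if completion is None:
        raise ConstructionError(
            f"no decycling completion of the zero-weight orbits for "
            f"sigma={space.sigma}, k={space.k}"
        )
    result = KmerSet(space, base | completion)
    if len(result) != len(part.orbits) or not is_decycling(result):
        raise ConstructionError("constructed set failed verification")
    return result


def random_pcr_set(space: KmerSpace, seed: int) -> KmerSet:
    """Independent uniform choice of one k-mer per rotation orbit."""
    rng = random.Random(seed)
    part = space.enumerate_pcrs()
    members = frozenset(rng.choice(sorted(orbit)) for orbit in part.orbits)
    return KmerSet(space, members)


def random_mds_walk(
    M0: KmerSet,
    n_moves: int,
    seed: int,
    allow_imoves: bool = False,
) -> KmerSet:
    """A seeded uniformly random walk of valid F-moves (and, when allowed
    and available, I-moves) starting from an MDS; every intermediate set is
    again an MDS."""
    from .decycling import is_mds

    if not is_mds(M0):
        raise PreconditionError("walk must start from a minimum decycling set")
    rng = random.Random(seed)
    M = M0
    for _ in range(n_moves):
        moves: list = valid_f_moves(M)
        if allow_imoves:
            moves = moves + valid_i_moves(M)
        mv = rng.choice(moves)
        if hasattr(mv, "mask"):
            M = apply_i_move(M, mv)
        else:
            M = apply_f_move(M, mv)
    return M
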