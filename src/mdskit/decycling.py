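"""K-mer set semantics: decycling checks, remaining path length, cycles,
hitting numbers, cycle signatures, and brute-force MDS enumeration.

A *decycling set* (DS) is a k-mer set whose removal leaves the de Bruijn
graph acyclic; a *minimum decycling set* (MDS) is a DS of minimum size,
which always picks exactly one k-mer per rotation orbit (PCR).

Path-length convention
----------------------
The longest remaining path is reported as a vertex count.  The convention
was calibrated once by exhaustively enumerating all 30 MDSs at (sigma=2,
k=4): their extremal vertex counts are exactly the published extremal
window guarantees (5 and 7), so the calibration offset is zero.  The
calibration is frozen in the test suite, not re-derived at run time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .errors import InputError, PreconditionError, ResourceLimitError, StateError
from .kmerspace import KmerSpace, successor_table

#: vertices-minus-offset reported by :func:`remaining_path_length`;
#: calibrated to zero (see the module docstring).
PATH_LENGTH_OFFSET = 0


@dataclass(frozen=True)
class KmerSet:
    """A set of k-mers within a space; the representation of DSs and MDSs."""

    space: KmerSpace
    members: frozenset

    def __post_init__(self) -> None:
        if not isinstance(self.members, frozenset):
            object.__setattr__(self, "members", frozenset(self.members))
        n = self.space.n_kmers
        for u in self.members:
            if not 0 <= u < n:
                raise InputError(f"k-mer code {u} out of range [0, {n})")

    @classmethod
    def from_strings(cls, space: KmerSpace, strings: Iterable[str]) -> "KmerSet":
        return cls(space, frozenset(space.encode(s) for s in strings))

    @classmethod
    def from_codes(cls, space: KmerSpace, codes: Iterable[int]) -> "KmerSet":
        return cls(space, frozenset(codes))

    def sorted_codes(self) -> tuple[int, ...]:
        return tuple(sorted(self.members))

    def strings(self, dna: bool = False) -> list[str]:
        return [self.space.decode(u, dna=dna) for u in self.sorted_codes()]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, u: int) -> bool:
        return u in self.members

    def __iter__(self) -> Iterator[int]:
        return iter(self.sorted_codes())


@dataclass(frozen=True)
class CycleList:
    """All simple directed cycles of a (small) de Bruijn graph, in a fixed
    deterministic order: each cycle starts at its smallest node and cycles
    are sorted by (length, node tuple)."""

    space: KmerSpace
    cycles: tuple[tuple[int, ...], ...]

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self) -> Iterator[tuple[int, ...]]:
        return iter(self.cycles)


@dataclass(frozen=True)
class SignatureVector:
    """Hitting numbers of one k-mer set against a fixed cycle list."""

    order: CycleList
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.order):
            raise InputError("signature length must match the cycle list")


# ----------------------------------------------------------------- low level
def _acyclic_without(space: KmerSpace, members: frozenset) -> bool:
    """Kahn peeling of D_k minus ``members``; True iff no directed cycle
    remains.  Iterative, no recursion-depth dependence."""
    sigma, n, nw = space.sigma, space.n_kmers, space.n_words
    indeg = [0] * n
    n_nodes = 0
    for u in range(n):
        if u in members:
            continue
        n_nodes += 1
        base = (u % nw) * sigma
        for b in range(sigma):
            v = base + b
            if v not in members:
                indeg[v] += 1
    stack = [u for u in range(n) if u not in members and indeg[u] == 0]
    seen = 0
    while stack:
        u = stack.pop()
        seen += 1
        base = (u % nw) * sigma
        for b in range(sigma):
            v = base + b
            if v not in members:
                indeg[v] -= 1
                if indeg[v] == 0:
                    stack.append(v)
    return seen == n_nodes


def _longest_path_vertices(space: KmerSpace, members: frozenset) -> int:
    """Number of vertices on a longest path of D_k minus ``members``
    (0 for the empty graph); longest-path DP over a Kahn order."""
    sigma, n, nw = space.sigma, space.n_kmers, space.n_words
    indeg = [0] * n
    n_nodes = 0
    for u in range(n):
        if u in members:
            continue
        n_nodes += 1
        base = (u % nw) * sigma
        for b in range(sigma):
            v = base + b
            if v not in members:
                indeg[v] += 1
    longest = [1] * n
    stack = [u for u in range(n) if u not in members and indeg[u] == 0]
    seen = 0
    best = 0
    while stack:
        u = stack.pop()
        seen += 1
        lu = longest[u]
        if lu > best:
            best = lu
        lu += 1
        base = (u % nw) * sigma
        for b in range(sigma):
            v = base + b
            if v not in members:
                if longest[v] < lu:
                    longest[v] = lu
                indeg[v] -= 1
                if indeg[v] == 0:
                    stack.append(v)
    if seen != n_nodes:
        raise StateError("graph has a cycle")
    return best


# ------------------------------------------------------------------- queries
def is_decycling(M: KmerSet) -> bool:
    """True iff removing M's members (and incident edges) from D_k leaves a
    directed acyclic graph."""
    return _acyclic_without(M.space, M.members)


def is_pcr_set(M: KmerSet) -> bool:
    """True iff M contains exactly one k-mer from every rotation orbit."""
    space = M.space
    seen_orbits: set[int] = set()
    for u in M.members:
        root = min(space.pcr_of(u))
        if root in seen_orbits:
            return False
        seen_orbits.add(root)
    return len(seen_orbits) == space.count_pcrs()


def is_mds(M: KmerSet) -> bool:
    return is_pcr_set(M) and is_decycling(M)


def remaining_path_length(M: KmerSet) -> int:
    """Length of the longest path of D_k minus M, in the calibrated
    (vertex count) convention; 0 when no vertices remain."""
    if not _acyclic_without(M.space, M.members):
        raise StateError("graph has a cycle")
    v = _longest_path_vertices(M.space, M.members)
    return max(0, v - PATH_LENGTH_OFFSET)


def remaining_path_vertices(M: KmerSet) -> int:
    """Vertex count of the longest remaining path: the calibration-free
    form used by the sketch window bound (currently identical to
    :func:`remaining_path_length` since the calibrated offset is zero)."""
    if not _acyclic_without(M.space, M.members):
        raise StateError("graph has a cycle")
    return _longest_path_vertices(M.space, M.members)


def longest_remaining_path(M: KmerSet) -> list[int]:
    """One witness path achieving the maximum, as a list of k-mer codes
    (empty when no vertices remain)."""
    space = M.space
    members = M.members
    if not _acyclic_without(space, members):
        raise StateError("graph has a cycle")
    sigma, n, nw = space.sigma, space.n_kmers, space.n_words
    indeg = [0] * n
    for u in range(n):
        if u in members:
            continue
        base = (u % nw) * sigma
        for b in range(sigma):
            v = base + b
            if v not in members:
                indeg[v] += 1
    longest = [1] * n
    parent = [-1] * n
    stack = [u for u in range(n) if u not in members and indeg[u] == 0]
    best, best_end = 0, -1
    while stack:
        u = stack.pop()
        lu = longest[u]
        if lu > best:
            best, best_end = lu, u
        base = (u % nw) * sigma
        for b in range(sigma):
            v = base + b
            if v not in members:
                if longest[v] < lu + 1:
                    longest[v] = lu + 1
                    parent[v] = u
                indeg[v] -= 1
                if indeg[v] == 0:
                    stack.append(v)
    path: list[int] = []
    u = best_end
    while u != -1:
        path.append(u)
        u = parent[u]
    path.reverse()
    return path


# -------------------------------------------------------------------- cycles
def enumerate_cycles(
    space: KmerSpace, max_nodes: int = 16, max_cycles: int = 1_000_000
) -> CycleList:
    """All simple directed cycles of D_k via ordered-root DFS enumeration
    (each cycle is found exactly once, rooted at its smallest node).

    Gated to tiny graphs: cycle counts explode quickly, so signatures are a
    test instrument, not a production feature.
    """
    n = space.n_kmers
    if n > max_nodes:
        raise ResourceLimitError(
            f"cycle enumeration on {n} nodes exceeds the cap of {max_nodes}"
        )
    succ = successor_table(space.sigma, space.k)
    cycles: list[tuple[int, ...]] = []
    for s in range(n):
        path = [s]
        onpath = {s}
        iters = [iter(succ[s])]
        while iters:
            v = next(iters[-1], None)
            if v is None:
                iters.pop()
                onpath.discard(path.pop())
                continue
            if v == s:
                cycles.append(tuple(path))
                if len(cycles) > max_cycles:
                    raise ResourceLimitError("too many simple cycles")
            elif v > s and v not in onpath:
                path.append(v)
                onpath.add(v)
                iters.append(iter(succ[v]))
    cycles.sort(key=lambda c: (len(c), c))
    return CycleList(space=space, cycles=tuple(cycles))


def _check_cycle(space: KmerSpace, C: Sequence[int]) -> None:
    if len(C) == 0:
        raise InputError("a cycle must contain at least one node")
    if len(set(C)) != len(C):
        raise InputError("cycle nodes must be distinct")
    for i, u in enumerate(C):
        v = C[(i + 1) % len(C)]
        if space.suffix_word(u) != space.prefix_word(v):
            raise InputError(
                f"not a de Bruijn cycle: no edge {space.decode(u)} -> {space.decode(v)}"
            )


def hitting_number(M: KmerSet, C: Sequence[int]) -> int:
    """|M intersect C| for a directed cycle C (given as a node sequence)."""
    _check_cycle(M.space, C)
    return sum(1 for u in C if u in M.members)


def cycle_signature(M: KmerSet, cycles: CycleList) -> SignatureVector:
    """Componentwise hitting numbers in the CycleList order."""
    members = M.members
    values = tuple(sum(1 for u in C if u in members) for C in cycles)
    return SignatureVector(order=cycles, values=values)


# ------------------------------------------------------- exhaustive MDS space
def count_pcr_sets(space: KmerSpace) -> int:
    """Exact number of one-kmer-per-PCR sets: the product of orbit sizes,
    computed from per-period orbit counts (no enumeration needed)."""
    total = 1
    for d in range(1, space.k + 1):
        if space.k % d == 0:
            total *= d ** space.count_lyndon_words(d)
    return total


def iter_pcr_sets(space: KmerSpace, limit: int = 10**7) -> Iterator[frozenset]:
    """All PCR sets in deterministic (orbit-sorted, member-sorted) order."""
    if count_pcr_sets(space) > limit:
        raise ResourceLimitError(
            f"{count_pcr_sets(space)} PCR sets exceed the cap of {limit}; "
            "use the traversal enumeration instead"
        )
    part = space.enumerate_pcrs()
    orbit_choices = [sorted(orbit) for orbit in part.orbits]
    for combo in itertools.product(*orbit_choices):
        yield frozenset(combo)


def brute_force_mds(space: KmerSpace, limit: int = 10**7) -> list[KmerSet]:
    """All MDSs, by filtering every PCR set for acyclicity after removal
    (every MDS is a PCR set).  Deterministic order; small k only."""
    out = []
    for members in iter_pcr_sets(space, limit=limit):
        if _acyclic_without(space, members):
            out.append(KmerSet(space, members))
    return out
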