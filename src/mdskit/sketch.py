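"""Bridge from k-mer sets to sketching.

Only context-free selection schemes are covered: the context is a single
k-mer, so the scheme is the indicator function of its k-mer set, and its
window guarantee is the remaining path length of that set.  Gaps are
measured in k-mer start positions, not symbols.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass

from .decycling import KmerSet, is_decycling, longest_remaining_path, remaining_path_vertices
from .errors import InputError, InvariantError, PreconditionError
from .kmerspace import KmerSpace


@dataclass(frozen=True)
class ContextFreeScheme:
    """A selection scheme whose context is the k-mer itself; selection of a
    position depends only on the k-mer starting there."""

    selected: KmerSet

    @property
    def space(self) -> KmerSpace:
        return self.selected.space


@dataclass(frozen=True)
class SketchResult:
    positions: tuple[int, ...]  # 1-based start positions, sorted
    source_length: int
    k: int

    @property
    def n_kmer_positions(self) -> int:
        return self.source_length - self.k + 1


def sketch_sequence(scheme: ContextFreeScheme, S: str) -> SketchResult:
    """Start positions (1-based) whose k-mer belongs to the scheme's set."""
    space = scheme.space
    k = space.k
    if len(S) < k:
        raise InputError(f"sequence of length {len(S)} is shorter than k={k}")
    members = scheme.selected.members
    nw = space.n_words
    positions = []
    code = space.encode(S[:k])
    if code in members:
        positions.append(1)
    for i in range(1, len(S) - k + 1):
        # rolling update: drop the leading symbol, append the next one
        code = (code % nw) * space.sigma + space._encode(S[i + k - 1], 1)
        if code in members:
            positions.append(i + 1)
    return SketchResult(positions=tuple(positions), source_length=len(S), k=k)


def max_gap(result: SketchResult) -> int:
    """Maximum run of consecutive unselected k-mer start positions, counting
    the runs at both ends; a sequence with no selection returns the total
    number of k-mer positions."""
    n_positions = result.n_kmer_positions
    if not result.positions:
        return n_positions
    gaps = [result.positions[0] - 1, n_positions - result.positions[-1]]
    gaps.extend(
        b - a - 1 for a, b in zip(result.positions, result.positions[1:])
    )
    return max(gaps)


def _random_sequence(space: KmerSpace, length: int, rng: random.Random) -> str:
    return "".join(str(rng.randrange(space.sigma)) for _ in range(length))


def verify_window_guarantee(
    M: KmerSet,
    n_sequences: int = 200,
    length: int = 200,
    seed: int = 0,
    exhaustive_length: int | None = None,
) -> dict:
    """Check, on seeded random sequences (and optionally on *all* sequences
    of a given length), that no run of unselected k-mer positions exceeds
    the vertex-count remaining path length of the decycling set M.

    A violation is raised, not reported: it would falsify either the path
    computation or the decycling check.  Returns a JSON-friendly report.
    """
    if not is_decycling(M):
        raise PreconditionError("window guarantee is only defined for decycling sets")
    space = M.space
    rplv = remaining_path_vertices(M)
    scheme = ContextFreeScheme(selected=M)
    rng = random.Random(seed)
    max_observed = 0

    def check(S: str) -> None:
        nonlocal max_observed
        g = max_gap(sketch_sequence(scheme, S))
        if g > rplv:
            raise InvariantError(
                f"gap {g} exceeds the remaining-path bound {rplv} on {S!r}"
            )
        max_observed = max(max_observed, g)

    for _ in range(n_sequences):
        check(_random_sequence(space, length, rng))
    n_exhaustive = 0
    if exhaustive_length is not None:
        space.check_enumerable(space.sigma**exhaustive_length)
        for tup in itertools.product(range(space.sigma), repeat=exhaustive_length):
            check("".join(map(str, tup)))
            n_exhaustive += 1
    return {
        "max_gap_observed": max_observed,
        "rpl_vertices": rplv,
        "n_sequences": n_sequences,
        "n_exhaustive": n_exhaustive,
        "seed": seed,
    }


def spell_path(space: KmerSpace, path: list[int]) -> str:
    """The sequence spelled by a de Bruijn path (its k-mers are exactly the
    path's vertices); useful to exhibit the tight window."""
    if not path:
        return ""
    s = space.decode(path[0])
    for u in path[1:]:
        s += space.decode(u)[-1]
    return s


def witness_sequence(M: KmerSet) -> str:
    """A sequence attaining the maximum gap: the spelling of one longest
    remaining path."""
    return spell_path(M.space, longest_remaining_path(M))


def syncmer_set(space: KmerSpace, s: int) -> KmerSet:
    """K-mers whose smallest s-mer (lexicographic on codes, leftmost
    tie-break) sits at position 1 — the positional-minimum scheme with the
    first mask bit set, which always yields a decycling set."""
    if not 1 <= s <= space.k:
        raise InputError(f"s must lie in [1, k={space.k}], got {s}")
    space.check_enumerable()
    k = space.k
    members = set()
    for u in range(space.n_kmers):
        kmer = space.decode(u)
        smers = [kmer[i : i + s] for i in range(k - s + 1)]
        if min(range(len(smers)), key=lambda i: (smers[i], i)) == 0:
            members.add(u)
    return KmerSet(space, frozenset(members))
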