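"""The F-move / RF-move / I-move calculus.

An F-move for a (k-1)-mer ``f`` replaces the left-companions lc(f) of a set
by the right-companions rc(f); an RF-move is the inverse.  An I-move ``f|m``
swaps only the left-companions indicated by a letter mask ``m``.  Every
replaced k-mer ``af`` is swapped for its own left rotation ``fa``, so all
moves trivially preserve one-per-PCR structure; the interesting content is
that they also preserve the decycling property on MDSs.

Mask semantics: bit ``a`` of an I-move mask is set iff ``af`` is in the set
before the move (and ``fa`` is in the result after).  Under this convention
the F-move corresponds to the full mask and the RF-move to the zero mask;
both are excluded from the I-move mask range.  For a homopolymer word
``f = c^(k-1)`` the shared k-mer ``c^k`` counts as both companion kinds: its
bit is fixed at zero, the move never touches ``c^k``, and only the remaining
letters are governed by the mask (hence 2^(sigma-1) - 2 admissible masks).

All moves are pure: inputs are never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .decycling import KmerSet
from .errors import PreconditionError
from .kmerspace import KmerSpace

# Per-letter companion tags.
TAG_LEFT = "L"  # af in M only
TAG_RIGHT = "R"  # fa in M only
TAG_BOTH = "B"  # the shared homopolymer a^k in M (homopolymer words only)
TAG_NONE = "N"  # neither
TAG_DOUBLE = "D"  # both af and fa in M with af != fa (impossible in an MDS)


@dataclass(frozen=True, order=True)
class FMove:
    f: int


@dataclass(frozen=True, order=True)
class RFMove:
    f: int


@dataclass(frozen=True, order=True)
class IMove:
    f: int
    mask: int

    def governed_letters(self, space: KmerSpace) -> tuple[int, ...]:
        homo = space.homopolymer_word_letter(self.f)
        return tuple(a for a in range(space.sigma) if a != homo)

    def complement(self, space: KmerSpace) -> "IMove":
        """The bit-complement mask over the governed letters (the reverse
        jump of the undirected component-graph edge)."""
        mask = 0
        for a in self.governed_letters(space):
            if not (self.mask >> a) & 1:
                mask |= 1 << a
        return IMove(self.f, mask)


@dataclass(frozen=True)
class MovePattern:
    """Per-letter classification of the companions of ``f`` against a set."""

    f: int
    tags: tuple[str, ...]

    @property
    def is_f_valid(self) -> bool:
        return all(t in (TAG_LEFT, TAG_BOTH) for t in self.tags)

    @property
    def is_rf_valid(self) -> bool:
        return all(t in (TAG_RIGHT, TAG_BOTH) for t in self.tags)


def companion_pattern(M: KmerSet, f: int) -> MovePattern:
    """Classify each letter ``a`` by which of ``af`` / ``fa`` lies in M.

    Classification is total; a letter with both companions present (and
    distinct) gets the distinguished 'double' tag, which no MDS can exhibit.
    """
    space = M.space
    nw, sigma = space.n_words, space.sigma
    homo = space.homopolymer_word_letter(f)
    tags = []
    for a in range(sigma):
        left = a * nw + f
        right = f * sigma + a
        if a == homo:
            # left == right == the homopolymer k-mer a^k
            tags.append(TAG_BOTH if left in M.members else TAG_NONE)
            continue
        lin, rin = left in M.members, right in M.members
        if lin and rin:
            tags.append(TAG_DOUBLE)
        elif lin:
            tags.append(TAG_LEFT)
        elif rin:
            tags.append(TAG_RIGHT)
        else:
            tags.append(TAG_NONE)
    return MovePattern(f=f, tags=tuple(tags))


# ----------------------------------------------------------------- validity
def valid_f_moves(M: KmerSet) -> list[FMove]:
    """All f with lc(f) wholly contained in M."""
    space = M.space
    nw = space.n_words
    members = M.members
    out = []
    for f in range(nw):
        if all(a * nw + f in members for a in range(space.sigma)):
            out.append(FMove(f))
    return out


def valid_rf_moves(M: KmerSet) -> list[RFMove]:
    """All f with rc(f) wholly contained in M."""
    space = M.space
    sigma = space.sigma
    members = M.members
    out = []
    for f in range(space.n_words):
        if all(f * sigma + a in members for a in range(sigma)):
            out.append(RFMove(f))
    return out


def valid_i_moves(M: KmerSet) -> list[IMove]:
    """All (f, mask) pairs valid in M: every letter is covered by exactly one
    companion side, with at least one letter on each side among the letters
    the mask governs."""
    space = M.space
    out = []
    for f in range(space.n_words):
        pat = companion_pattern(M, f)
        if TAG_NONE in pat.tags or TAG_DOUBLE in pat.tags:
            continue
        lefts = [a for a, t in enumerate(pat.tags) if t == TAG_LEFT]
        rights = [a for a, t in enumerate(pat.tags) if t == TAG_RIGHT]
        if lefts and rights:
            out.append(IMove(f, sum(1 << a for a in lefts)))
    return sorted(out)


def imove_valid_in(M: KmerSet, mv: IMove) -> bool:
    """Validity check for one specific I-move (cheaper than enumerating)."""
    space = M.space
    nw, sigma = space.n_words, space.sigma
    members = M.members
    homo = space.homopolymer_word_letter(mv.f)
    if homo is not None and (mv.mask >> homo) & 1:
        return False
    n_left = 0
    n_right = 0
    for a in range(sigma):
        if a == homo:
            if homo * nw + mv.f not in members:
                return False
            continue
        left = a * nw + mv.f
        right = mv.f * sigma + a
        if (mv.mask >> a) & 1:
            if left not in members or right in members:
                return False
            n_left += 1
        else:
            if right not in members or left in members:
                return False
            n_right += 1
    return n_left > 0 and n_right > 0


# -------------------------------------------------------------- application
def apply_f_move(M: KmerSet, move: FMove | int) -> KmerSet:
    """(M minus lc(f)) union rc(f); size-preserving, remove-then-add so a
    homopolymer k-mer shared by both companion sets is retained."""
    f = move.f if isinstance(move, FMove) else move
    space = M.space
    lc = frozenset(space.left_companions(f))
    missing = lc - M.members
    if missing:
        raise PreconditionError(
            "invalid F-move f=%s: missing left companions %s"
            % (space.decode_word(f), sorted(space.decode(u) for u in missing))
        )
    return KmerSet(space, M.members.difference(lc).union(space.right_companions(f)))


def apply_rf_move(M: KmerSet, move: RFMove | int) -> KmerSet:
    f = move.f if isinstance(move, RFMove) else move
    space = M.space
    rc = frozenset(space.right_companions(f))
    missing = rc - M.members
    if missing:
        raise PreconditionError(
            "invalid RF-move f=%s: missing right companions %s"
            % (space.decode_word(f), sorted(space.decode(u) for u in missing))
        )
    return KmerSet(space, M.members.difference(rc).union(space.left_companions(f)))


def apply_i_move(M: KmerSet, mv: IMove) -> KmerSet:
    """Swap the masked left-companions af for their rotations fa."""
    space = M.space
    if not imove_valid_in(M, mv):
        raise PreconditionError(
            f"I-move f={space.decode_word(mv.f)} mask={mv.mask:b} is not valid here"
        )
    nw, sigma = space.n_words, space.sigma
    removed = {a * nw + mv.f for a in range(sigma) if (mv.mask >> a) & 1}
    added = {mv.f * sigma + a for a in range(sigma) if (mv.mask >> a) & 1}
    return KmerSet(space, M.members.difference(removed).union(added))
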