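"""Alphabet encoding and de Bruijn graph topology.

K-mers over an alphabet of size ``sigma`` are exact integers in big-endian
base-``sigma`` (leftmost symbol most significant), so successor and rotation
arithmetic are O(1) and "lexicographically smallest" coincides with "smallest
code".  Symbols are the digits ``0..sigma-1``; for ``sigma == 4`` the DNA
letters ``ACGT`` are accepted and emitted with ``A=0, C=1, G=2, T=3``.

The de Bruijn graph of order ``k`` has one node per k-mer and an edge
``u -> v`` whenever the length-(k-1) suffix of ``u`` equals the prefix of
``v``; every node has exactly ``sigma`` successors and ``sigma`` predecessors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from .errors import InputError, ResourceLimitError

_DNA_TO_DIGIT = {"A": 0, "C": 1, "G": 2, "T": 3}
_DIGIT_TO_DNA = "ACGT"

#: Enumeration guard: operations that materialize sigma**k objects refuse
#: above this many nodes unless the space was built with a larger limit.
DEFAULT_NODE_LIMIT = 1 << 26


def _divisors(n: int) -> list[int]:
    out = [d for d in range(1, n + 1) if n % d == 0]
    return out


def _euler_phi(n: int) -> int:
    result, m, p = n, n, 2
    while p * p <= m:
        if m % p == 0:
            while m % p == 0:
                m //= p
            result -= result // p
        p += 1
    if m > 1:
        result -= result // m
    return result


def _mobius(n: int) -> int:
    result, m, p = 1, n, 2
    while p * p <= m:
        if m % p == 0:
            m //= p
            if m % p == 0:
                return 0
            result = -result
        p += 1
    if m > 1:
        result = -result
    return result


@dataclass(frozen=True)
class KmerSpace:
    """Parameters (sigma, k) plus the encoding and topology conventions."""

    sigma: int
    k: int
    node_limit: int = DEFAULT_NODE_LIMIT

    def __post_init__(self) -> None:
        if not isinstance(self.sigma, int) or self.sigma < 2:
            raise InputError(f"alphabet size must be an integer >= 2, got {self.sigma!r}")
        if not isinstance(self.k, int) or self.k < 2:
            raise InputError(f"word length k must be an integer >= 2, got {self.k!r}")

    # ------------------------------------------------------------------ sizes
    @property
    def n_kmers(self) -> int:
        return self.sigma**self.k

    @property
    def n_words(self) -> int:
        return self.sigma ** (self.k - 1)

    def check_enumerable(self, need: int | None = None) -> None:
        need = self.n_kmers if need is None else need
        if need > self.node_limit:
            raise ResourceLimitError(
                f"enumeration of {need} objects exceeds the node limit "
                f"{self.node_limit} for sigma={self.sigma}, k={self.k}"
            )

    # --------------------------------------------------------------- encoding
    def encode(self, s: str) -> int:
        """Encode a symbol string of length k as a big-endian base-sigma code."""
        return self._encode(s, self.k)

    def encode_word(self, s: str) -> int:
        """Encode a (k-1)-mer ``f`` (used to index companion sets and moves)."""
        return self._encode(s, self.k - 1)

    def _encode(self, s: str, length: int) -> int:
        if len(s) != length:
            raise InputError(f"expected a string of length {length}, got {len(s)}: {s!r}")
        code = 0
        for i, ch in enumerate(s):
            if ch.isdigit():
                d = int(ch)
            elif self.sigma == 4 and ch in _DNA_TO_DIGIT:
                d = _DNA_TO_DIGIT[ch]
            else:
                raise InputError(f"illegal symbol {ch!r} at position {i + 1} in {s!r}")
            if d >= self.sigma:
                raise InputError(
                    f"symbol {ch!r} at position {i + 1} is outside the "
                    f"alphabet 0..{self.sigma - 1}"
                )
            code = code * self.sigma + d
        return code

    def decode(self, code: int, dna: bool = False) -> str:
        return self._decode(code, self.k, dna)

    def decode_word(self, code: int, dna: bool = False) -> str:
        return self._decode(code, self.k - 1, dna)

    def _decode(self, code: int, length: int, dna: bool) -> str:
        if not 0 <= code < self.sigma**length:
            raise InputError(f"code {code} out of range for length {length}")
        digits = []
        for _ in range(length):
            code, d = divmod(code, self.sigma)
            digits.append(d)
        digits.reverse()
        if dna:
            if self.sigma != 4:
                raise InputError("DNA output requires sigma=4")
            return "".join(_DIGIT_TO_DNA[d] for d in digits)
        return "".join(str(d) for d in digits)

    def digits(self, code: int) -> tuple[int, ...]:
        """The k digits of a k-mer, leftmost first."""
        out = []
        for _ in range(self.k):
            code, d = divmod(code, self.sigma)
            out.append(d)
        out.reverse()
        return tuple(out)

    # --------------------------------------------------------------- topology
    def successors(self, u: int) -> list[int]:
        base = (u % self.n_words) * self.sigma
        return [base + b for b in range(self.sigma)]

    def predecessors(self, u: int) -> list[int]:
        base = u // self.sigma
        return [a * self.n_words + base for a in range(self.sigma)]

    def rotate(self, u: int) -> int:
        """Cyclic left rotation u1 u2 ... uk -> u2 ... uk u1."""
        return (u % self.n_words) * self.sigma + u // self.n_words

    def suffix_word(self, u: int) -> int:
        return u % self.n_words

    def prefix_word(self, u: int) -> int:
        return u // self.sigma

    # ------------------------------------------------------------- companions
    def left_companions(self, f: int) -> tuple[int, ...]:
        """lc(f) = { a*f : a in alphabet } — all k-mers with suffix f."""
        nw = self.n_words
        return tuple(a * nw + f for a in range(self.sigma))

    def right_companions(self, f: int) -> tuple[int, ...]:
        """rc(f) = { f*a : a in alphabet } — all k-mers with prefix f."""
        return tuple(f * self.sigma + a for a in range(self.sigma))

    # lc(f) and rc(f) are disjoint unless f is a homopolymer a^(k-1), in which
    # case they share exactly the homopolymer k-mer a^k.  Three other modules
    # depend on this rule, so it is centralized here.
    def homopolymer_kmer_letter(self, u: int) -> int | None:
        rep = (self.n_kmers - 1) // (self.sigma - 1)
        if u % rep == 0 and u // rep < self.sigma:
            return u // rep
        return None

    def homopolymer_word_letter(self, f: int) -> int | None:
        rep = (self.n_words - 1) // (self.sigma - 1)
        if f % rep == 0 and f // rep < self.sigma:
            return f // rep
        return None

    # ------------------------------------------------------------------- PCRs
    def pcr_of(self, u: int) -> tuple[int, ...]:
        """The orbit of ``u`` under rotation, in rotation order starting from
        the lexicographically smallest (= numerically smallest) member."""
        orbit = [u]
        v = self.rotate(u)
        while v != u:
            orbit.append(v)
            v = self.rotate(v)
        start = orbit.index(min(orbit))
        return tuple(orbit[start:] + orbit[:start])

    def enumerate_pcrs(self) -> "PCRPartition":
        self.check_enumerable()
        seen = bytearray(self.n_kmers)
        orbits: list[tuple[int, ...]] = []
        index: dict[int, int] = {}
        for u in range(self.n_kmers):
            if seen[u]:
                continue
            orbit = self.pcr_of(u)  # u is the smallest member: ascending scan
            oid = len(orbits)
            orbits.append(orbit)
            for v in orbit:
                seen[v] = 1
                index[v] = oid
        part = PCRPartition(space=self, orbits=tuple(orbits), index=index)
        if len(orbits) != self.count_pcrs():
            raise AssertionError("orbit count disagrees with the necklace formula")
        return part

    def count_pcrs(self) -> int:
        """Necklace count (1/k) * sum_{d|k} phi(d) * sigma^(k/d), exactly."""
        total = sum(_euler_phi(d) * self.sigma ** (self.k // d) for d in _divisors(self.k))
        assert total % self.k == 0
        return total // self.k

    def count_lyndon_words(self, length: int) -> int:
        """Number of rotation orbits whose period is exactly ``length``."""
        total = sum(_mobius(length // e) * self.sigma**e for e in _divisors(length))
        assert total % length == 0
        return total // length


@dataclass(frozen=True)
class PCRPartition:
    """The partition of all sigma^k k-mers into rotation orbits (PCRs)."""

    space: KmerSpace
    orbits: tuple[tuple[int, ...], ...]
    index: dict[int, int] = field(compare=False, repr=False)

    def __len__(self) -> int:
        return len(self.orbits)

    def orbit_of(self, u: int) -> tuple[int, ...]:
        return self.orbits[self.index[u]]


@lru_cache(maxsize=None)
def successor_table(sigma: int, k: int) -> list[tuple[int, ...]]:
    """Materialized successor lists, cached per (sigma, k) for hot loops."""
    nw = sigma ** (k - 1)
    return [tuple((u % nw) * sigma + b for b in range(sigma)) for u in range(sigma**k)]
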