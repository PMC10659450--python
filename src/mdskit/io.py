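"""Plain-text set files and FASTA reading.

Set file format::

    #mds sigma=<sigma> k=<k>
    <one k-mer per line, digit alphabet, sorted ascending by code>

ACGT bodies are accepted (and can be emitted) when sigma is 4.  Plain text
wins over any bitset format here: the sets of interest have at most
sigma^k / k members at the k values this package targets.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterator

from .decycling import KmerSet
from .errors import InputError
from .kmerspace import KmerSpace

_HEADER_RE = re.compile(r"^#mds\s+sigma=(\d+)\s+k=(\d+)\s*$")


def read_set_file(path: str | Path) -> KmerSet:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise InputError(f"{path}: empty file, expected a '#mds sigma=.. k=..' header")
    m = _HEADER_RE.match(lines[0])
    if not m:
        raise InputError(f"{path}:1: malformed header {lines[0]!r}")
    space = KmerSpace(sigma=int(m.group(1)), k=int(m.group(2)))
    codes = set()
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            codes.add(space.encode(line))
        except InputError as exc:
            raise InputError(f"{path}:{lineno}: {exc}") from exc
    return KmerSet(space, frozenset(codes))


def write_set_file(M: KmerSet, path: str | Path, dna: bool = False) -> None:
    path = Path(path)
    space = M.space
    lines = [f"#mds sigma={space.sigma} k={space.k}"]
    lines.extend(space.decode(u, dna=dna) for u in M.sorted_codes())
    path.write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Minimal FASTA reader (read-only input for sketch checks)."""
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)
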