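# mdskit

Tools for **minimum decycling sets (MDSs)** of k-mers — the unavoidable
k-mer sets that give sequence-sketching methods their window guarantee.

A set of k-mers is *decycling* when removing it from the order-k de Bruijn
graph leaves no directed cycle, so every long enough sequence must contain
one of its members. Minimum-size decycling sets pick exactly one k-mer from
every rotation orbit (pure cycling register, PCR). The package implements:

- **`kmerspace`** — integer k-mer encoding, de Bruijn topology, rotation
  orbits, necklace counting, companion sets.
- **`decycling`** — decycling / PCR-set checks, remaining path length
  (= the window guarantee of the associated selection scheme), simple-cycle
  enumeration, hitting numbers and cycle signatures, brute-force MDS
  enumeration for small k.
- **`moves`** — the F-move / RF-move / I-move calculus that rewrites one
  MDS into another.
- **`mdsgraph`** — layered enumeration of MDS-graph components, derivation
  of a component's full I-move list from a single member (constrained-cycle
  tagging), and breadth-first traversal of the component graph that
  enumerates the entire MDS space.
- **`generators`** — the complex-embedding (Mykkeltveit-style) MDS
  construction, random PCR sets, random MDS walks.
- **`optimize`** — simulated annealing over the component graph for MDSs
  with extremal remaining path length.
- **`sketch`** — context-free selection schemes, empirical window-guarantee
  verification, positional-minimum (syncmer-like) sets.
- **`io` / `cli`** — plain-text set files, TSV/JSON reports, and the
  `mdskit` command-line tool.

For the binary alphabet the package exactly reproduces the known structure
of the MDS space up to k=7 — e.g. 30 MDSs in 3 components at k=4, 68 288
MDSs in 273 components at k=6 — and the exact extremal window guarantees
(min/max 5/7, 11/12, 13/26, 25/32 for k=4..7).

## Command line

```sh
mdskit mykkeltveit --k 6 --out m6.txt     # build an MDS
mdskit verify m6.txt                      # PCR-set / decycling / RPL report
mdskit rpl m6.txt                         # remaining path length only
mdskit moves m6.txt                       # valid F-, RF- and I-moves
mdskit enumerate --k 6                    # all components (TSV, one row each)
mdskit components --k 6 --out graph.json  # component graph as JSON
mdskit anneal --k 6 --objective min --iters 200 --seed 1 --out best.txt
mdskit random-pcr --k 6 --seed 7 --out r.txt
mdskit random-walk m6.txt --n-moves 50 --seed 3 --allow-imoves
mdskit sketch-check m6.txt --fasta seqs.fa
```

Exit codes: `0` success, `2` precondition/parse error, `3` enumeration
limit exceeded.

Set files are plain text: a `#mds sigma=<s> k=<k>` header followed by one
k-mer per line (digits; `ACGT` accepted when sigma is 4), sorted.

## Conventions worth knowing

- K-mers are big-endian base-sigma integers; "lexicographically smallest"
  and "numerically smallest" coincide.
- Remaining path length counts **vertices** on the longest remaining path.
  The convention was calibrated once against the exhaustively enumerated
  k=4 extrema (5 and 7) and is frozen in the tests.
- I-move masks: bit *a* set means the left-companion *af* is in the set
  before the move (and the rotation *fa* after). For a homopolymer word the
  shared k-mer's bit is fixed and the move never touches it.
- Enumeration above k=7 (binary) is out of scope: the spaces grow
  super-exponentially and published figures there are estimates.
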