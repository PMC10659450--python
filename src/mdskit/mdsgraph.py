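"""Component-level machinery for the MDS graph.

The MDS graph has one node per MDS and an edge for every F-move.  Each of
its connected components is strongly connected, partitioned into
sigma^(k-1) layers with F-move edges advancing the layer index cyclically,
and carries a component-invariant list of valid I-moves.  I-moves link
MDSs from different components, giving an (undirected) *component graph*
whose breadth-first traversal enumerates the whole MDS space — completeness
being conditional on the connectivity conjecture, which holds for every
parameter pair this package enumerates exhaustively.

Components are enumerated layer by layer keeping only the current and next
layer resident plus a visited-key ledger, and the component's full I-move
list is derived from a *single* member MDS by tagging the de Bruijn edges
that lie on a constrained cycle (a cycle hitting the MDS exactly once), so
its cost is independent of the component size.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import deque
from dataclasses import dataclass, field

from .decycling import (
    KmerSet,
    _longest_path_vertices,
    PATH_LENGTH_OFFSET,
    is_decycling,
    is_pcr_set,
)
from .errors import InvariantError, PreconditionError
from .kmerspace import KmerSpace, successor_table
from .moves import IMove, apply_i_move, imove_valid_in

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Component:
    """One strongly connected component of the MDS graph."""

    key: tuple[int, ...]  # sorted codes of the lexicographically smallest member
    representative: KmerSet  # that smallest member
    size: int  # number of MDSs
    layer_sizes: tuple[int, ...]  # sigma^(k-1) entries summing to size
    imoves: tuple[IMove, ...]  # the component-invariant valid I-move list
    rpl_min: int  # min remaining path length over members
    rpl_max: int  # max over members
    hosts: dict = field(compare=False, repr=False, default_factory=dict)

    def key_digest(self) -> str:
        return hashlib.sha1(",".join(map(str, self.key)).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ComponentGraphSummary:
    """The component graph: nodes are component keys, edges are I-move
    adjacencies (undirected), plus the grand total of MDSs."""

    space: KmerSpace
    components: tuple[Component, ...]
    edges: frozenset  # frozenset of frozenset({i, j}) component-index pairs
    n_mds_total: int

    @property
    def nodes(self) -> list[tuple[int, ...]]:
        return [c.key for c in self.components]

    def rpl_range(self) -> tuple[int, int]:
        return (
            min(c.rpl_min for c in self.components),
            max(c.rpl_max for c in self.components),
        )


def _require_mds(M: KmerSet) -> None:
    if not (is_pcr_set(M) and is_decycling(M)):
        raise PreconditionError("the seed set is not a minimum decycling set")


# ---------------------------------------------------------------- Prop 6 core
def component_i_moves(M: KmerSet) -> list[IMove]:
    """The full valid-I-move list of M's component, computed from M alone.

    For every x in M, a forward and a backward M-avoiding DFS find the
    de Bruijn edges lying on some cycle that hits M exactly once (at x).
    An I-move f|m belongs to the component iff no such tagged edge runs
    af -> fb with bit a set and bit b clear.  Runtime is independent of the
    number of MDSs in the component.
    """
    space = M.space
    _require_mds(M)
    sigma, nw = space.sigma, space.n_words
    succ = successor_table(sigma, space.k)
    members = M.members
    tagged: set[tuple[int, int]] = set()

    for x in members:
        # forward reach from x avoiding M
        fwd: set[int] = set()
        stack = [v for v in succ[x] if v != x and v not in members]
        while stack:
            u = stack.pop()
            if u in fwd:
                continue
            fwd.add(u)
            for v in succ[u]:
                if v != x and v not in members and v not in fwd:
                    stack.append(v)
        # backward reach to x avoiding M
        bwd: set[int] = set()
        stack = [u for u in space.predecessors(x) if u != x and u not in members]
        while stack:
            u = stack.pop()
            if u in bwd:
                continue
            bwd.add(u)
            for v in space.predecessors(u):
                if v != x and v not in members and v not in bwd:
                    stack.append(v)
        # tag edges on constrained cycles through x
        if x in succ[x]:
            tagged.add((x, x))
        for v in succ[x]:
            if v != x and v in bwd:
                tagged.add((x, v))
        for u in fwd:
            for v in succ[u]:
                if v == x or v in bwd:
                    tagged.add((u, v))

    out = []
    for f in range(nw):
        homo = space.homopolymer_word_letter(f)
        governed = [a for a in range(sigma) if a != homo]
        bad_pairs = [
            (a, b)
            for a in governed
            for b in governed
            if a != b and (a * nw + f, f * sigma + b) in tagged
        ]
        n_gov = len(governed)
        for gmask in range(1, (1 << n_gov) - 1):
            mask = sum(1 << governed[i] for i in range(n_gov) if (gmask >> i) & 1)
            if not any((mask >> a) & 1 and not (mask >> b) & 1 for a, b in bad_pairs):
                out.append(IMove(f, mask))
    return sorted(out)


# -------------------------------------------------------- component traversal
def _explore_component(
    space: KmerSpace,
    m0: frozenset,
    cid: int,
    ledger: dict,
    imoves: list[IMove],
    compute_rpl: bool = True,
) -> Component:
    """Layered BFS of the F-move forward closure of ``m0`` (which is the
    whole component, by strong connectivity).  Registers every member in
    ``ledger`` as key -> (cid, layer) and checks layer consistency on every
    cross edge — a violation would falsify the partite structure and raises.
    """
    sigma, nw = space.sigma, space.n_words
    lc_sets = [frozenset(space.left_companions(f)) for f in range(nw)]
    rc_sets = [frozenset(space.right_companions(f)) for f in range(nw)]

    def rpl(members: frozenset) -> int:
        v = _longest_path_vertices(space, members)
        return max(0, v - PATH_LENGTH_OFFSET)

    M_as_set = KmerSet(space, m0)
    hosts: dict[IMove, frozenset] = {
        mv: m0 for mv in imoves if imove_valid_in(M_as_set, mv)
    }
    pending = [mv for mv in imoves if mv not in hosts]

    ledger[m0] = (cid, 0)
    layer_sizes = [0] * nw
    layer_sizes[0] = 1
    r0 = rpl(m0) if compute_rpl else 0
    rpl_min = rpl_max = r0
    rep = m0
    rep_key = tuple(sorted(m0))
    size = 1

    frontier = [m0]
    layer = 0
    while frontier:
        nxt: list[frozenset] = []
        nxt_layer = (layer + 1) % nw
        for M in frontier:
            for f in range(nw):
                if lc_sets[f] <= M:
                    child = M.difference(lc_sets[f]).union(rc_sets[f])
                    got = ledger.get(child)
                    if got is not None:
                        gcid, glayer = got
                        if gcid != cid or glayer != nxt_layer:
                            raise InvariantError(
                                "layer closure violated: edge from layer "
                                f"{layer} reaches ({gcid}, {glayer})"
                            )
                        continue
                    ledger[child] = (cid, nxt_layer)
                    nxt.append(child)
                    size += 1
                    layer_sizes[nxt_layer] += 1
                    if compute_rpl:
                        r = rpl(child)
                        if r < rpl_min:
                            rpl_min = r
                        elif r > rpl_max:
                            rpl_max = r
                    ckey = tuple(sorted(child))
                    if ckey < rep_key:
                        rep_key, rep = ckey, child
                    if pending:
                        cset = KmerSet(space, child)
                        still = []
                        for mv in pending:
                            if imove_valid_in(cset, mv):
                                hosts[mv] = child
                            else:
                                still.append(mv)
                        pending = still
        frontier = nxt
        layer = nxt_layer
    if pending:
        raise InvariantError(
            f"no member MDS hosts I-moves {pending}; this falsifies the "
            "constrained-cycle characterization"
        )
    return Component(
        key=rep_key,
        representative=KmerSet(space, rep),
        size=size,
        layer_sizes=tuple(layer_sizes),
        imoves=tuple(imoves),
        rpl_min=rpl_min,
        rpl_max=rpl_max,
        hosts=hosts,
    )


def enumerate_component(M0: KmerSet, compute_rpl: bool = True) -> Component:
    """Enumerate the full MDS-graph component containing ``M0``."""
    _require_mds(M0)
    imoves = component_i_moves(M0)
    return _explore_component(
        M0.space, M0.members, 0, {}, imoves, compute_rpl=compute_rpl
    )


def find_mds_with_pattern(M0: KmerSet, mv: IMove) -> KmerSet:
    """Some MDS of M0's component in which ``mv`` is valid: the first one in
    deterministic layered traversal order (such a host must exist whenever
    ``mv`` is in the component's I-move list)."""
    _require_mds(M0)
    space = M0.space
    nw = space.n_words
    lc_sets = [frozenset(space.left_companions(f)) for f in range(nw)]
    rc_sets = [frozenset(space.right_companions(f)) for f in range(nw)]
    seen = {M0.members}
    queue = deque([M0.members])
    while queue:
        M = queue.popleft()
        ks = KmerSet(space, M)
        if imove_valid_in(ks, mv):
            return ks
        for f in range(nw):
            if lc_sets[f] <= M:
                child = M.difference(lc_sets[f]).union(rc_sets[f])
                if child not in seen:
                    seen.add(child)
                    queue.append(child)
    raise InvariantError(
        "no MDS in the component hosts the requested I-move; this falsifies "
        "the constrained-cycle characterization"
    )


def enumerate_all_components(
    space: KmerSpace,
    seed_mds: KmerSet,
    compute_rpl: bool = True,
) -> ComponentGraphSummary:
    """Breadth-first traversal over components: enumerate a component,
    compute its I-move list, realize each I-move from a host member, jump,
    and recurse on unseen destinations.  Components are processed FIFO and
    I-moves in sorted (f, mask) order, so the result is deterministic.

    Completeness is conditional on the component graph being connected,
    which is verified exhaustively for every parameter pair small enough to
    brute force."""
    _require_mds(seed_mds)
    ledger: dict[frozenset, tuple[int, int]] = {}
    components: list[Component] = []
    edges_raw: list[tuple[int, frozenset]] = []
    queue: deque[frozenset] = deque([seed_mds.members])
    while queue:
        m = queue.popleft()
        if m in ledger:
            continue
        cid = len(components)
        imoves = component_i_moves(KmerSet(space, m))
        comp = _explore_component(space, m, cid, ledger, imoves, compute_rpl)
        components.append(comp)
        logger.info(
            "component %d: size=%d |I|=%d rpl=[%d,%d]",
            cid, comp.size, len(imoves), comp.rpl_min, comp.rpl_max,
        )
        for mv in imoves:
            dest = apply_i_move(KmerSet(space, comp.hosts[mv]), mv).members
            edges_raw.append((cid, dest))
            queue.append(dest)
    edges = set()
    for cid, dest in edges_raw:
        did = ledger[dest][0]
        if did == cid:
            raise InvariantError("an I-move landed in its own component")
        edges.add(frozenset((cid, did)))
    return ComponentGraphSummary(
        space=space,
        components=tuple(components),
        edges=frozenset(edges),
        n_mds_total=sum(c.size for c in components),
    )


def component_rpl_range(component: Component) -> tuple[int, int]:
    """(min, max) remaining path length over the component's members."""
    return (component.rpl_min, component.rpl_max)


# ------------------------------------------------------------------- reports
def component_report_rows(summary: ComponentGraphSummary) -> list[dict]:
    rows = []
    for comp in summary.components:
        rows.append(
            {
                "key": comp.key_digest(),
                "size": comp.size,
                "layer_sizes": ",".join(map(str, comp.layer_sizes)),
                "n_imoves": len(comp.imoves),
                "rpl_min": comp.rpl_min,
                "rpl_max": comp.rpl_max,
            }
        )
    return rows


def component_report_tsv(summary: ComponentGraphSummary) -> str:
    header = ["key", "size", "layer_sizes", "n_imoves", "rpl_min", "rpl_max"]
    lines = ["\t".join(header)]
    for row in component_report_rows(summary):
        lines.append("\t".join(str(row[h]) for h in header))
    return "\n".join(lines) + "\n"


def component_graph_json(summary: ComponentGraphSummary) -> str:
    digests = [c.key_digest() for c in summary.components]
    edges = sorted(sorted(digests[i] for i in pair) for pair in summary.edges)
    return json.dumps(
        {
            "sigma": summary.space.sigma,
            "k": summary.space.k,
            "n_mds_total": summary.n_mds_total,
            "nodes": digests,
            "edges": edges,
        },
        indent=2,
    )
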