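"""Simulated-annealing search over the component graph for MDSs with
extremal remaining path length.

Each iteration samples the current component with a short random F-move
walk (remaining path length evaluated at every step), then jumps to a
neighboring component through a randomly chosen valid I-move.  The jump is
kept if the new component's sampled extremum improves on the current one,
and otherwise kept with Metropolis probability exp(-|delta| / T) under a
geometric cooling schedule.  When the current component admits no I-move at
all, the walk is perturbed by a longer F-move walk.  Every source of
randomness flows from the config seed, so runs are reproducible.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .decycling import KmerSet, remaining_path_length
from .errors import PreconditionError
from .kmerspace import KmerSpace
from .mdsgraph import component_i_moves, find_mds_with_pattern
from .moves import apply_f_move, apply_i_move, valid_f_moves


@dataclass(frozen=True)
class AnnealConfig:
    objective: str = "minimize"  # or "maximize"
    fmoves_per_component: int | None = None  # default 2k, set in anneal()
    iterations: int = 100
    t0: float | None = None  # default k
    cooling: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if self.objective not in ("minimize", "maximize"):
            raise PreconditionError("objective must be 'minimize' or 'maximize'")
        if not 0.0 < self.cooling < 1.0:
            raise PreconditionError("cooling must lie in (0, 1)")


@dataclass(frozen=True)
class AnnealResult:
    best_set: KmerSet
    best_value: int
    trace: tuple[tuple[int, str, int], ...]  # (iteration, component digest, best so far)
    l_min_estimate: int  # smallest RPL ever evaluated during the run
    l_max_estimate: int  # largest RPL ever evaluated during the run


def _imoves_digest(imoves) -> str:
    import hashlib

    blob = ";".join(f"{mv.f}|{mv.mask}" for mv in imoves)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def anneal(space: KmerSpace, config: AnnealConfig, seed_mds: KmerSet) -> AnnealResult:
    """Run the annealing search from ``seed_mds``; returns the best MDS ever
    evaluated (every evaluated set is an MDS, since only F/I-moves are used)."""
    from .decycling import is_mds

    if not is_mds(seed_mds):
        raise PreconditionError("annealing must start from a minimum decycling set")
    k = space.k
    n_local = config.fmoves_per_component or 2 * k
    t = config.t0 if config.t0 is not None else float(k)
    rng = random.Random(config.seed)
    minimize = config.objective == "minimize"
    sign = 1 if minimize else -1

    l_min = l_max = remaining_path_length(seed_mds)
    best_set, best_value = seed_mds, l_min
    trace: list[tuple[int, str, int]] = []

    def evaluate(M: KmerSet) -> int:
        nonlocal l_min, l_max, best_set, best_value
        r = remaining_path_length(M)
        l_min = min(l_min, r)
        l_max = max(l_max, r)
        if sign * r < sign * best_value:
            best_set, best_value = M, r
        return r

    def local_search(M: KmerSet) -> tuple[int, KmerSet]:
        """Random F-move walk of n_local steps; returns the walk's extremum
        and the final position (which stays inside the component)."""
        ext = evaluate(M)
        for _ in range(n_local):
            M = apply_f_move(M, rng.choice(valid_f_moves(M)))
            r = evaluate(M)
            if sign * r < sign * ext:
                ext = r
        return ext, M

    cur_val, cur = local_search(seed_mds)
    for it in range(config.iterations):
        imoves = component_i_moves(cur)
        trace.append((it, _imoves_digest(imoves), best_value))
        if not imoves:
            # no way out of the component: perturb with a longer F-move walk
            from .generators import random_mds_walk

            cur = random_mds_walk(cur, 4 * k, rng.randrange(2**31))
            cur_val, cur = local_search(cur)
        else:
            mv = rng.choice(imoves)
            host = find_mds_with_pattern(cur, mv)
            cand_val, cand = local_search(apply_i_move(host, mv))
            delta = sign * (cand_val - cur_val)
            if delta <= 0 or rng.random() < math.exp(-abs(delta) / max(t, 1e-12)):
                cur_val, cur = cand_val, cand
        t *= config.cooling
    return AnnealResult(
        best_set=best_set,
        best_value=best_value,
        trace=tuple(trace),
        l_min_estimate=l_min,
        l_max_estimate=l_max,
    )
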