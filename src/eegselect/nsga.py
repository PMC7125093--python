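"""Elitist non-dominated sorting genetic algorithms (NSGA-II / NSGA-III).

Both variants share the same skeleton: binary chromosomes, binary-tournament
mating selection, two-point crossover, per-gene bit-flip mutation, and
elitist survival of the combined parent+offspring population through fast
non-dominated sorting.  They differ in how the last, partially admitted
front is thinned:

* NSGA-II keeps the members with the largest crowding distance;
* NSGA-III associates members with a systematic lattice of reference points
  on the normalized hyperplane (equally inclined to all objective axes) and
  fills under-represented niches first, which preserves diversity better in
  many-objective problems.

The run terminates when a maximum generation count is reached or when the
objective-space movement between consecutive tolerance checkpoints — the
mean distance from the current non-dominated set to the previous one, after
ideal/nadir normalization — falls below the configured tolerance.

Every distinct chromosome is evaluated exactly once (evaluations are
memoized: the evaluator contract is deterministic) and logged.  The returned
front is the non-dominated set over *all* evaluated candidates: with four
objectives the true front can exceed the population size, and reporting the
archive keeps every non-dominated configuration the search discovered.
"""

from __future__ import annotations

from itertools import combinations_with_replacement
from typing import Callable, Sequence

import numpy as np

from .optimize import (
    Chromosome,
    FrontMember,
    GAConfig,
    ObjectiveVector,
    ParameterTable,
    ParetoFront,
    decode_chromosome,
    non_dominated_indices,
)

__all__ = ["run_nsga", "fast_non_dominated_sort", "crowding_distance",
           "reference_points"]


# ---------------------------------------------------------------------------
# Sorting and diversity machinery
# ---------------------------------------------------------------------------

def fast_non_dominated_sort(images: np.ndarray) -> list[np.ndarray]:
    """Partition row indices of ``images`` into successive non-dominated fronts."""
    n = len(images)
    dominates_list: list[np.ndarray] = []
    n_dominators = np.zeros(n, dtype=np.int64)
    for i in range(n):
        le = np.all(images[i] <= images, axis=1)
        lt = np.any(images[i] < images, axis=1)
        dominated = np.flatnonzero(le & lt)
        dominates_list.append(dominated)
        n_dominators[dominated] += 1
    fronts = []
    current = np.flatnonzero(n_dominators == 0)
    while len(current):
        fronts.append(current)
        n_dominators[current] = -1
        for i in current:
            n_dominators[dominates_list[i]] -= 1
        current = np.flatnonzero(n_dominators == 0)
    return fronts


def crowding_distance(images: np.ndarray, front: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance of the rows indexed by ``front``."""
    m = len(front)
    dist = np.zeros(m)
    if m <= 2:
        dist[:] = np.inf
        return dist
    for obj in range(images.shape[1]):
        vals = images[front, obj]
        order = np.argsort(vals, kind="stable")
        dist[order[0]] = dist[order[-1]] = np.inf
        span = vals[order[-1]] - vals[order[0]]
        if span <= 0:
            continue
        dist[order[1:-1]] += (vals[order[2:]] - vals[order[:-2]]) / span
    return dist


def reference_points(n_objectives: int, divisions: int) -> np.ndarray:
    """Systematic (Das-Dennis) lattice on the unit simplex.

    Places every point with coordinates ``k_i / divisions`` summing to one;
    for 4 objectives and 4 divisions this yields 35 points.
    """
    points = []
    for cuts in combinations_with_replacement(range(n_objectives), divisions):
        counts = np.bincount(cuts, minlength=n_objectives)
        points.append(counts / divisions)
    return np.array(points)


def _normalize(images: np.ndarray) -> np.ndarray:
    """Deb's NSGA-III normalization: ideal shift, ASF extremes, intercepts."""
    ideal = images.min(axis=0)
    shifted = images - ideal
    m = images.shape[1]
    weights = np.full((m, m), 1e-6) + np.eye(m)
    extremes = np.empty(m, dtype=int)
    for j in range(m):
        asf = np.max(shifted / weights[j], axis=1)
        extremes[j] = int(np.argmin(asf))
    intercepts = shifted.max(axis=0)  # nadir fallback
    try:
        mat = shifted[extremes]
        if np.linalg.matrix_rank(mat) == m:
            plane = np.linalg.solve(mat, np.ones(m))
            cand = 1.0 / plane
            if np.all(cand > 1e-12) and np.all(np.isfinite(cand)):
                intercepts = cand
    except np.linalg.LinAlgError:
        pass
    intercepts = np.maximum(intercepts, 1e-12)
    return shifted / intercepts


def _associate(normalized: np.ndarray, refs: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest reference line (by perpendicular distance) for each point."""
    norms_sq = np.sum(refs ** 2, axis=1)
    proj = normalized @ refs.T / norms_sq
    residual = normalized[:, None, :] - proj[:, :, None] * refs[None, :, :]
    dists = np.linalg.norm(residual, axis=2)
    nearest = np.argmin(dists, axis=1)
    return nearest, dists[np.arange(len(normalized)), nearest]


def _niching(n_fill: int, last: list[int], nearest: np.ndarray,
             dist: np.ndarray, niche_count: np.ndarray,
             rng: np.random.Generator) -> list[int]:
    """NSGA-III niche-preserving selection from the last admitted front."""
    chosen: list[int] = []
    candidates = {i: (int(nearest[i]), float(dist[i])) for i in last}
    active = set(range(len(niche_count)))
    while len(chosen) < n_fill and candidates:
        counts = {r: niche_count[r] for r in active
                  if any(ref == r for ref, _ in candidates.values())}
        if not counts:
            break
        min_count = min(counts.values())
        tied = sorted(r for r, c in counts.items() if c == min_count)
        ref = tied[int(rng.integers(len(tied)))]
        members = sorted(i for i, (r, _) in candidates.items() if r == ref)
        if niche_count[ref] == 0:
            pick = min(members, key=lambda i: (candidates[i][1], i))
        else:
            pick = members[int(rng.integers(len(members)))]
        chosen.append(pick)
        niche_count[ref] += 1
        del candidates[pick]
    # degenerate fallback (should not trigger): pad deterministically
    remaining = [i for i in last if i not in chosen]
    while len(chosen) < n_fill and remaining:
        chosen.append(remaining.pop(0))
    return chosen


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def _two_point_crossover(a: np.ndarray, b: np.ndarray,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = len(a)
    i, j = sorted(rng.choice(n + 1, size=2, replace=False))
    c1, c2 = a.copy(), b.copy()
    c1[i:j], c2[i:j] = b[i:j], a[i:j]
    return c1, c2


def _mutate(genes: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    flips = rng.random(len(genes)) < prob
    out = genes.copy()
    out[flips] ^= 1
    return out


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_nsga(cfg: GAConfig,
             evaluator: Callable[[tuple[int, ...]], ObjectiveVector],
             n_channels: int = 56,
             table: ParameterTable = ParameterTable(),
             frozen_tail: Sequence[int] | None = None,
             initial_population: np.ndarray | None = None) -> ParetoFront:
    """Run NSGA-II or NSGA-III over binary channel/parameter chromosomes.

    Parameters
    ----------
    cfg:
        Driver settings (variant, population, termination, operators, seed).
    evaluator:
        Deterministic map from a gene tuple to an :class:`ObjectiveVector`.
    n_channels:
        Number of channel genes; total genes are ``n_channels + 8``.
    frozen_tail:
        Optional 8 genes forced onto the nu/gamma fields of every candidate
        (restricts the search to the channel mask alone).
    initial_population:
        Optional ``(population_size, n_genes)`` binary seed population.
    """
    n_genes = n_channels + 8
    rng = np.random.default_rng(cfg.seed)
    mutation_prob = cfg.mutation_prob if cfg.mutation_prob is not None else 1.0 / n_genes
    tail = None if frozen_tail is None else np.asarray(frozen_tail, dtype=np.int64)
    if tail is not None and len(tail) != 8:
        raise ValueError("frozen_tail must supply exactly 8 genes")

    memo: dict[tuple[int, ...], ObjectiveVector] = {}
    eval_log: list[tuple[int, tuple[int, ...], ObjectiveVector]] = []
    gen_log: list[dict] = []

    def finalize(genes_pop: np.ndarray) -> np.ndarray:
        if tail is not None:
            genes_pop = genes_pop.copy()
            genes_pop[:, n_channels:] = tail
        return genes_pop

    def evaluate(genes_pop: np.ndarray, generation: int) -> np.ndarray:
        images = np.empty((len(genes_pop), 4))
        for i, row in enumerate(genes_pop):
            key = tuple(int(g) for g in row)
            obj = memo.get(key)
            if obj is None:
                obj = evaluator(key)
                memo[key] = obj
                eval_log.append((generation, key, obj))
            images[i] = obj.minimization()
        return images

    if initial_population is not None:
        population = np.asarray(initial_population, dtype=np.int64)
        if population.shape != (cfg.population_size, n_genes):
            raise ValueError(
                f"initial population must have shape "
                f"({cfg.population_size}, {n_genes}), got {population.shape}"
            )
        population = finalize(population)
    else:
        population = finalize(rng.integers(0, 2, size=(cfg.population_size, n_genes)))
    images = evaluate(population, 0)

    refs = reference_points(4, cfg.ref_divisions) if cfg.variant == "nsga3" else None
    prev_checkpoint: np.ndarray | None = None
    generations_run = 0

    def archive_front_images() -> np.ndarray:
        all_images = np.array([obj.minimization() for obj in memo.values()])
        return all_images[non_dominated_indices(all_images)]

    def log_generation(gen: int, pop_images: np.ndarray) -> None:
        fronts = fast_non_dominated_sort(pop_images)
        feasible = pop_images[pop_images[:, 0] <= n_channels]
        record = {
            "generation": gen,
            "front_size": int(len(fronts[0])),
            "best_n_channels": float(feasible[:, 0].min()) if len(feasible) else None,
            "best_accuracy": float(1 - pop_images[:, 1].min()),
            "best_tar": float(1 - pop_images[:, 2].min()),
            "best_trr": float(1 - pop_images[:, 3].min()),
        }
        gen_log.append(record)

    log_generation(0, images)

    for gen in range(1, cfg.max_generations + 1):
        generations_run = gen
        # mating selection: binary tournament
        fronts = fast_non_dominated_sort(images)
        rank = np.empty(len(images), dtype=int)
        crowd = np.zeros(len(images))
        for level, front in enumerate(fronts):
            rank[front] = level
            crowd[front] = crowding_distance(images, front)

        def better(i: int, j: int) -> int:
            if rank[i] != rank[j]:
                return i if rank[i] < rank[j] else j
            if cfg.variant == "nsga2" and crowd[i] != crowd[j]:
                return i if crowd[i] > crowd[j] else j
            return i if rng.random() < 0.5 else j

        offspring_rows = []
        while len(offspring_rows) < cfg.population_size:
            contenders = rng.integers(0, cfg.population_size, size=4)
            p1 = better(int(contenders[0]), int(contenders[1]))
            p2 = better(int(contenders[2]), int(contenders[3]))
            a, b = population[p1], population[p2]
            if rng.random() < cfg.crossover_prob:
                a, b = _two_point_crossover(a, b, rng)
            offspring_rows.append(_mutate(a, mutation_prob, rng))
            if len(offspring_rows) < cfg.population_size:
                offspring_rows.append(_mutate(b, mutation_prob, rng))
        offspring = finalize(np.array(offspring_rows, dtype=np.int64))
        off_images = evaluate(offspring, gen)

        combined = np.vstack([population, offspring])
        combined_images = np.vstack([images, off_images])
        fronts = fast_non_dominated_sort(combined_images)

        survivors: list[int] = []
        last_front: np.ndarray | None = None
        for front in fronts:
            if len(survivors) + len(front) <= cfg.population_size:
                survivors.extend(int(i) for i in front)
            else:
                last_front = front
                break
        if last_front is not None and len(survivors) < cfg.population_size:
            n_fill = cfg.population_size - len(survivors)
            if cfg.variant == "nsga2":
                cd = crowding_distance(combined_images, last_front)
                order = np.argsort(-cd, kind="stable")
                survivors.extend(int(last_front[i]) for i in order[:n_fill])
            else:
                pool = survivors + [int(i) for i in last_front]
                normalized = _normalize(combined_images[pool])
                nearest_local, dist_local = _associate(normalized, refs)
                nearest = np.full(len(combined_images), -1)
                dist = np.full(len(combined_images), np.inf)
                for local, idx in enumerate(pool):
                    nearest[idx] = nearest_local[local]
                    dist[idx] = dist_local[local]
                niche_count = np.zeros(len(refs), dtype=int)
                for idx in survivors:
                    niche_count[nearest[idx]] += 1
                chosen = _niching(n_fill, [int(i) for i in last_front],
                                  nearest, dist, niche_count, rng)
                survivors.extend(chosen)

        population = combined[survivors]
        images = combined_images[survivors]
        log_generation(gen, images)

        if gen % cfg.tolerance_check_period == 0:
            current = archive_front_images()
            if prev_checkpoint is not None:
                union = np.vstack([current, prev_checkpoint])
                ideal = union.min(axis=0)
                span = np.maximum(union.max(axis=0) - ideal, 1e-12)
                cur_n = (current - ideal) / span
                prev_n = (prev_checkpoint - ideal) / span
                d = np.linalg.norm(cur_n[:, None, :] - prev_n[None, :, :], axis=2)
                movement = float(d.min(axis=1).mean())
                if movement < cfg.tolerance:
                    break
            prev_checkpoint = current

    # archive front over every evaluated chromosome, duplicates collapsed
    keys = list(memo.keys())
    all_images = np.array([memo[k].minimization() for k in keys])
    front_idx = non_dominated_indices(all_images)
    seen_images: set[tuple] = set()
    members: list[FrontMember] = []
    order = sorted(front_idx, key=lambda i: tuple(all_images[i]) + keys[i])
    for i in order:
        img = tuple(all_images[i])
        if img in seen_images:
            continue
        seen_images.add(img)
        chrom = Chromosome(genes=keys[i], n_channels=n_channels)
        mask, nu, gamma = decode_chromosome(chrom, table)
        members.append(FrontMember(chromosome=chrom, objectives=memo[keys[i]],
                                   nu=nu, gamma=gamma, channel_indices=mask))
    return ParetoFront(members=members, n_evaluations=len(memo),
                       generations_run=generations_run,
                       generation_log=gen_log, evaluation_log=eval_log)
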