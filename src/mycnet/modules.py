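"""Composite cis-regulatory module discovery by a genetic algorithm.

A composite module is a small set of PWMs (three by default, mirroring a
Myc matrix plus two partner factors) with a per-component score cutoff and one
shared pairwise-distance bound: a promoter "fits" the module when every
component has at least one site above its cutoff and some selection of one
site per component keeps every pairwise start distance within the bound
(equivalently, the selected starts span at most ``max_pair_distance`` bp).

The GA evolves a population of candidate modules to maximize a fitness that
rewards separating module scores between the YES (regulated) and NO
(background) promoter sets while penalizing permissive modules:

    fitness = (mean_yes - mean_no) / pooled_sd  -  penalty_rate * complexity

where complexity is the mean normalized cutoff slack plus the normalized
distance-window slack.  Selection is tournament of size 3 with elitism, so the
best-fitness trace is non-decreasing by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import pct_half_up
from .pwm import SiteHit

logger = logging.getLogger(__name__)

CUTOFF_GRID = np.round(np.arange(0.50, 1.0001, 0.05), 2)
DISTANCE_GRID = tuple(range(25, 501, 25))
_SD_FLOOR = 0.1


class ModuleError(ValueError):
    pass


#: per-gene scan index: pwm id -> (offsets, mss scores), both sorted by offset
GeneHits = Mapping[str, tuple[np.ndarray, np.ndarray]]


def index_hits(hits: Iterable[SiteHit]) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Group raw scan hits by gene and matrix for fast module evaluation."""
    acc: dict[str, dict[str, list[tuple[int, float]]]] = {}
    for h in hits:
        acc.setdefault(h.gene_id, {}).setdefault(h.pwm_id, []).append((h.offset, h.mss))
    out: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for gene, per_pwm in acc.items():
        out[gene] = {}
        for pwm_id, pairs in per_pwm.items():
            pairs.sort()
            offs = np.array([p[0] for p in pairs], dtype=int)
            mss = np.array([p[1] for p in pairs], dtype=float)
            out[gene][pwm_id] = (offs, mss)
    return out


@dataclass(frozen=True)
class CompositeModule:
    """Components are (pwm_id, score_cutoff) pairs; ids must be distinct."""

    components: tuple[tuple[str, float], ...]
    max_pair_distance: int
    fitness: float = float("nan")

    def __post_init__(self) -> None:
        if not self.components:
            raise ModuleError("empty module")
        ids = [c[0] for c in self.components]
        if len(set(ids)) != len(ids):
            raise ModuleError("duplicate matrix in module")
        if self.max_pair_distance <= 0:
            raise ModuleError("max_pair_distance must be positive")

    @property
    def pwm_ids(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.components)

    def canonical(self) -> tuple:
        return (tuple(sorted(self.components)), self.max_pair_distance)

    def complexity(self) -> float:
        """Normalized permissiveness: cutoff slack plus distance slack, each in [0,1]."""
        lo, hi = float(CUTOFF_GRID[0]), float(CUTOFF_GRID[-1])
        cut_slack = float(np.mean([(hi - c) / (hi - lo) for _, c in self.components]))
        d_lo, d_hi = DISTANCE_GRID[0], DISTANCE_GRID[-1]
        dist_slack = (self.max_pair_distance - d_lo) / (d_hi - d_lo)
        return cut_slack + dist_slack

    def to_dict(self) -> dict:
        return {
            "components": [{"pwm_id": p, "cutoff": c} for p, c in self.components],
            "max_pair_distance": self.max_pair_distance,
            "fitness": self.fitness,
        }


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters.

    The defaults are the full-scale discovery settings; ``fast()`` is the
    reduced configuration used for test-scale problems.
    """

    iterations: int = 800
    population_size: int = 1000
    non_change_limit: int = 800
    elite_size: int = 50
    mutation_rate: float = 0.25
    penalty_rate: float = 0.3
    module_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.elite_size < self.population_size:
            raise ModuleError("elite_size must be below population_size")
        for name in ("mutation_rate", "penalty_rate"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ModuleError(f"{name} must lie in (0,1)")

    @classmethod
    def full(cls, **kw) -> "GAConfig":
        return cls(**kw)

    @classmethod
    def fast(cls, **kw) -> "GAConfig":
        defaults = dict(iterations=100, population_size=200, non_change_limit=100, elite_size=20)
        defaults.update(kw)
        return cls(**defaults)


def _admissible_selections(module: CompositeModule, gene_hits: GeneHits):
    """Candidate (offset, mss) lists per component after cutoff filtering."""
    per_component = []
    for pwm_id, cutoff in module.components:
        entry = gene_hits.get(pwm_id)
        if entry is None:
            return None
        offs, mss = entry
        keep = mss >= cutoff
        if not keep.any():
            return None
        per_component.append((offs[keep], mss[keep]))
    return per_component


def module_fits(module: CompositeModule, gene_hits: GeneHits) -> bool:
    """True iff some one-site-per-component selection spans <= max_pair_distance."""
    per_component = _admissible_selections(module, gene_hits)
    if per_component is None:
        return False
    k = len(per_component)
    pooled = sorted(
        (off, ci) for ci, (offs, _) in enumerate(per_component) for off in offs
    )
    D = module.max_pair_distance
    lo = 0
    counts = [0] * k
    seen = 0
    for hi, (off, ci) in enumerate(pooled):
        counts[ci] += 1
        if counts[ci] == 1:
            seen += 1
        while off - pooled[lo][0] > D:
            cj = pooled[lo][1]
            counts[cj] -= 1
            if counts[cj] == 0:
                seen -= 1
            lo += 1
        if seen == k:
            return True
    return False


def _range_max(scores: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Vectorized max of scores[lo[i]:hi[i]] for monotone index pairs (lo < hi)."""
    n = len(scores)
    pairs = np.empty(2 * len(lo), dtype=np.int64)
    pairs[0::2] = lo
    pairs[1::2] = np.minimum(hi, n - 1)
    out = np.maximum.reduceat(scores, pairs)[0::2]
    # a clamped right edge drops the final element; restore it
    tail = hi == n
    if tail.any():
        out[tail] = np.maximum(out[tail], scores[n - 1])
    return out


def module_score(module: CompositeModule, gene_hits: GeneHits) -> float:
    """Best total mss over admissible selections; 0 when the module does not fit.

    All pairwise distances within a selection are bounded iff the span
    (max start - min start) is, so the optimum anchors a window [a, a+D] at
    some selected start a and takes each component's best site inside it.
    """
    per_component = _admissible_selections(module, gene_hits)
    if per_component is None:
        return 0.0
    D = module.max_pair_distance
    anchors = np.unique(np.concatenate([offs for offs, _ in per_component]))
    total = np.zeros(len(anchors))
    valid = np.ones(len(anchors), dtype=bool)
    for offs, mss in per_component:
        lo = np.searchsorted(offs, anchors, side="left")
        hi = np.searchsorted(offs, anchors + D, side="right")
        ok = lo < hi
        valid &= ok
        if not valid.any():
            return 0.0
        contrib = np.zeros(len(anchors))
        contrib[ok] = _range_max(mss, lo[ok], hi[ok])
        total += contrib
    if not valid.any():
        return 0.0
    return float(total[valid].max())


def ga_fitness(
    module: CompositeModule,
    yes_hits: Mapping[str, GeneHits],
    no_hits: Mapping[str, GeneHits],
    penalty_rate: float,
) -> float:
    """Separation of module scores between YES and NO minus complexity penalty."""
    if not yes_hits or not no_hits:
        raise ModuleError("YES and NO promoter sets must be non-empty")
    ys = np.array([module_score(module, yes_hits[g]) for g in sorted(yes_hits)])
    ns = np.array([module_score(module, no_hits[g]) for g in sorted(no_hits)])
    ny, nn = len(ys), len(ns)
    if ny + nn > 2:
        pooled_var = ((ny - 1) * ys.var(ddof=1) + (nn - 1) * ns.var(ddof=1)) / (ny + nn - 2)
    else:
        pooled_var = 0.0
    sd = max(np.sqrt(pooled_var), _SD_FLOOR)
    separation = (ys.mean() - ns.mean()) / sd if ys.mean() != ns.mean() else 0.0
    return separation - penalty_rate * module.complexity()


def _random_module(
    rng: np.random.Generator,
    library: Sequence[str],
    module_size: int,
    myc_ids: Sequence[str] | None,
) -> CompositeModule:
    ids: list[str] = []
    if myc_ids:
        ids.append(str(rng.choice(list(myc_ids))))
    remaining = [p for p in library if p not in ids]
    ids.extend(str(x) for x in rng.choice(remaining, size=module_size - len(ids), replace=False))
    comps = tuple((p, float(rng.choice(CUTOFF_GRID))) for p in ids)
    return CompositeModule(comps, int(rng.choice(DISTANCE_GRID)))


def _mutate(
    rng: np.random.Generator,
    module: CompositeModule,
    library: Sequence[str],
    rate: float,
    myc_ids: Sequence[str] | None,
) -> CompositeModule:
    comps = list(module.components)
    for i, (pwm_id, cutoff) in enumerate(comps):
        if rng.random() < rate:  # matrix identity
            anchored = bool(myc_ids) and i == 0
            pool = list(myc_ids) if anchored else library
            others = [p for p in pool if p not in {c[0] for c in comps}]
            if others:
                pwm_id = str(rng.choice(others))
        if rng.random() < rate:  # cutoff jitter +-0.05 on the grid
            cutoff = float(np.clip(round(cutoff + rng.choice([-0.05, 0.05]), 2),
                                   CUTOFF_GRID[0], CUTOFF_GRID[-1]))
        comps[i] = (pwm_id, cutoff)
    dist = module.max_pair_distance
    if rng.random() < rate:
        dist = int(rng.choice(DISTANCE_GRID))
    return CompositeModule(tuple(comps), dist)


def _sort_key(m: CompositeModule) -> tuple:
    # best first: fitness desc, then simpler, then stable id order
    return (-m.fitness, m.complexity(), tuple(sorted(m.pwm_ids)))


def run_ga(
    config: GAConfig,
    pwm_library: Sequence[str],
    yes_hits: Mapping[str, GeneHits],
    no_hits: Mapping[str, GeneHits],
    myc_ids: Sequence[str] | None = None,
) -> tuple[CompositeModule, list[float]]:
    """Evolve composite modules; returns the best-ever module and the history.

    ``pwm_library`` lists candidate matrix ids (hits must be pre-scanned at or
    below the lowest cutoff on the grid).  ``myc_ids``, when given, anchors the
    first component to one of those matrices.  Fully deterministic for a fixed
    ``config.seed``; the per-iteration best-fitness history is non-decreasing.
    """
    library = sorted(set(pwm_library))
    if len(library) < config.module_size:
        raise ModuleError("matrix library smaller than module size")
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple, float] = {}

    def fitness(m: CompositeModule) -> float:
        key = m.canonical()
        if key not in cache:
            cache[key] = ga_fitness(m, yes_hits, no_hits, config.penalty_rate)
        return cache[key]

    population = [
        _random_module(rng, library, config.module_size, myc_ids)
        for _ in range(config.population_size)
    ]
    population = [replace(m, fitness=fitness(m)) for m in population]
    population.sort(key=_sort_key)
    best = population[0]
    history = [best.fitness]
    stale = 0

    for _ in range(config.iterations):
        nxt = population[: config.elite_size]
        while len(nxt) < config.population_size:
            contenders = rng.integers(0, len(population), size=3)
            parent = min((population[i] for i in contenders), key=_sort_key)
            child = _mutate(rng, parent, library, config.mutation_rate, myc_ids)
            nxt.append(replace(child, fitness=fitness(child)))
        population = sorted(nxt, key=_sort_key)
        if _sort_key(population[0]) < _sort_key(best):
            best = population[0]
            stale = 0
        else:
            stale += 1
        history.append(best.fitness)
        if stale >= config.non_change_limit:
            break
    return best, history


def module_coverage(
    module: CompositeModule, genes_hits: Mapping[str, GeneHits]
) -> tuple[int, int]:
    """(number of fitting genes, integer half-up percentage) over a gene set."""
    if not genes_hits:
        raise ModuleError("empty gene set")
    n_fit = sum(module_fits(module, gh) for gh in genes_hits.values())
    return n_fit, int(pct_half_up(n_fit, len(genes_hits)))


def coverage_percentage(n_fit: int, n_total: int) -> int:
    """Printed coverage convention: integer percentage, ties rounded up."""
    if n_total <= 0:
        raise ModuleError("empty gene set")
    return int(pct_half_up(n_fit, n_total))


def save_module(module: CompositeModule, path: str | Path) -> None:
    Path(path).write_text(json.dumps(module.to_dict(), indent=2) + "\n")


def load_module(path: str | Path) -> CompositeModule:
    d = json.loads(Path(path).read_text())
    return CompositeModule(
        tuple((c["pwm_id"], float(c["cutoff"])) for c in d["components"]),
        int(d["max_pair_distance"]),
        float(d.get("fitness", float("nan"))),
    )
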