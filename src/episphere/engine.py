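"""Spherical evolutionary search for epistatic SNP combinations.

Candidate solutions are continuous k-vectors over the SNP index range,
decoded to distinct sorted index tuples for scoring.  Each generation,
every individual is perturbed by two spherical steps — a random-angle
displacement whose radius is a scaled distance to a "pbest" elite and
to a population/archive pair — recombined by binomial crossover, and
kept only if it improves the penalty-boundary-intersection value of
its own decomposition subproblem.  Scale factors F are drawn from a
Cauchy distribution centered on a success-history memory (weighted
Lehmer mean of recently winning F values).  Losing parents feed an
external archive that diversifies the difference vectors.

The search result is the nondominated front, under minimization of
(K2, LR), of every distinct combination the run evaluated.

The inner loop runs on scalar arithmetic: the vectors involved have
only ``order_k`` (2–4) components, where Python floats beat ufunc
dispatch by an order of magnitude.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .dataset import GenotypeDataset
from .decomposition import generate_weights
from .scoring import DatasetScorer, ObjectivePair

logger = logging.getLogger(__name__)

__all__ = [
    "Individual",
    "Archive",
    "HistoryMemory",
    "DetectionRecord",
    "DetectionResult",
    "initialize_population",
    "decode_position",
    "spherical_step",
    "mutate",
    "crossover",
    "select",
    "update_archive",
    "sample_scale_factor",
    "update_memory",
    "pareto_front",
    "run_search",
]


@dataclass
class Individual:
    """One candidate: a continuous position and its decoded score."""

    position: np.ndarray
    decoded: tuple[int, ...]
    objectives: ObjectivePair


@dataclass
class Archive:
    """Bounded store of losing parents; random eviction when full."""

    capacity: int
    members: list[Individual] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class HistoryMemory:
    """Success-history memory of the spherical scale factor F."""

    values: np.ndarray
    k_index: int = 0  # next slot to overwrite (cyclic)

    @classmethod
    def initial(cls, size: int) -> "HistoryMemory":
        return cls(values=np.full(size, 0.5))


@dataclass
class DetectionRecord:
    """One reported SNP combination with its scores and validation state."""

    snp_indices: tuple[int, ...]
    snp_names: tuple[str, ...]
    k2: float
    lr: float
    raw_g: float
    g_test_p: float | None = None
    mdr_accuracy: float | None = None
    passed_validation: bool | None = None


@dataclass
class DetectionResult:
    """Nondominated SNP combinations found by one search run."""

    records: list[DetectionRecord]
    n_evaluations: int
    n_unique_evaluated: int
    config: RunConfig

    def combinations(self) -> list[tuple[int, ...]]:
        return [r.snp_indices for r in self.records]


def decode_position(position, n_snps: int) -> tuple[int, ...]:
    """Map a continuous position to k distinct sorted SNP indices.

    Coordinates are floored and clipped; a duplicate is repaired by
    advancing the later coordinate cyclically to the nearest unused
    index.  Total on finite input and idempotent on decoded output.
    """
    used: set[int] = set()
    out: list[int] = []
    for v in position:
        i = math.floor(v)
        if i < 0:
            i = 0
        elif i >= n_snps:
            i = n_snps - 1
        while i in used:
            i = (i + 1) % n_snps
        used.add(i)
        out.append(i)
    return tuple(sorted(out))


def spherical_step(a, b, f: float, rng: np.random.Generator) -> np.ndarray:
    """Random-direction displacement of length f·‖a − b‖₂.

    The direction is the hyperspherical-coordinate unit vector with
    angles drawn uniformly from [0, 2π); for one dimension the step is
    a random sign.  The returned norm equals f·‖a − b‖₂ exactly.
    """
    dim = len(a)
    s = 0.0
    for j in range(dim):
        d = float(a[j]) - float(b[j])
        s += d * d
    radius = f * math.sqrt(s)
    if dim == 1:
        return np.array([radius if rng.random() < 0.5 else -radius])
    theta = rng.uniform(0.0, 2.0 * math.pi, size=dim - 1)
    out = np.empty(dim)
    prod = radius
    for j in range(dim - 1, 0, -1):
        t = float(theta[j - 1])
        out[j] = prod * math.cos(t)
        prod *= math.sin(t)
    out[0] = prod
    return out


def _reflect_scalar(v: float, span: float, top: float) -> float:
    x = math.fmod(v, 2.0 * span)
    if x < 0.0:
        x += 2.0 * span
    if x > span:
        x = 2.0 * span - x
    return x if x < top else top


def mutate(
    xi,
    pbest,
    xr1,
    xr2,
    f: float,
    n_snps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Trial base vector: two spherical steps around the parent.

    T = X + step(X, pbest) + step(Xr1, Xr2), with out-of-bound
    coordinates reflected back into [0, n_snps).
    """
    s1 = spherical_step(xi, pbest, f, rng)
    s2 = spherical_step(xr1, xr2, f, rng)
    span = float(n_snps)
    top = math.nextafter(span, 0.0)
    out = np.empty(len(xi))
    for j in range(len(xi)):
        out[j] = _reflect_scalar(
            float(xi[j]) + float(s1[j]) + float(s2[j]), span, top
        )
    return out


def crossover(xi, ti, cr: float, rng: np.random.Generator) -> np.ndarray:
    """Binomial crossover with one forced coordinate from the trial."""
    dim = len(xi)
    j_rand = int(rng.integers(dim))
    out = np.empty(dim)
    for j in range(dim):
        if j == j_rand or rng.random() < cr:
            out[j] = float(ti[j])
        else:
            out[j] = float(xi[j])
    return out


def initialize_population(
    np_size: int,
    k: int,
    n_snps: int,
    scorer,
    rng: np.random.Generator,
) -> list[Individual]:
    """Uniform positions in [0, n_snps)^k, decoded and scored."""
    if n_snps < k:
        raise ValueError("fewer SNPs than the interaction order")
    population = []
    for _ in range(np_size):
        pos = rng.uniform(0.0, n_snps, size=k)
        decoded = decode_position(pos, n_snps)
        population.append(Individual(pos, decoded, scorer(decoded)))
    return population


def select(
    parent: Individual,
    trial: Individual,
    fx_parent,
    fx_trial,
    omega,
    ref,
    theta: float,
) -> tuple[Individual, bool, float]:
    """Elitist selection on one decomposition subproblem.

    Compares the penalty-boundary-intersection values of the parent's
    and trial's normalized objective vectors under the subproblem's
    weight; the trial survives only on a strict improvement (ties keep
    the parent).  Returns (survivor, success flag, |Δfitness|).
    ``run_search`` applies this same rule inline.
    """
    from .decomposition import pbi_aggregate

    f_parent = pbi_aggregate(fx_parent, omega, ref, theta)
    f_trial = pbi_aggregate(fx_trial, omega, ref, theta)
    if f_trial < f_parent:
        return trial, True, f_parent - f_trial
    return parent, False, 0.0


def update_archive(
    archive: Archive, loser: Individual, rng: np.random.Generator
) -> Archive:
    """Append a losing parent, evicting a random old member when full."""
    archive.members.append(loser)
    while len(archive.members) > archive.capacity:
        victim = int(rng.integers(len(archive.members) - 1))
        archive.members.pop(victim)
    return archive


def sample_scale_factor(
    memory: HistoryMemory, rng: np.random.Generator
) -> float:
    """Draw F ~ Cauchy(random memory slot, 0.1), clamped into (0, 1]."""
    loc = float(memory.values[rng.integers(len(memory.values))])
    while True:
        f = loc + 0.1 * float(rng.standard_cauchy())
        if f > 1.0:
            return 1.0
        if f > 0.0:
            return f


def update_memory(
    memory: HistoryMemory, successes: list[tuple[float, float]]
) -> HistoryMemory:
    """Record winning F values as a Δf-weighted Lehmer mean.

    With no successes, the slot copies the previous slot's value
    (the memory itself is otherwise unaltered).
    """
    idx = memory.k_index
    if successes:
        fs = np.array([s[0] for s in successes])
        dfs = np.array([s[1] for s in successes])
        total = dfs.sum()
        w = dfs / total if total > 0 else np.full(len(dfs), 1.0 / len(dfs))
        memory.values[idx] = float((w * fs**2).sum() / (w * fs).sum())
    else:
        memory.values[idx] = memory.values[idx - 1]
    memory.k_index = (idx + 1) % len(memory.values)
    return memory


def pareto_front(
    scored: dict[tuple[int, ...], ObjectivePair]
) -> list[tuple[tuple[int, ...], ObjectivePair]]:
    """Nondominated combinations under minimization of (k2, lr).

    Sorted by K2 ascending; ties resolved lexicographically on the
    index tuple.
    """
    items = sorted(scored.items(), key=lambda kv: (kv[1].k2, kv[1].lr, kv[0]))
    front: list[tuple[tuple[int, ...], ObjectivePair]] = []
    best_lr = math.inf
    for combo, pair in items:
        if pair.lr < best_lr:
            front.append((combo, pair))
            best_lr = pair.lr
    return front


def run_search(
    dataset: GenotypeDataset,
    config: RunConfig,
    rng: np.random.Generator | None = None,
) -> DetectionResult:
    """Run the full spherical evolutionary multi-objective search.

    Returns the nondominated set of all distinct SNP combinations
    evaluated within the budget, sorted by K2.  Identical seeds and
    inputs reproduce the result exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k = config.order_k
    n_snps = dataset.n_snps
    if not 2 <= k < n_snps:
        raise ValueError("need 2 ≤ order_k < n_snps")
    np_size = config.population_size
    budget = config.resolved_budget(n_snps)
    scheme = generate_weights(np_size, config.resolved_neighborhood_size())
    theta = config.pbi_theta
    weights = [(float(w[0]), float(w[1])) for w in scheme.weights]
    w_norms = [math.hypot(w0, w1) for w0, w1 in weights]

    scorer = DatasetScorer(dataset, lr_direction=config.lr_direction)
    cache: dict[tuple[int, ...], ObjectivePair] = {}
    evaluations = 0

    def evaluate(decoded: tuple[int, ...]) -> ObjectivePair:
        nonlocal evaluations
        evaluations += 1
        pair = cache.get(decoded)
        if pair is None:
            pair = scorer(decoded)
            cache[decoded] = pair
        return pair

    population = []
    for _ in range(np_size):
        pos = rng.uniform(0.0, n_snps, size=k)
        decoded = decode_position(pos, n_snps)
        population.append(Individual(pos, decoded, evaluate(decoded)))

    archive = Archive(capacity=config.archive_capacity_factor * np_size)
    memory = HistoryMemory.initial(config.memory_size)

    # running raw-objective bounds for min–max normalization; the
    # reference point is the componentwise minimum of all normalized
    # vectors, which is pinned at the origin by the scaling itself
    lo0 = lo1 = math.inf
    hi0 = hi1 = -math.inf

    def absorb(pair: ObjectivePair) -> None:
        nonlocal lo0, lo1, hi0, hi1
        if pair.k2 < lo0:
            lo0 = pair.k2
        if pair.k2 > hi0:
            hi0 = pair.k2
        if pair.lr < lo1:
            lo1 = pair.lr
        if pair.lr > hi1:
            hi1 = pair.lr

    for ind in population:
        absorb(ind.objectives)

    def scalar_fitness(pair: ObjectivePair, i: int) -> float:
        span0 = hi0 - lo0
        span1 = hi1 - lo1
        fx0 = (pair.k2 - lo0) / span0 if span0 > 0 else 0.0
        fx1 = (pair.lr - lo1) / span1 if span1 > 0 else 0.0
        w0, w1 = weights[i]
        norm = w_norms[i]
        d1 = abs(fx0 * w0 + fx1 * w1) / norm
        px = fx0 - d1 * w0 / norm
        py = fx1 - d1 * w1 / norm
        return d1 + theta * math.hypot(px, py)

    n_pbest = max(1, math.ceil(config.pbest_fraction * np_size))
    generation = 0
    while evaluations + np_size <= budget:
        generation += 1
        fitness = np.array(
            [
                scalar_fitness(ind.objectives, i)
                for i, ind in enumerate(population)
            ]
        )
        elite = [int(j) for j in np.argsort(fitness, kind="stable")[:n_pbest]]
        successes: list[tuple[float, float]] = []
        for i, parent in enumerate(population):
            f = sample_scale_factor(memory, rng)
            pbest = population[elite[int(rng.integers(n_pbest))]]
            r1 = int(rng.integers(np_size))
            while r1 == i:
                r1 = int(rng.integers(np_size))
            pool = np_size + len(archive)
            r2 = int(rng.integers(pool))
            while r2 == i or r2 == r1:
                r2 = int(rng.integers(pool))
            xr2 = (
                population[r2].position
                if r2 < np_size
                else archive.members[r2 - np_size].position
            )
            trial_pos = crossover(
                parent.position,
                mutate(
                    parent.position,
                    pbest.position,
                    population[r1].position,
                    xr2,
                    f,
                    n_snps,
                    rng,
                ),
                config.crossover_rate,
                rng,
            )
            decoded = decode_position(trial_pos, n_snps)
            pair = evaluate(decoded)
            absorb(pair)
            f_parent = scalar_fitness(parent.objectives, i)
            f_trial = scalar_fitness(pair, i)
            if f_trial < f_parent:
                update_archive(archive, parent, rng)
                successes.append((f, abs(f_trial - f_parent)))
                population[i] = Individual(trial_pos, decoded, pair)
        update_memory(memory, successes)
        if logger.isEnabledFor(logging.INFO):
            best_k2 = min(p.k2 for p in cache.values())
            best_g = max(p.raw_g for p in cache.values())
            logger.info(
                "gen=%d evals=%d best_k2=%.3f best_g=%.3f archive=%d mean_mF=%.3f",
                generation,
                evaluations,
                best_k2,
                best_g,
                len(archive),
                float(memory.values.mean()),
            )

    front = pareto_front(cache)
    records = [
        DetectionRecord(
            snp_indices=combo,
            snp_names=dataset.names_for(combo),
            k2=pair.k2,
            lr=pair.lr,
            raw_g=pair.raw_g,
        )
        for combo, pair in front
    ]
    return DetectionResult(
        records=records,
        n_evaluations=evaluations,
        n_unique_evaluated=len(cache),
        config=config,
    )
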