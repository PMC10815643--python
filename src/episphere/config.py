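"""Run configuration for the evolutionary search and validation stages.

Every tunable of the search engine, the decomposition, and the
validation filters lives here so that a run is fully described by a
(dataset, config, seed) triple.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Parameters of a detection run.

    Attributes
    ----------
    order_k
        Interaction order searched (number of SNPs per combination).
    population_size
        NP, number of concurrently evolving candidate vectors; also the
        number of scalar subproblems in the decomposition.
    max_evaluations
        Total objective-evaluation budget, including the initial
        population.  ``None`` sizes the budget automatically as
        ``coverage_multiplier × C(n_snps, order_k)`` (capped below by
        one generation), so that a search without marginal signal is
        coverage-converged.
    coverage_multiplier
        Budget multiplier used when ``max_evaluations`` is ``None``.
    archive_capacity_factor
        External archive capacity as a multiple of ``population_size``.
    memory_size
        H, number of slots in the success-history memory for the
        spherical scale factor F.
    pbest_fraction
        p ∈ (0, 1]: mutation directs toward a random member of the top
        ``ceil(p·NP)`` individuals; smaller is greedier.
    crossover_rate
        CR of the binomial crossover.
    pbi_theta
        θ ≥ 0, penalty of the boundary-intersection scalarization.
    neighborhood_size
        K, weight-vector neighborhood size; ``None`` → max(2, NP // 10).
    seed
        Seed for the single random generator driving the run.
    g_test_alpha
        Family-wise significance level of the G-test validation filter.
    mdr_accuracy_min
        Balanced-accuracy threshold of the MDR validation filter.
    mdr_folds
        Cross-validation folds used by MDR.
    lr_direction
        'negated' stores −G as the second objective so that minimizing
        favors association; 'raw' stores +G unchanged.
    expected_mode
        'margins' derives expected counts from both table margins
        (classical G-test); 'hwe' derives row expectations from
        Hardy–Weinberg genotype frequencies.
    """

    order_k: int = 2
    population_size: int = 100
    max_evaluations: int | None = None
    coverage_multiplier: float = 4.0
    archive_capacity_factor: int = 2
    memory_size: int = 5
    pbest_fraction: float = 0.1
    crossover_rate: float = 0.5
    pbi_theta: float = 5.0
    neighborhood_size: int | None = None
    seed: int = 0
    g_test_alpha: float = 0.05
    mdr_accuracy_min: float = 0.55
    mdr_folds: int = 10
    lr_direction: str = "negated"
    expected_mode: str = "margins"

    def __post_init__(self) -> None:
        if self.order_k < 2:
            raise ValueError("order_k must be at least 2")
        if self.population_size < 4:
            raise ValueError(
                "population_size must be ≥ 4 (mutation needs distinct "
                "r1, r2, pbest and self)"
            )
        if not 0 < self.pbest_fraction <= 1:
            raise ValueError("pbest_fraction must be in (0, 1]")
        if self.memory_size < 1:
            raise ValueError("memory_size must be ≥ 1")
        if self.pbi_theta < 0:
            raise ValueError("pbi_theta must be ≥ 0")
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.archive_capacity_factor < 1:
            raise ValueError("archive_capacity_factor must be ≥ 1")
        if self.lr_direction not in ("negated", "raw"):
            raise ValueError("lr_direction must be 'negated' or 'raw'")
        if self.expected_mode not in ("margins", "hwe"):
            raise ValueError("expected_mode must be 'margins' or 'hwe'")
        if (
            self.neighborhood_size is not None
            and self.neighborhood_size > self.population_size
        ):
            raise ValueError("neighborhood_size cannot exceed population_size")

    def resolved_neighborhood_size(self) -> int:
        if self.neighborhood_size is not None:
            return self.neighborhood_size
        return max(2, self.population_size // 10)

    def resolved_budget(self, n_snps: int) -> int:
        """Evaluation budget for a panel of ``n_snps`` loci."""
        if self.max_evaluations is not None:
            return self.max_evaluations
        space = math.comb(n_snps, self.order_k)
        budget = int(round(self.coverage_multiplier * space))
        return max(budget, 2 * self.population_size)

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
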