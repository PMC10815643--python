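"""Brute-force enumeration over all k-SNP combinations.

Feasible only for small panels; serves as the reference against which
the stochastic search is checked, and as a fallback detector.
"""

from __future__ import annotations

import itertools

from .dataset import GenotypeDataset
from .engine import pareto_front
from .scoring import DatasetScorer, ObjectivePair

__all__ = ["exhaustive_scores", "exhaustive_front", "exhaustive_best_k2"]


def exhaustive_scores(
    dataset: GenotypeDataset, k: int = 2, lr_direction: str = "negated"
) -> dict[tuple[int, ...], ObjectivePair]:
    """Score every C(n_snps, k) combination."""
    scorer = DatasetScorer(dataset, lr_direction=lr_direction)
    return {
        combo: scorer(combo)
        for combo in itertools.combinations(range(dataset.n_snps), k)
    }


def exhaustive_front(
    dataset: GenotypeDataset, k: int = 2, lr_direction: str = "negated"
) -> list[tuple[tuple[int, ...], ObjectivePair]]:
    """Nondominated set of the full enumeration, sorted by K2."""
    return pareto_front(exhaustive_scores(dataset, k, lr_direction))


def exhaustive_best_k2(
    dataset: GenotypeDataset, k: int = 2
) -> tuple[tuple[int, ...], float]:
    scores = exhaustive_scores(dataset, k)
    combo = min(scores, key=lambda c: (scores[c].k2, c))
    return combo, scores[combo].k2
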