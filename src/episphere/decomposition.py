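"""Decomposition of the bi-objective (K2, LR) problem into scalar
subproblems, MOEA/D style.

Each population slot owns one weight vector on the 2-simplex and is
scored by the penalty boundary intersection (PBI) aggregation
d1 + θ·d2, where d1 is the projection of the normalized objective
vector onto the weight ray through the reference point and d2 the
perpendicular distance to that ray.  Objectives are min–max normalized
over the pool of everything evaluated so far, because K2 (log-marginal
likelihood scale) and the G statistic live on incommensurate scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import ObjectivePair

__all__ = [
    "WeightScheme",
    "ReferencePoint",
    "generate_weights",
    "normalize_objectives",
    "pbi_aggregate",
    "update_reference",
    "best_by_subproblem",
]


@dataclass
class WeightScheme:
    """NP unit-simplex weight vectors with K-nearest neighborhoods."""

    weights: np.ndarray  # NP × 2
    neighborhoods: np.ndarray  # NP × K indices
    k: int


@dataclass
class ReferencePoint:
    """Componentwise best (minimum) normalized objective values seen."""

    r: np.ndarray

    @classmethod
    def initial(cls) -> "ReferencePoint":
        return cls(np.full(2, np.inf))


def generate_weights(np_size: int, k: int | None = None) -> WeightScheme:
    """Uniform simplex lattice ω_i = (i/(NP−1), 1 − i/(NP−1)).

    Neighborhoods are the K nearest weights by Euclidean distance
    (ties broken by lower index) and always contain the weight itself.
    """
    if np_size < 2:
        raise ValueError("need at least 2 weight vectors")
    t = np.arange(np_size) / (np_size - 1)
    weights = np.column_stack([t, 1.0 - t])
    if k is None:
        k = max(2, np_size // 10)
    k = min(k, np_size)
    dists = np.abs(t[:, None] - t[None, :])  # Euclidean ∝ |t_i − t_j| here
    # stable argsort on (distance, index) implements the tie-break
    order = np.argsort(dists, axis=1, kind="stable")
    neighborhoods = order[:, :k]
    return WeightScheme(weights=weights, neighborhoods=neighborhoods, k=k)


def normalize_objectives(
    pairs: list[ObjectivePair],
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Min–max scale (k2, lr) pairs into [0, 1]².

    ``bounds`` optionally fixes (min, max) per coordinate (e.g. the
    running bounds over every evaluation so far); otherwise the bounds
    of the given pool are used.  A constant coordinate maps to 0.
    """
    if not pairs:
        raise ValueError("empty objective pool")
    raw = np.array([[p.k2, p.lr] for p in pairs], dtype=np.float64)
    if bounds is None:
        lo, hi = raw.min(axis=0), raw.max(axis=0)
    else:
        lo, hi = bounds
    span = hi - lo
    out = np.zeros_like(raw)
    for j in range(2):
        if span[j] > 0:
            out[:, j] = (raw[:, j] - lo[j]) / span[j]
    return out


def pbi_aggregate(
    fx: np.ndarray, omega: np.ndarray, ref: ReferencePoint, theta: float
) -> float:
    """Penalty boundary intersection value d1 + θ·d2.

    d1 = |(fx − r)·ω| / ‖ω‖ is the length of the projection of
    fx − r onto the weight direction; d2 is the distance from fx to
    the line through r along ω.
    """
    omega = np.asarray(omega, dtype=np.float64)
    norm = np.linalg.norm(omega)
    if norm == 0:
        raise ValueError("zero weight vector")
    diff = np.asarray(fx, dtype=np.float64) - ref.r
    d1 = abs(float(diff @ omega)) / norm
    d2 = float(np.linalg.norm(diff - d1 * omega / norm))
    return d1 + theta * d2


def update_reference(ref: ReferencePoint, fx: np.ndarray) -> ReferencePoint:
    """Fold a new normalized objective vector into the reference point."""
    return ReferencePoint(np.minimum(ref.r, np.asarray(fx, dtype=np.float64)))


def best_by_subproblem(
    candidates: list[tuple[tuple[int, ...], ObjectivePair]],
    scheme: WeightScheme,
    ref: ReferencePoint,
    theta: float,
) -> list[int]:
    """Index of the PBI-minimizing candidate for every weight vector.

    Ties break by lower K2, then lexicographically smaller SNP tuple.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    pairs = [p for _, p in candidates]
    fx = normalize_objectives(pairs)
    champions: list[int] = []
    for w in scheme.weights:
        best_i = 0
        best_key = None
        for i, (combo, pair) in enumerate(candidates):
            key = (pbi_aggregate(fx[i], w, ref, theta), pair.k2, combo)
            if best_key is None or key < best_key:
                best_key = key
                best_i = i
        champions.append(best_i)
    return champions
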