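"""Simulation of epistatic disease models and case–control panels.

Emulates a GAMETES-style generator: a k-locus penetrance table is
searched at random to match a target minor-allele frequency (MAF),
heritability h² and prevalence P(D); disease models either carry
single-locus marginal effects (DME) or have them flattened away so the
signal is purely epistatic (DNME).  Datasets embed one such
interaction among background SNPs drawn independently of phenotype.

Heritability follows the variance-explained definition

    h² = Σ_g P(g) · (f_g − P(D))² / (P(D)·(1 − P(D)))

with P(g) the Hardy–Weinberg joint-genotype probability and f_g the
penetrance of genotype g.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .dataset import GenotypeDataset

__all__ = [
    "DiseaseModelSpec",
    "PenetranceTable",
    "TruthRecord",
    "InfeasibleModelError",
    "genotype_prob",
    "joint_genotype_probs",
    "table_heritability",
    "table_prevalence",
    "marginal_penetrances",
    "marginal_deviation",
    "random_penetrance_table",
    "generate_dataset",
    "model_suite",
]

DEFAULT_PREVALENCE = 0.2


class InfeasibleModelError(RuntimeError):
    """No penetrance table satisfying the spec was found."""


@dataclass(frozen=True)
class DiseaseModelSpec:
    """Target parameters of one simulated disease model.

    ``prevalence=None`` leaves the population disease probability
    unconstrained (it settles wherever the random table search lands),
    which is required for flat-marginal models at high heritability —
    the variance a bounded penetrance table can carry at a fixed
    prevalence is limited.
    """

    maf: float
    h2: float
    prevalence: float | None = DEFAULT_PREVALENCE
    order: int = 2
    marginal_effects: bool = False  # False → DNME, True → DME
    h2_tolerance: float = 0.01
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if not 0 <= self.h2 < 1:
            raise ValueError("h2 must be in [0, 1)")
        if self.prevalence is not None and not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.order < 2:
            raise ValueError("order must be ≥ 2")


@dataclass
class PenetranceTable:
    """3^k penetrance values indexed by joint genotype (base-3 order)."""

    probs: np.ndarray
    spec: DiseaseModelSpec
    achieved_h2: float = 0.0
    achieved_prevalence: float = 0.0
    marginal_dev: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        k = self.spec.order
        if self.probs.shape != (3**k,):
            raise ValueError(f"expected {3 ** k} penetrance values")
        if ((self.probs < -1e-12) | (self.probs > 1 + 1e-12)).any():
            raise ValueError("penetrances must lie in [0, 1]")
        self.probs = np.clip(self.probs, 0.0, 1.0)


@dataclass
class TruthRecord:
    """Ground truth of one simulated dataset."""

    dataset_id: str
    snp_indices: tuple[int, ...]
    spec: DiseaseModelSpec
    labels: tuple[str, ...] = field(default_factory=tuple)


def genotype_prob(genotype: int, maf: float) -> float:
    """Hardy–Weinberg probability of a single-locus genotype."""
    q = maf
    if genotype == 0:
        return (1 - q) ** 2
    if genotype == 1:
        return 2 * q * (1 - q)
    if genotype == 2:
        return q**2
    raise ValueError(f"genotype must be 0, 1 or 2, got {genotype}")


def joint_genotype_probs(mafs: np.ndarray | list[float]) -> np.ndarray:
    """HWE joint-genotype probabilities for k loci, base-3 ordering."""
    mafs = np.asarray(mafs, dtype=np.float64)
    probs = np.ones(1)
    for q in mafs:
        single = np.array([genotype_prob(g, q) for g in (0, 1, 2)])
        probs = np.kron(probs, single)
    return probs


def table_prevalence(probs: np.ndarray, mafs) -> float:
    return float(joint_genotype_probs(mafs) @ np.asarray(probs))


def table_heritability(table: PenetranceTable | np.ndarray, mafs) -> float:
    """Variance-explained heritability of a penetrance table."""
    probs = table.probs if isinstance(table, PenetranceTable) else table
    p_g = joint_genotype_probs(mafs)
    pd = float(p_g @ probs)
    if pd <= 0 or pd >= 1:
        return 0.0
    return float(p_g @ (probs - pd) ** 2 / (pd * (1 - pd)))


def marginal_penetrances(
    table: PenetranceTable | np.ndarray, mafs
) -> np.ndarray:
    """Single-locus marginal penetrance vectors, one length-3 row per locus."""
    probs = np.asarray(
        table.probs if isinstance(table, PenetranceTable) else table
    )
    mafs = np.asarray(mafs, dtype=np.float64)
    k = len(mafs)
    cube = probs.reshape((3,) * k)
    p_g = joint_genotype_probs(mafs).reshape((3,) * k)
    out = np.zeros((k, 3))
    for locus in range(k):
        axes = tuple(a for a in range(k) if a != locus)
        joint = (cube * p_g).sum(axis=axes)
        mass = p_g.sum(axis=axes)
        out[locus] = joint / mass
    return out


def marginal_deviation(table: PenetranceTable | np.ndarray, mafs) -> float:
    probs = table.probs if isinstance(table, PenetranceTable) else table
    mafs = np.asarray(mafs, dtype=np.float64)
    pd = table_prevalence(probs, mafs)
    marg = marginal_penetrances(probs, mafs)
    return float(np.abs(marg - pd).max())


def _flatten_marginals(
    probs: np.ndarray, p_cube: np.ndarray, target: float, k: int
) -> np.ndarray:
    """One sweep of iterative proportional fitting toward flat marginals."""
    cube = probs.reshape((3,) * k).copy()
    for locus in range(k):
        axes = tuple(a for a in range(k) if a != locus)
        joint = (cube * p_cube).sum(axis=axes)
        mass = p_cube.sum(axis=axes)
        marg = joint / mass
        ratio = np.where(marg > 0, target / np.maximum(marg, 1e-12), 1.0)
        shape = [1] * k
        shape[locus] = 3
        cube = cube * ratio.reshape(shape)
    return cube.reshape(-1)


def random_penetrance_table(
    spec: DiseaseModelSpec,
    rng: np.random.Generator,
    max_restarts: int = 500,
    max_iters: int = 400,
    marginal_tol: float = 1e-3,
) -> PenetranceTable:
    """Search for a random penetrance table matching ``spec``.

    Random tables are alternately rescaled toward the target prevalence
    and heritability; for DNME models an iterative proportional sweep
    additionally projects every single-locus marginal onto the
    prevalence.  Restarts from a fresh random table when the iteration
    stalls (clipping at [0, 1] can make a particular draw infeasible).
    """
    k = spec.order
    mafs = np.full(k, spec.maf)
    p_g = joint_genotype_probs(mafs)
    p_cube = p_g.reshape((3,) * k)
    target_pd, target_h2 = spec.prevalence, spec.h2

    if target_h2 == 0:
        pd0 = target_pd if target_pd is not None else DEFAULT_PREVALENCE
        probs = np.full(3**k, pd0)
        return PenetranceTable(
            probs, spec, 0.0, pd0, marginal_deviation(probs, mafs)
        )

    h2_tol = spec.h2_tolerance
    for _ in range(max_restarts):
        f = rng.uniform(0.0, 1.0, size=3**k)
        ok = False
        for _ in range(max_iters):
            pd = float(p_g @ f)
            if pd <= 0:
                break
            # 1. prevalence (skipped when unconstrained)
            if target_pd is not None:
                f = np.clip(f * (target_pd / pd), 0.0, 1.0)
                pd = float(p_g @ f)
            # 2. flat marginals for purely epistatic models
            if not spec.marginal_effects:
                f = np.clip(_flatten_marginals(f, p_cube, pd, k), 0.0, 1.0)
            # 3. heritability: spread about the prevalence
            pd = float(p_g @ f)
            h2 = table_heritability(f, mafs)
            if h2 <= 0 or pd <= 0 or pd >= 1:
                break
            s = np.sqrt(target_h2 / h2)
            f = np.clip(pd + s * (f - pd), 0.0, 1.0)

            pd = float(p_g @ f)
            h2 = table_heritability(f, mafs)
            dev = (
                marginal_deviation(f, mafs)
                if not spec.marginal_effects
                else 0.0
            )
            pd_ok = target_pd is None or abs(pd - target_pd) < 1e-4
            if (
                pd_ok
                and abs(h2 - target_h2) < min(h2_tol, 0.5 * 0.02)
                and dev < marginal_tol
            ):
                ok = True
                break
        if ok:
            return PenetranceTable(
                f,
                spec,
                achieved_h2=table_heritability(f, mafs),
                achieved_prevalence=float(p_g @ f),
                marginal_dev=marginal_deviation(f, mafs),
            )
    raise InfeasibleModelError(
        f"no penetrance table found for {spec} after {max_restarts} restarts"
    )


def generate_dataset(
    spec: DiseaseModelSpec,
    n_cases: int,
    n_controls: int,
    n_snps: int,
    rng: np.random.Generator,
    table: PenetranceTable | None = None,
    dataset_id: str = "sim",
    max_batches: int = 10_000,
) -> tuple[GenotypeDataset, TruthRecord]:
    """Simulate a balanced case–control panel with one embedded interaction.

    Disease-locus genotypes are drawn under HWE at ``spec.maf`` and the
    phenotype from the penetrance table; samples are accumulated by
    rejection until exactly ``n_cases`` and ``n_controls`` are reached.
    Background SNPs are phenotype-independent with MAF ~ U(0.01, 0.5).
    """
    k = spec.order
    if n_snps <= k:
        raise ValueError("n_snps must exceed the interaction order")
    if table is None:
        table = random_penetrance_table(spec, rng)
    mafs = np.full(k, spec.maf)
    p_g = joint_genotype_probs(mafs)

    want = {1: n_cases, 0: n_controls}
    got: dict[int, list[np.ndarray]] = {0: [], 1: []}
    counts = {0: 0, 1: 0}
    batch = max(4 * (n_cases + n_controls), 1024)
    for _ in range(max_batches):
        if counts[0] >= want[0] and counts[1] >= want[1]:
            break
        codes = rng.choice(3**k, size=batch, p=p_g)
        y = (rng.random(batch) < table.probs[codes]).astype(np.int8)
        for cls in (0, 1):
            need = want[cls] - counts[cls]
            if need > 0:
                take = codes[y == cls][:need]
                got[cls].append(take)
                counts[cls] += len(take)
    else:
        raise InfeasibleModelError(
            f"could not accumulate {n_cases}/{n_controls} samples for {spec}"
        )

    codes_all = np.concatenate(
        [np.concatenate(got[1]), np.concatenate(got[0])]
    )
    pheno = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    perm = rng.permutation(len(pheno))
    codes_all, pheno = codes_all[perm], pheno[perm]

    # decode base-3 joint codes into per-locus genotypes
    disease_geno = np.empty((len(pheno), k), dtype=np.int8)
    rem = codes_all.copy()
    for pos in range(k - 1, -1, -1):
        disease_geno[:, pos] = rem % 3
        rem //= 3

    n = n_cases + n_controls
    n_bg = n_snps - k
    bg_maf = rng.uniform(0.01, 0.5, size=n_bg)
    background = rng.binomial(2, bg_maf[None, :], size=(n, n_bg)).astype(
        np.int8
    )

    positions = np.sort(rng.choice(n_snps, size=k, replace=False))
    genotypes = np.empty((n, n_snps), dtype=np.int8)
    bg_cols = [j for j in range(n_snps) if j not in set(positions)]
    genotypes[:, bg_cols] = background
    genotypes[:, positions] = disease_geno

    labels = tuple(f"M{i}P{i}" for i in range(k))
    names = [f"N{j}" for j in range(n_snps)]
    for lab, pos in zip(labels, positions):
        names[pos] = lab
    truth = TruthRecord(
        dataset_id=dataset_id,
        snp_indices=tuple(int(p) for p in positions),
        spec=spec,
        labels=labels,
    )
    dataset = GenotypeDataset(
        genotypes=genotypes,
        phenotype=pheno,
        snp_names=names,
        truth=[truth.snp_indices],
    )
    return dataset, truth


def model_suite(kind: str) -> list[DiseaseModelSpec]:
    """The simulated disease-model grids.

    ``dnme``: 10 purely epistatic models — MAF ∈ {0.2, 0.4} crossed
    with h² ∈ {0.01, 0.05, 0.1, 0.2, 0.4} (the 0.1 slots fill the grid
    out to ten models).  ``dme``: 12 marginal-effect models —
    MAF ∈ {0.05, 0.1, 0.2, 0.5} crossed with h² ∈ {0.005, 0.05, 0.2}.
    """
    kind = kind.lower()
    if kind == "dnme":
        grid = itertools.product((0.2, 0.4), (0.01, 0.05, 0.1, 0.2, 0.4))
        return [
            DiseaseModelSpec(
                maf=maf,
                h2=h2,
                # at h²=0.4 a flat-marginal table cannot hold the default
                # prevalence (bounded penetrance variance); leave it free
                prevalence=None if h2 >= 0.4 else DEFAULT_PREVALENCE,
                marginal_effects=False,
                name=f"DNME{i + 1}",
            )
            for i, (maf, h2) in enumerate(grid)
        ]
    if kind == "dme":
        grid = itertools.product((0.05, 0.1, 0.2, 0.5), (0.005, 0.05, 0.2))
        return [
            DiseaseModelSpec(
                maf=maf,
                h2=h2,
                marginal_effects=True,
                name=f"DME{i + 1}",
            )
            for i, (maf, h2) in enumerate(grid)
        ]
    raise ValueError("kind must be 'dme' or 'dnme'")
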