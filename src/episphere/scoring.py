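"""Association statistics for SNP combinations.

All statistics operate on an I×2 contingency table of joint-genotype
counts split by phenotype.  Two scores drive the evolutionary search:

* ``k2_score`` — the negative log of the Bayesian-network marginal
  likelihood (K2 metric) of the genotype→phenotype structure.  Lower
  values mean stronger association.  The product form

      Π_i (J−1)! / (N_i + J−1)! · Π_j N_ij!

  overflows factorials for realistic sample sizes, so it is evaluated
  in log space with the log-gamma function; −ln is monotone decreasing,
  which preserves the lower-is-stronger ordering.

* ``lr_score`` — the likelihood-ratio goodness-of-fit statistic
  G = 2 Σ_ij N_ij ln(N_ij / E_ij) against the no-association
  expectation.  G grows with association; the search minimizes the
  negated value by default (see :class:`ObjectivePair`).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .dataset import GenotypeDataset

__all__ = [
    "ContingencyTable",
    "ObjectivePair",
    "build_contingency",
    "k2_score",
    "expected_counts",
    "lr_score",
    "pearson_chi2",
    "g_test",
    "DatasetScorer",
]


@dataclass(frozen=True)
class ObjectivePair:
    """Bi-objective score of one SNP combination.

    ``k2`` and ``lr`` are both minimization-oriented: with the default
    ``lr_direction='negated'`` the second objective stores −G, so a
    stronger association lowers both coordinates.  ``raw_g`` keeps the
    untransformed G statistic for the validation stage.
    """

    k2: float
    lr: float
    raw_g: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.k2, self.lr])


@dataclass
class ContingencyTable:
    """Joint-genotype × phenotype counts for a k-SNP combination.

    Rows are the joint genotypes actually observed (at most 3^k),
    column 0 counts controls and column 1 counts cases.  ``hwe_probs``
    optionally carries the Hardy–Weinberg probability of each row's
    joint genotype (allele frequencies estimated from the same
    samples), used by the ``expected_mode='hwe'`` variant.
    """

    counts: np.ndarray
    row_labels: list[tuple[int, ...]]
    hwe_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError("counts must be an I×2 matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("contingency table has no observations")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]


def _joint_codes(
    genotypes: np.ndarray, snp_indices: tuple[int, ...]
) -> np.ndarray:
    """Base-3 encoding of the joint genotype of the selected SNPs."""
    codes = np.zeros(genotypes.shape[0], dtype=np.int64)
    for idx in snp_indices:
        codes = codes * 3 + genotypes[:, idx]
    return codes


def build_contingency(
    dataset: GenotypeDataset, snp_indices: tuple[int, ...]
) -> ContingencyTable:
    """Count joint genotypes of ``snp_indices`` split by phenotype.

    One row per joint genotype observed in the data; column 0 counts
    controls, column 1 cases.
    """
    snp_indices = tuple(int(i) for i in snp_indices)
    if len(set(snp_indices)) != len(snp_indices):
        raise ValueError(f"duplicate SNP indices {snp_indices}")
    for i in snp_indices:
        if not 0 <= i < dataset.n_snps:
            raise ValueError(f"SNP index {i} out of range")
    k = len(snp_indices)
    codes = _joint_codes(dataset.genotypes, snp_indices)
    flat = np.bincount(codes * 2 + dataset.phenotype, minlength=2 * 3**k)
    table = flat.reshape(3**k, 2)
    observed = table.sum(axis=1) > 0
    labels = [
        tuple((code // 3**p) % 3 for p in range(k - 1, -1, -1))
        for code in np.nonzero(observed)[0]
    ]
    # per-locus allele frequencies for the optional HWE expectation
    freqs = [dataset.genotypes[:, i].mean() / 2.0 for i in snp_indices]
    hwe = np.array(
        [
            np.prod([_hwe_prob(g, q) for g, q in zip(label, freqs)])
            for label in labels
        ]
    )
    return ContingencyTable(table[observed], labels, hwe)


def _hwe_prob(genotype: int, q: float) -> float:
    if genotype == 0:
        return (1 - q) ** 2
    if genotype == 1:
        return 2 * q * (1 - q)
    return q**2


@functools.lru_cache(maxsize=8)
def _lgamma_table(n: int) -> np.ndarray:
    # _lgamma_table(n)[m] == ln(Γ(m)) == ln((m-1)!) for m up to n+2
    return gammaln(np.arange(n + 3, dtype=np.float64))


def k2_score(table: ContingencyTable) -> float:
    """Negative log of the K2 Bayesian marginal-likelihood product.

    Returns Σ_i [ ln((N_i+1)!) − Σ_j ln(N_ij!) ] for J = 2 phenotype
    states; lower values indicate stronger association.
    """
    lg = _lgamma_table(table.n)
    n_i = table.counts.sum(axis=1)
    return float(
        (lg[n_i + 2] - lg[table.counts + 1].sum(axis=1)).sum()
    )


def expected_counts(
    table: ContingencyTable, mode: str = "margins"
) -> np.ndarray:
    """No-association expected counts E_ij.

    ``mode='margins'`` uses the classical two-way independence
    expectation (row total × column total) / N.  ``mode='hwe'`` derives
    row expectations from Hardy–Weinberg joint-genotype probabilities
    at the sample allele frequencies, scaled by the column totals.
    """
    n = table.n
    if n == 0:
        raise ValueError("zero grand total")
    col = table.counts.sum(axis=0).astype(np.float64)
    if mode == "margins":
        row = table.counts.sum(axis=1).astype(np.float64)
        return np.outer(row, col) / n
    if mode == "hwe":
        if table.hwe_probs is None:
            raise ValueError("table carries no HWE probabilities")
        return np.outer(table.hwe_probs, col)
    raise ValueError(f"unknown expected-counts mode {mode!r}")


def lr_score(table: ContingencyTable, mode: str = "margins") -> float:
    """Likelihood-ratio statistic G = 2 Σ N_ij ln(N_ij / E_ij).

    Cells with N_ij = 0 contribute 0 by the 0·ln(0) convention.
    """
    expected = expected_counts(table, mode)
    observed = table.counts.astype(np.float64)
    mask = observed > 0
    g = 2.0 * np.sum(
        observed[mask] * np.log(observed[mask] / expected[mask])
    )
    return float(max(g, 0.0))


def _df(table: ContingencyTable) -> int:
    return (table.n_rows - 1) * (table.counts.shape[1] - 1)


def pearson_chi2(
    table: ContingencyTable, mode: str = "margins"
) -> tuple[float, int, float]:
    """Pearson χ² statistic, degrees of freedom, and upper-tail p.

    Cells with E_ij = 0 contribute 0.  With df ≤ 0 the p-value is 1.
    """
    expected = expected_counts(table, mode)
    observed = table.counts.astype(np.float64)
    mask = expected > 0
    stat = float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))
    df = _df(table)
    if df <= 0:
        return stat, df, 1.0
    return stat, df, float(chi2_dist.sf(stat, df))


def g_test(
    table: ContingencyTable, mode: str = "margins"
) -> tuple[float, int, float]:
    """G-test of independence: the ``lr_score`` statistic with a χ² tail."""
    stat = lr_score(table, mode)
    df = _df(table)
    if df <= 0:
        return stat, df, 1.0
    return stat, df, float(chi2_dist.sf(stat, df))


def score_combination(
    dataset: GenotypeDataset,
    snp_indices: tuple[int, ...],
    lr_direction: str = "negated",
) -> ObjectivePair:
    """Convenience wrapper scoring one combination on both objectives."""
    table = build_contingency(dataset, snp_indices)
    k2 = k2_score(table)
    g = lr_score(table)
    lr = -g if lr_direction == "negated" else g
    return ObjectivePair(k2=k2, lr=lr, raw_g=g)


class DatasetScorer:
    """Vectorized repeat scorer bound to one dataset.

    Precomputes the phenotype offsets and the log-gamma table once, so
    the evolutionary engine can score tens of thousands of
    combinations cheaply.  Produces values identical to
    :func:`score_combination`.
    """

    def __init__(self, dataset: GenotypeDataset, lr_direction: str = "negated"):
        self.dataset = dataset
        self.lr_direction = lr_direction
        self._geno = dataset.genotypes.astype(np.int64)
        self._pheno = dataset.phenotype.astype(np.int64)
        self._lg = _lgamma_table(dataset.n_samples)
        self._n_cases = float(dataset.n_cases)
        self._n_controls = float(dataset.n_controls)
        self._n = float(dataset.n_samples)
        # precomputed digit planes: flat cell index of a pair (i, j) is
        # 6·g_i + 2·g_j + phenotype, so pair scoring is two adds + bincount
        self._col6 = np.ascontiguousarray(self._geno.T * 6)
        self._col2p = np.ascontiguousarray(self._geno.T * 2 + self._pheno)

    def _counts(self, snp_indices: tuple[int, ...]) -> np.ndarray:
        if len(snp_indices) == 2:
            i, j = snp_indices
            flat = np.bincount(self._col6[i] + self._col2p[j], minlength=18)
            return flat.reshape(9, 2)
        codes = np.zeros(self._geno.shape[0], dtype=np.int64)
        for idx in snp_indices:
            codes = codes * 3 + self._geno[:, idx]
        k = len(snp_indices)
        flat = np.bincount(codes * 2 + self._pheno, minlength=2 * 3**k)
        return flat.reshape(3**k, 2)

    def __call__(self, snp_indices: tuple[int, ...]) -> ObjectivePair:
        counts = self._counts(snp_indices)
        n_i = counts.sum(axis=1)
        observed = n_i > 0
        counts = counts[observed]
        n_i = n_i[observed]
        lg = self._lg
        k2 = float((lg[n_i + 2] - lg[counts + 1].sum(axis=1)).sum())
        # G with margin expectations: E_ij = n_i * col_j / n
        cf = counts.astype(np.float64)
        e = np.outer(n_i.astype(np.float64), [self._n_controls, self._n_cases])
        e /= self._n
        mask = cf > 0
        g = float(max(2.0 * np.sum(cf[mask] * np.log(cf[mask] / e[mask])), 0.0))
        lr = -g if self.lr_direction == "negated" else g
        return ObjectivePair(k2=k2, lr=lr, raw_g=g)
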