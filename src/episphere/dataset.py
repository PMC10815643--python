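"""Case–control genotype data container.

Genotypes are coded by minor-allele count: 0 homozygous major, 1
heterozygous, 2 homozygous minor.  The phenotype is binary with cases
coded 1 and controls 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GenotypeFormatError(ValueError):
    """Raised when a genotype matrix or phenotype vector is malformed."""


@dataclass
class GenotypeDataset:
    """An n_samples × n_snps genotype matrix with a binary phenotype.

    Parameters
    ----------
    genotypes
        Integer matrix with values in {0, 1, 2}; one row per sample,
        one column per SNP.
    phenotype
        Binary vector (1 = case, 0 = control), one entry per sample.
    snp_names
        Unique locus identifiers, one per genotype column.
    truth
        Optional ground-truth pathogenic SNP index tuples (0-based
        column indices), present for simulated data.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_names: list[str]
    truth: list[tuple[int, ...]] | None = field(default=None)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise GenotypeFormatError("genotypes must be a 2-D matrix")
        n, m = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise GenotypeFormatError(
                f"phenotype length {self.phenotype.shape} does not match "
                f"{n} genotype rows"
            )
        if m > 0 and not np.isin(self.genotypes, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(self.genotypes, (0, 1, 2)))[0]
            raise GenotypeFormatError(
                f"genotype value at row {bad[0]}, column {bad[1]} is not in "
                "{0, 1, 2}"
            )
        if not np.isin(self.phenotype, (0, 1)).all():
            bad_row = int(np.argwhere(~np.isin(self.phenotype, (0, 1)))[0][0])
            raise GenotypeFormatError(
                f"phenotype value at row {bad_row} is not binary"
            )
        if len(self.snp_names) != m:
            raise GenotypeFormatError(
                f"{len(self.snp_names)} snp_names for {m} genotype columns"
            )
        if len(set(self.snp_names)) != m:
            raise GenotypeFormatError("snp_names are not unique")
        if self.truth is not None:
            self.truth = [tuple(sorted(int(i) for i in t)) for t in self.truth]
            for t in self.truth:
                if any(i < 0 or i >= m for i in t):
                    raise GenotypeFormatError(
                        f"truth indices {t} out of range for {m} SNPs"
                    )

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return self.n_samples - self.n_cases

    def names_for(self, indices: tuple[int, ...]) -> tuple[str, ...]:
        """Map 0-based column indices to locus identifiers."""
        return tuple(self.snp_names[i] for i in indices)
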