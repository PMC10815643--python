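"""File formats: GAMETES-style genotype text, truth sidecars, result
tables and Cytoscape-loadable SIF interaction networks.

The genotype dialect is tab-delimited text with a header row of SNP
names and a trailing ``Class`` column (1 = case, 0 = control), the
format emitted by the GAMETES simulator family.  A plain ``csv``
dialect (comma-separated, same column layout) is also accepted.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset, GenotypeFormatError
from .engine import DetectionRecord, DetectionResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_truth",
    "write_interaction_network",
    "write_results",
    "read_results",
    "read_results_with_meta",
]

_SEP = {"gametes": "\t", "csv": ","}
CLASS_COLUMN = "Class"


def _truth_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".truth.json")


def read_genotypes(
    path: str | Path, dialect: str = "gametes"
) -> GenotypeDataset:
    """Read a genotype matrix; the last column is the phenotype.

    A sidecar ``<file>.truth.json`` written by :func:`write_genotypes`
    is picked up automatically when present.
    """
    path = Path(path)
    if dialect not in _SEP:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        frame = pd.read_csv(path, sep=_SEP[dialect], dtype=str)
    except pd.errors.ParserError as exc:
        raise GenotypeFormatError(f"{path}: ragged or malformed rows ({exc})")
    if frame.shape[1] < 1:
        raise GenotypeFormatError(f"{path}: no columns")
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax())
        raise GenotypeFormatError(f"{path}: missing value in row {row}")
    try:
        values = frame.to_numpy(dtype=np.int64)
    except ValueError as exc:
        raise GenotypeFormatError(f"{path}: non-integer entry ({exc})")
    geno, pheno = values[:, :-1], values[:, -1]
    names = [str(c) for c in frame.columns[:-1]]
    bad = np.argwhere(~np.isin(geno, (0, 1, 2)))
    if len(bad):
        r, c = bad[0]
        raise GenotypeFormatError(
            f"{path}: genotype value {geno[r, c]} at row {r}, "
            f"column {names[c]!r} is not in {{0,1,2}}"
        )
    if not np.isin(pheno, (0, 1)).all():
        r = int(np.argwhere(~np.isin(pheno, (0, 1)))[0][0])
        raise GenotypeFormatError(
            f"{path}: class value {pheno[r]} at row {r} is not binary"
        )
    truth = None
    sidecar = _truth_path(path)
    if sidecar.exists():
        truth = read_truth(sidecar)
    return GenotypeDataset(
        genotypes=geno, phenotype=pheno, snp_names=names, truth=truth
    )


def write_genotypes(
    dataset: GenotypeDataset, path: str | Path, dialect: str = "gametes"
) -> None:
    """Write the GAMETES-style text file (class column last).

    Ground-truth combinations, when present, go to a JSON sidecar next
    to the data file.
    """
    path = Path(path)
    if dialect not in _SEP:
        raise ValueError(f"unknown dialect {dialect!r}")
    frame = pd.DataFrame(dataset.genotypes, columns=dataset.snp_names)
    frame[CLASS_COLUMN] = dataset.phenotype
    frame.to_csv(path, sep=_SEP[dialect], index=False)
    if dataset.truth is not None:
        payload = {
            "truth": [list(t) for t in dataset.truth],
            "snp_names": [
                [dataset.snp_names[i] for i in t] for t in dataset.truth
            ],
        }
        _truth_path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> list[tuple[int, ...]]:
    payload = json.loads(Path(path).read_text())
    return [tuple(int(i) for i in t) for t in payload["truth"]]


def write_interaction_network(
    results: list[DetectionResult] | DetectionResult,
    path: str | Path,
    interaction: str = "epistasis",
) -> tuple[int, int]:
    """Write a SIF edge list Cytoscape can load.

    Every reported k-locus combination contributes all k(k−1)/2
    pairwise edges; duplicate edges are merged.  Returns the node and
    edge counts.
    """
    if isinstance(results, DetectionResult):
        results = [results]
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    for result in results:
        for rec in result.records:
            if len(rec.snp_names) < 2:
                raise ValueError(
                    f"combination {rec.snp_names} has fewer than 2 SNPs"
                )
            nodes.update(rec.snp_names)
            for a, b in itertools.combinations(sorted(rec.snp_names), 2):
                edges.add((a, b))
    lines = [f"{a}\t{interaction}\t{b}" for a, b in sorted(edges)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    logger.info(
        "wrote network %s: %d nodes, %d edges", path, len(nodes), len(edges)
    )
    return len(nodes), len(edges)


_RESULT_COLUMNS = [
    "snp_names",
    "snp_indices",
    "K2",
    "LR",
    "raw_G",
    "g_test_p",
    "mdr_accuracy",
    "passed_validation",
]


def write_results(result: DetectionResult, path: str | Path) -> None:
    """Tab-delimited detection table, one combination per row.

    A header comment preserves the number of distinct combinations the
    search evaluated, which downstream validation needs for its
    multiplicity correction.
    """
    rows = [
        {
            "snp_names": ",".join(r.snp_names),
            "snp_indices": ",".join(str(i) for i in r.snp_indices),
            "K2": r.k2,
            "LR": r.lr,
            "raw_G": r.raw_g,
            "g_test_p": r.g_test_p,
            "mdr_accuracy": r.mdr_accuracy,
            "passed_validation": r.passed_validation,
        }
        for r in result.records
    ]
    frame = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# candidates_evaluated={result.n_unique_evaluated}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_results(path: str | Path) -> list[DetectionRecord]:
    records, _ = read_results_with_meta(path)
    return records


def read_results_with_meta(
    path: str | Path,
) -> tuple[list[DetectionRecord], int]:
    """Read a detection table plus its evaluated-candidate count."""
    n_unique = 0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# candidates_evaluated="):
        n_unique = int(first.split("=", 1)[1])
    frame = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for _, row in frame.iterrows():
        records.append(
            DetectionRecord(
                snp_indices=tuple(
                    int(i) for i in str(row["snp_indices"]).split(",")
                ),
                snp_names=tuple(str(row["snp_names"]).split(",")),
                k2=float(row["K2"]),
                lr=float(row["LR"]),
                raw_g=float(row["raw_G"]),
                g_test_p=(
                    None if pd.isna(row["g_test_p"]) else float(row["g_test_p"])
                ),
                mdr_accuracy=(
                    None
                    if pd.isna(row["mdr_accuracy"])
                    else float(row["mdr_accuracy"])
                ),
                passed_validation=(
                    None
                    if pd.isna(row["passed_validation"])
                    else bool(row["passed_validation"])
                ),
            )
        )
    return records, max(n_unique, len(records), 1)
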