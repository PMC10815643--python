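"""Detection-accuracy metrics and validation filters.

``power`` counts in how many simulated datasets the true pathogenic
combination was reported.  Three variants are distinguished: power1 on
the raw detections, power2 after a G-test significance filter, and
power3 after a multifactor-dimensionality-reduction (MDR)
classification filter.  Confusion-matrix metrics (TPR, PPV, ACC, FDR,
F1) are computed over the validated detections against the per-dataset
candidate universe.

The G-test filter is Bonferroni-corrected, by default over the number
of distinct combinations the search evaluated: the top-ranked
candidate of a stochastic search is the minimum of that many p-values,
and correcting only over the few reported candidates would make the
null false-validation rate approach one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .dataset import GenotypeDataset
from .engine import DetectionRecord, DetectionResult
from .scoring import build_contingency, g_test

__all__ = [
    "ConfusionCounts",
    "PowerReport",
    "power",
    "confusion_metrics",
    "gtest_validate",
    "mdr_classify",
    "mdr_validate",
    "evaluate_experiment",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass
class PowerReport:
    """Per-experiment detection accuracies and confusion metrics."""

    power1: float
    power2: float
    power3: float
    n_datasets: int
    counts: ConfusionCounts
    metrics: dict[str, float | None]
    per_dataset: list[dict] = field(default_factory=list)


def power(
    detections: list[list[tuple[int, ...]]],
    truths: list[set[tuple[int, ...]] | list[tuple[int, ...]]],
) -> float:
    """Fraction of datasets whose truth combination was detected.

    Tuples are compared unordered (sorted); each dataset counts once.
    """
    if len(detections) != len(truths):
        raise ValueError("detections and truths must have equal length")
    if not truths:
        raise ValueError("no datasets")
    hits = 0
    for det, truth in zip(detections, truths):
        det_set = {tuple(sorted(c)) for c in det}
        truth_set = {tuple(sorted(c)) for c in truth}
        if truth_set & det_set:
            hits += 1
    return hits / len(truths)


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """TPR, PPV, ACC, FDR and F1; ``None`` where a denominator is zero."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    tpr = tp / (tp + fn) if tp + fn > 0 else None
    ppv = tp / (tp + fp) if tp + fp > 0 else None
    total = tp + fp + tn + fn
    acc = (tp + tn) / total if total > 0 else None
    fdr = fp / (tp + fp) if tp + fp > 0 else None
    if tpr is None or ppv is None:
        f1 = None
    elif tpr + ppv == 0:
        f1 = 0.0
    else:
        f1 = 2 * tpr * ppv / (tpr + ppv)
    return {"TPR": tpr, "PPV": ppv, "ACC": acc, "FDR": fdr, "F1": f1}


def gtest_validate(
    candidates: list[DetectionRecord],
    dataset: GenotypeDataset,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    n_comparisons: int | None = None,
) -> list[DetectionRecord]:
    """Keep candidates significant under a Bonferroni-corrected G-test.

    ``n_comparisons`` sets the Bonferroni denominator (defaults to the
    number of candidates); pass the search's distinct-evaluation count
    to correct for the selection performed by the optimizer.  With
    ``correction='none'`` the raw level ``alpha`` is used.
    """
    if not candidates:
        return []
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    m = n_comparisons if n_comparisons is not None else len(candidates)
    threshold = alpha / m if correction == "bonferroni" else alpha
    kept = []
    for rec in candidates:
        _, _, p = g_test(build_contingency(dataset, rec.snp_indices))
        rec.g_test_p = p
        if p < threshold:
            kept.append(rec)
    return kept


def mdr_classify(
    combination: tuple[int, ...],
    dataset: GenotypeDataset,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Cross-validated balanced accuracy of the MDR risk rule.

    Each joint-genotype cell is labeled high-risk when its training
    case:control ratio exceeds the overall training ratio; test samples
    are classified by their cell's label (unseen cells → low-risk).
    Returns the mean balanced accuracy over stratified folds; folds
    containing a single class are skipped with a warning.
    """
    if folds < 2:
        raise ValueError("folds must be ≥ 2")
    codes = np.zeros(dataset.n_samples, dtype=np.int64)
    for idx in combination:
        codes = codes * 3 + dataset.genotypes[:, idx]
    y = np.asarray(dataset.phenotype, dtype=np.int64)
    n_cells = 3 ** len(combination)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(codes[:, None], y):
        y_tr, y_te = y[train], y[test]
        if y_tr.min() == y_tr.max() or y_te.min() == y_te.max():
            warnings.warn("skipping single-class fold", stacklevel=2)
            continue
        cases = np.bincount(codes[train][y_tr == 1], minlength=n_cells)
        controls = np.bincount(codes[train][y_tr == 0], minlength=n_cells)
        overall = y_tr.sum() / max(len(y_tr) - y_tr.sum(), 1)
        # high-risk iff case:control ratio exceeds the overall ratio;
        # cells without training data default to low-risk
        high = (cases > overall * controls) & (cases + controls > 0)
        pred = high[codes[test]].astype(np.int64)
        sens = (pred[y_te == 1] == 1).mean()
        spec = (pred[y_te == 0] == 0).mean()
        accs.append(0.5 * (sens + spec))
    return float(np.mean(accs)) if accs else 0.5


def mdr_validate(
    candidates: list[DetectionRecord],
    dataset: GenotypeDataset,
    accuracy_min: float = 0.55,
    folds: int = 10,
    seed: int = 0,
) -> list[DetectionRecord]:
    """Keep candidates whose MDR balanced accuracy reaches the threshold."""
    kept = []
    for rec in candidates:
        acc = mdr_classify(rec.snp_indices, dataset, folds=folds, seed=seed)
        rec.mdr_accuracy = acc
        if acc >= accuracy_min:
            kept.append(rec)
    return kept


def evaluate_experiment(
    results: list[DetectionResult],
    truths: list[list[tuple[int, ...]]],
    datasets: list[GenotypeDataset],
) -> PowerReport:
    """Score one experiment: matched detection runs, truths and data.

    power1 uses the raw nondominated detections, power2 the G-test
    survivors, power3 the MDR survivors (both filters applied to the
    raw detections independently).  Confusion counts are accumulated on
    the G-test-validated set: TP = truth combinations recovered, FP =
    validated non-truth combinations, FN = truths missed; TN counts the
    remaining (rejected, non-truth) members of the detector's final
    candidate archive.
    """
    if not len(results) == len(truths) == len(datasets):
        raise ValueError("results, truths and datasets must be matched")
    raw_sets, g_sets, mdr_sets = [], [], []
    counts = ConfusionCounts()
    per_dataset = []
    for result, truth, dataset in zip(results, truths, datasets):
        cfg = result.config
        raw = list(result.records)
        g_kept = gtest_validate(
            raw,
            dataset,
            alpha=cfg.g_test_alpha,
            n_comparisons=result.n_unique_evaluated,
        )
        mdr_kept = mdr_validate(
            raw,
            dataset,
            accuracy_min=cfg.mdr_accuracy_min,
            folds=cfg.mdr_folds,
            seed=cfg.seed,
        )
        g_combos = {r.snp_indices for r in g_kept}
        for rec in raw:
            rec.passed_validation = rec.snp_indices in g_combos
        truth_set = {tuple(sorted(t)) for t in truth}
        universe = {r.snp_indices for r in raw} | truth_set
        tp = len(g_combos & truth_set)
        fp = len(g_combos - truth_set)
        fn = len(truth_set - g_combos)
        tn = len(universe - g_combos - truth_set)
        counts = counts + ConfusionCounts(tp, fp, tn, fn)
        raw_sets.append([r.snp_indices for r in raw])
        g_sets.append([r.snp_indices for r in g_kept])
        mdr_sets.append([r.snp_indices for r in mdr_kept])
        per_dataset.append(
            {
                "truth": sorted(truth_set),
                "detected": sorted(r.snp_indices for r in raw),
                "g_validated": sorted(g_combos),
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "tn": tn,
            }
        )
    return PowerReport(
        power1=power(raw_sets, truths),
        power2=power(g_sets, truths),
        power3=power(mdr_sets, truths),
        n_datasets=len(results),
        counts=counts,
        metrics=confusion_metrics(counts),
        per_dataset=per_dataset,
    )
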