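"""End-to-end simulation experiments over disease-model suites.

For every model in a suite, replicate datasets are simulated with one
embedded interaction, the evolutionary search is run on each, and
detections are validated and scored.  Two aggregations are provided:
``mean_*`` averages per-model metrics (F1 = 0 for a model where
nothing true was found; models with no positive calls drop out of the
PPV mean), while ``pooled_*`` computes TPR and PPV from confusion
counts summed over every model of the suite.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .dataset import GenotypeDataset
from .engine import DetectionResult, run_search
from .evaluation import (
    ConfusionCounts,
    PowerReport,
    confusion_metrics,
    evaluate_experiment,
)
from .simulator import (
    DiseaseModelSpec,
    generate_dataset,
    model_suite,
    random_penetrance_table,
)

logger = logging.getLogger(__name__)

__all__ = ["ModelOutcome", "SuiteOutcome", "run_model_experiment", "run_suite"]


@dataclass
class ModelOutcome:
    """Detection report for one disease model."""

    spec: DiseaseModelSpec
    report: PowerReport

    @property
    def tpr(self) -> float | None:
        return self.report.metrics["TPR"]

    @property
    def ppv(self) -> float | None:
        return self.report.metrics["PPV"]

    @property
    def f1(self) -> float | None:
        f1 = self.report.metrics["F1"]
        if f1 is None and self.report.counts.fn > 0:
            return 0.0  # nothing true found: zero by convention
        return f1


@dataclass
class SuiteOutcome:
    """Aggregate over all models of one suite."""

    kind: str
    models: list[ModelOutcome] = field(default_factory=list)

    @staticmethod
    def _mean(values: list[float | None]) -> float | None:
        defined = [v for v in values if v is not None]
        return float(np.mean(defined)) if defined else None

    @property
    def mean_tpr(self) -> float | None:
        return self._mean([m.tpr for m in self.models])

    @property
    def mean_ppv(self) -> float | None:
        return self._mean([m.ppv for m in self.models])

    @property
    def mean_f1(self) -> float | None:
        return self._mean([m.f1 for m in self.models])

    @property
    def pooled_counts(self) -> "ConfusionCounts":
        total = ConfusionCounts()
        for m in self.models:
            total = total + m.report.counts
        return total

    @property
    def pooled_tpr(self) -> float | None:
        return confusion_metrics(self.pooled_counts)["TPR"]

    @property
    def pooled_ppv(self) -> float | None:
        return confusion_metrics(self.pooled_counts)["PPV"]

    @property
    def mean_power1(self) -> float:
        return float(np.mean([m.report.power1 for m in self.models]))

    @property
    def mean_power2(self) -> float:
        return float(np.mean([m.report.power2 for m in self.models]))

    @property
    def mean_power3(self) -> float:
        return float(np.mean([m.report.power3 for m in self.models]))


def run_model_experiment(
    spec: DiseaseModelSpec,
    n_datasets: int,
    n_snps: int,
    n_cases: int,
    n_controls: int,
    config: RunConfig,
    seed: int,
    fresh_table_per_dataset: bool = True,
) -> ModelOutcome:
    """Simulate and analyse replicate datasets of one disease model.

    Each replicate draws its own random penetrance architecture at the
    model's (MAF, h², prevalence) targets, mirroring a generator run
    with random architectures per dataset.
    """
    ss = np.random.SeedSequence(
        [seed, zlib.crc32(spec.name.encode()) % 2**31]
    )
    children = ss.spawn(n_datasets)
    results: list[DetectionResult] = []
    truths: list[list[tuple[int, ...]]] = []
    datasets: list[GenotypeDataset] = []
    shared_table = None
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        if fresh_table_per_dataset or shared_table is None:
            shared_table = random_penetrance_table(spec, rng)
        dataset, truth = generate_dataset(
            spec,
            n_cases,
            n_controls,
            n_snps,
            rng,
            table=shared_table,
            dataset_id=f"{spec.name}-{i}",
        )
        run_cfg = config.replace(
            seed=int(rng.integers(2**31 - 1)), order_k=spec.order
        )
        results.append(run_search(dataset, run_cfg))
        truths.append([truth.snp_indices])
        datasets.append(dataset)
    report = evaluate_experiment(results, truths, datasets)
    logger.info(
        "%s: power1=%.2f power2=%.2f power3=%.2f TPR=%s PPV=%s",
        spec.name,
        report.power1,
        report.power2,
        report.power3,
        report.metrics["TPR"],
        report.metrics["PPV"],
    )
    return ModelOutcome(spec=spec, report=report)


def run_suite(
    kind: str,
    n_datasets: int,
    n_snps: int,
    n_cases: int,
    n_controls: int,
    config: RunConfig | None = None,
    seed: int = 0,
) -> SuiteOutcome:
    """Run the full DME or DNME model suite."""
    config = config or RunConfig()
    outcome = SuiteOutcome(kind=kind)
    for spec in model_suite(kind):
        outcome.models.append(
            run_model_experiment(
                spec, n_datasets, n_snps, n_cases, n_controls, config, seed
            )
        )
    return outcome
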