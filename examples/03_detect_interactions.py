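"""Detect an epistatic pair with the spherical evolutionary search.

Simulates a 100-SNP panel with one hidden purely-epistatic pair, runs
the multi-objective search, validates the nondominated detections with
a selection-corrected G-test, and compares against the ground truth
and the exhaustive-enumeration optimum.
"""

import numpy as np

from episphere import (
    DiseaseModelSpec,
    RunConfig,
    exhaustive_best_k2,
    generate_dataset,
    gtest_validate,
    run_search,
)

rng = np.random.default_rng(7)
spec = DiseaseModelSpec(
    maf=0.4, h2=0.4, prevalence=None, marginal_effects=False, name="demo"
)
dataset, truth = generate_dataset(
    spec, n_cases=800, n_controls=800, n_snps=100, rng=rng
)

config = RunConfig(seed=2)  # budget auto-sized to 4 × C(100, 2)
result = run_search(dataset, config)
print(
    f"search evaluated {result.n_unique_evaluated} distinct pairs "
    f"({result.n_evaluations} evaluations)"
)
for rec in result.records:
    print(
        f"  nondominated: {'/'.join(rec.snp_names)}  "
        f"K2={rec.k2:.2f}  G={rec.raw_g:.2f}"
    )

validated = gtest_validate(
    result.records, dataset, alpha=0.05,
    n_comparisons=result.n_unique_evaluated,
)
print(f"{len(validated)} combination(s) pass the corrected G-test")

best_combo, best_k2 = exhaustive_best_k2(dataset)
hit = truth.snp_indices in [r.snp_indices for r in validated]
print(f"truth {truth.snp_indices} recovered: {hit}; "
      f"exhaustive K2 optimum is {best_combo} (K2={best_k2:.2f})")
if hit:
    print(
        "\nThe validated detection coincides with both the planted pair "
        "and the brute-force optimum — the search found the global "
        "solution without scoring every pair."
    )
else:
    print(
        "\nThis run's budget happened to miss the planted pair (the "
        "search covers ~95% of the space); note that the corrected "
        "G-test then rightly rejects the leftover noise combinations."
    )
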