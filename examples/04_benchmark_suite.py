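"""Run a miniature benchmark over the purely epistatic model suite.

Evaluates the detector on two replicate panels for each of the ten
no-marginal-effect (DNME) disease models and prints per-model power
and the suite-level confusion metrics.  Scaled far below the full
protocol so it finishes in about a minute; see scripts/acceptance.py
for the full desk-scale run.
"""

from episphere import RunConfig, run_suite

outcome = run_suite(
    "dnme",
    n_datasets=2,
    n_snps=100,
    n_cases=800,
    n_controls=800,
    config=RunConfig(),
    seed=3,
)

print("model     MAF   h²     power1  power2  power3")
for m in outcome.models:
    r = m.report
    print(
        f"{m.spec.name:8s} {m.spec.maf:.2f}  {m.spec.h2:<5.3g}"
        f"  {r.power1:5.2f}   {r.power2:5.2f}   {r.power3:5.2f}"
    )
print(
    f"\nsuite means: TPR={outcome.mean_tpr:.2f} PPV={outcome.mean_ppv:.2f} "
    f"F1={outcome.mean_f1:.2f}"
)
print(
    "On this small panel power is high across most architectures; the "
    "occasional miss reflects the finite search budget (~95% coverage of "
    "the pair space) and the harder low-MAF draws.  Validated precision "
    "stays at 1: the G-test, corrected over everything the search "
    "evaluated, admits no background pair.  At realistic panel sizes "
    "(200+ SNPs) the h² = 0.01 models drop toward zero power — see "
    "scripts/acceptance.py."
)
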