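# episphere

Detection of multi-locus SNP interactions (epistasis) in case–control
GWAS panels by a spherical-evolution, multi-objective search — plus the
disease-model simulator and evaluation harness needed to benchmark it.

## Who this is for

Statistical geneticists and methods researchers who need to find k-SNP
combinations whose *joint* genotype distribution separates cases from
controls — including purely epistatic signals with no single-locus
(marginal) effect — without enumerating all C(n, k) combinations, and
who want a reproducible simulation benchmark around the detector.

## The method

A panel is a matrix X ∈ {0,1,2}^(n×m) of minor-allele counts with a
binary phenotype y.  For a candidate SNP set S (|S| = k) the I×2
contingency table of joint genotypes by phenotype yields two
association objectives:

* **K2 score** — the negative log Bayesian-network marginal likelihood
  −ln Π_i (J−1)! Π_j N_ij! / (N_i+J−1)!  (J = 2), computed with
  log-gamma arithmetic; lower = stronger association;
* **LR score** — the likelihood-ratio statistic
  G = 2 Σ_ij N_ij ln(N_ij/E_ij) against the margin-product
  expectation, negated so that minimizing favors association.

The bi-objective problem min (K2, −G) is decomposed MOEA/D-style into
NP scalar subproblems (simplex-lattice weights, penalty boundary
intersection d1 + θ·d2 on min–max-normalized objectives).  Candidates
evolve as continuous k-vectors under a spherical mutation operator —
displacements of exact length F·‖A−B‖₂ in uniformly random
hyperspherical directions — with binomial crossover and elitist
per-subproblem selection.  The scale factor F self-adapts from a
success-history memory (Cauchy sampling around Lehmer means of
recently winning F values), and losing parents feed an external
archive that diversifies the search.  The run reports the nondominated
front of every distinct combination it evaluated, validated by a
selection-corrected G-test and by MDR (multifactor dimensionality
reduction) cross-validated balanced accuracy.

The companion simulator regenerates GAMETES-style benchmarks: random
penetrance tables matched to a target minor-allele frequency,
heritability h² and prevalence, with single-locus marginals optionally
flattened (DNME models, no marginal effects) or left as drawn (DME),
embedded in balanced panels among uniform-MAF background SNPs.

See `docs/methods.md` for assumptions, parameter defaults and
numerical choices.

## A worked example

```bash
python examples/03_detect_interactions.py
```

simulates a 1600-sample, 100-SNP panel with one hidden purely
epistatic pair (MAF 0.4, h² 0.4) and runs the detector:

```
search evaluated 4670 distinct pairs (19800 evaluations)
  nondominated: M0P0/M1P1  K2=751.53  G=777.40
1 combination(s) pass the corrected G-test
truth (50, 53) recovered: True; exhaustive K2 optimum is (50, 53) (K2=751.53)
```

The single nondominated combination is the planted pair M0P0/M1P1: its
K2 (751.5) is the minimum over all 4950 pairs — identical to the
brute-force enumeration optimum — and its G statistic (777.4) passes a
G-test Bonferroni-corrected over the 4670 combinations the search
actually weighed.  The other examples cover scoring single
combinations, simulating suites, running the miniature benchmark and
exporting Cytoscape SIF networks.

The same stages are scriptable from a shell:

```bash
episphere simulate --model dnme --maf 0.4 --h2 0.4 \
    --n-cases 800 --n-controls 800 --n-snps 100 --seed 3 --out panel.txt
episphere detect panel.txt --order 2 --seed 5 --out detections.tsv
episphere evaluate --results detections.tsv --data panel.txt
episphere network detections.tsv --out interactions.sif
```

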