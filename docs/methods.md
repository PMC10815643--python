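# Methods

## Problem

A case–control GWAS panel is a matrix of genotypes coded 0/1/2 (minor-
allele count) with a binary phenotype (1 = case).  A k-locus epistatic
interaction is a set of k SNPs whose *joint* genotype distribution
differs between cases and controls, possibly without any detectable
single-locus (marginal) effect.  The package searches the
C(n_snps, k) combination space for such sets.

## Association objectives

Both objectives are computed from the I×2 contingency table of joint
genotypes (rows; at most 3^k, only observed rows kept) by phenotype
(columns: controls, cases).

**K2 score.**  The Bayesian-network marginal likelihood of the
genotype→phenotype structure with a uniform Dirichlet prior,

    Π_i (J−1)! Π_j N_ij! / (N_i + J−1)!     (J = 2),

is evaluated as its negative logarithm via log-gamma arithmetic
(Σ_i [ln((N_i+1)!) − Σ_j ln(N_ij!)]), because factorials of counts up
to 1600 overflow any float.  −ln is monotone decreasing, so the
lower-is-stronger ordering of the product is preserved; exactness
against rational factorial arithmetic is asserted in the tests to
1e−9 relative for all counts ≤ 12.

**LR score.**  The likelihood-ratio goodness-of-fit statistic
G = 2 Σ N_ij ln(N_ij/E_ij), with 0·ln0 ≡ 0.  Expected counts default
to the two-way margin product E_ij = N_i·N_j/N — this makes the
statistic the classical G-test that the validation stage uses — and an
alternative derives row expectations from Hardy–Weinberg genotype
frequencies at the sample allele frequencies (`expected_mode='hwe'`).
G *grows* with association, so the second search objective stores −G
by default (`lr_direction='negated'`), making both objectives
minimization-oriented; the raw G is kept for validation.  The
alternative reading, minimizing +G directly, is available behind the
same flag but ranks the null above any signal and is not the default.

## Decomposition and scalarization

The bi-objective problem is decomposed MOEA/D-style into NP scalar
subproblems with simplex-lattice weights ω_i = (i/(NP−1), 1−i/(NP−1))
and K-nearest-weight neighborhoods (K = max(2, NP/10) by default).
K2 (a log-likelihood with magnitude in the hundreds) and G (tens) are
incommensurate, so objective vectors are min–max normalized over the
pool of every combination evaluated so far in the run; the bounds only
widen, which keeps normalized values in [0,1] and pins the reference
point (componentwise minimum of normalized vectors) at the origin.
Each subproblem is scored by penalty boundary intersection
d1 + θ·d2 (projection along the weight ray, θ-weighted perpendicular
distance; θ = 5, the customary PBI penalty).

## Search engine

Individuals are continuous k-vectors in [0, n_snps)^k decoded by
floor + clip, with duplicate coordinates advanced cyclically to the
nearest unused index.  Per generation and individual:

1. a scale factor F is drawn from Cauchy(m_F, 0.1) (clamped to (0,1],
   redrawn when ≤ 0), where m_F is a uniformly chosen slot of an
   H-slot success-history memory initialized at 0.5;
2. the trial base vector is X + S(X, X_pbest; F) + S(X_r1, X_r2; F),
   where S(A,B;F) is a displacement of exact length F·‖A−B‖₂ in a
   uniformly random hyperspherical direction, X_pbest is drawn from
   the top ⌈p·NP⌉ individuals by scalarized fitness (p = 0.1), X_r1
   from the population and X_r2 from population ∪ archive;
   out-of-bound coordinates are reflected;
3. binomial crossover (CR = 0.5, one forced coordinate) forms the
   trial, which replaces its parent iff it strictly lowers the PBI
   value of the parent's own subproblem.  Losing parents enter an
   external archive of capacity 2·NP with uniform-random eviction.

After each generation, the memory slot at the cyclic write index is
set to the Δf-weighted Lehmer mean of the winning F values
(Σw·F²/Σw·F, w ∝ fitness improvement), or copies the previous slot
when no trial won.

The run returns the nondominated front, under (K2, −G) minimization,
of *every distinct combination evaluated* — the search's historical
best-solution set — sorted by K2.  With a strong interaction the
componentwise optimum is a single combination and the front collapses
to it.

### Budget sizing

A purely epistatic pair emits no gradient through partial
combinations — any pair containing exactly one disease locus scores
like noise — so recovery is governed by how much of the combination
space the run touches.  The default budget is therefore
`coverage_multiplier × C(n_snps, k)` evaluations (multiplier 4), at
which a uniform sampler would visit 1 − e⁻⁴ ≈ 98% of the space;
population size then sets the generation count.  Models *with*
marginal effects converge much faster, but the budget is kept uniform
across suites for comparability.  `max_evaluations` overrides the
rule.

## Validation filters

**G-test.**  Candidates keep their raw G; the p-value is the χ² upper
tail at df = (I−1)(J−1).  The Bonferroni denominator defaults to the
number of *distinct combinations the search evaluated*, not the number
of reported candidates: the top-ranked detection is the minimum of
~10⁴ p-values, and correcting only over the handful reported would
pass the best noise combination in nearly every null run.  With the
selection-aware correction the null false-validation rate sits at the
nominal α (asserted over 200 null replicates).

**MDR.**  Each joint-genotype cell is labeled high-risk iff its
training case:control ratio exceeds the overall training ratio;
samples classify by their cell label (unseen cells low-risk), scored
by stratified 10-fold cross-validated balanced accuracy.  A candidate
passes at ≥ 0.55 balanced accuracy (no threshold is conventional; 0.55
sits three-plus null standard errors above chance at n = 1600 and is
config-exposed).

power1/2/3 are the fractions of datasets whose embedded combination
appears in, respectively, the raw front, the G-test survivors and the
MDR survivors (both filters applied to the raw front independently, so
power2 ≤ power1 and power3 ≤ power1 by construction).

## Disease-model simulator

Penetrance tables (3^k disease probabilities indexed by joint
genotype) are searched at random: draw f ~ U(0,1)^{3^k}, then iterate
(a) multiplicative rescale to the target prevalence, (b) for
no-marginal-effect (DNME) models an iterative-proportional sweep
flattening every single-locus marginal penetrance onto the prevalence
(tolerance 1e−3), (c) an affine spread about the prevalence matching
the variance-explained heritability

    h² = Σ_g P(g)(f_g − P(D))² / (P(D)(1 − P(D))),

with clipping to [0,1] and random restarts when a draw cannot
converge.  Prevalence may be left unconstrained (`prevalence=None`):
a bounded flat-marginal table at P(D) = 0.2 cannot exceed h² ≈ 0.17–
0.25 (MAF 0.2/0.4), so the high-heritability DNME models let the
prevalence settle where the table search lands, as unconstrained
generators do.

Datasets embed the k disease loci (HWE genotypes at the model MAF,
phenotype Bernoulli(f_g)) at seeded-random columns among background
SNPs drawn independently of phenotype with MAF ~ U(0.01, 0.5); cases
and controls are accumulated by rejection until the exact requested
counts (800/800 by default).  Each replicate draws a fresh random
architecture at the model's targets.

**Model suites.**  DNME: MAF ∈ {0.2, 0.4} × h² ∈ {0.01, 0.05, 0.1,
0.2, 0.4} (the h² = 0.1 column fills the grid out to the ten models
the benchmark specifies; the exact original architectures are not
published, so all tables are regenerated from the parameter grid).
DME: MAF ∈ {0.05, 0.1, 0.2, 0.5} × h² ∈ {0.005, 0.05, 0.2}, marginal
effects left as drawn, prevalence 0.2.

**What the simulator does not model:** linkage disequilibrium between
background SNPs, genotyping error/missingness, covariates and
population structure.  Passing benchmarks therefore demonstrate
detection of a clean embedded interaction against independent noise,
not robustness to the confounders of real GWAS data.

## Experiment aggregation

Per dataset, TP counts truth combinations among the G-test-validated
detections, FP the validated non-truth detections, FN the truths
missed; TN counts rejected non-truth members of the final front (the
candidate universe the detector actually weighed).  Per-model metrics
aggregate these counts over replicates.  At suite level two
conventions are exposed: `mean_*` averages per-model metrics (F1 = 0
for a model where nothing true was found; models with no positive
calls drop out of the PPV mean), and `pooled_*` computes TPR/PPV from
counts summed over all models.  The benchmark script reports mean F1
and pooled TPR/PPV; pooling keeps a single stray false positive in a
zero-power model from erasing a whole model's precision, which the
per-model mean overweights at desk-scale replicate counts.

## Desk-scale benchmark protocol

`scripts/acceptance.py` runs both suites at: 200-SNP panels (down from
the published 1000 — the budget rule keeps the search-coverage regime
comparable while a full-size suite would take hours on one CPU),
800 cases/800 controls, five replicate datasets per model, default
engine configuration.  The engine-versus-enumeration check uses
100-SNP panels where C(100,2) = 4950 is exhaustively scorable, with
the population sized so the 4× coverage budget fits in 50 generations.

## Numerical and degenerate-input choices

* 0·ln 0 ≡ 0 in G; χ² cells with E = 0 contribute 0; df ≤ 0 ⇒ p = 1.
* Ties in subproblem championing break by lower K2, then
  lexicographic SNP tuple; equal scalar fitness keeps the parent.
* Duplicate decoded coordinates repair upward cyclically; decoding is
  idempotent and total on finite input.
* All randomness flows from one `numpy.random.Generator` per run; a
  (dataset, config, seed) triple reproduces results bit-for-bit.

## Known limitations

* Orders k > 4 are untested and the decoding repair becomes
  increasingly distorting as k approaches n_snps.
* The coverage-based budget makes cost grow quadratically with panel
  size at k = 2; panels of 10⁴+ SNPs need a smaller multiplier and
  correspondingly lower expected power on purely epistatic signals.
* Suite-level reference comparisons inherit the uncertainty of
  regenerated penetrance architectures; they are checkpoint-level
  (±0.15), not exact reproductions.
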