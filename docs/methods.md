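# Methods

## The generative model

One simulated SNP is a 2 × 2 × k table built in four stages:

1. **Ancestral frequency.** The 'A' allele frequency in the base population,
   p_A, is drawn from Beta(θ, θ) with θ = 4·N_e·u = 4·N_e·v, the stationary
   distribution of a biallelic locus at mutation–drift equilibrium with equal
   forward and backward mutation rates. The default θ = 0.2 corresponds to
   mutation rates of order 10⁻⁹–10⁻⁸ and effective sizes of order 10⁶, and
   makes the frequency spectrum strongly U-shaped: most loci sit near 0 or 1.
   Draws are strictly interior; a boundary value (possible only by floating
   underflow) is redrawn.
2. **Line drift.** Each of the 2k treatment-line frequencies f_A is an
   independent draw from a normal distribution with mean p_A and variance
   F_ST·p_A(1 − p_A), truncated — i.e. renormalised, not clamped — to [0, 1].
   F_ST is the sole divergence knob; the number of generations is subsumed
   into it. Clamping was rejected because it creates point masses at 0 and 1
   on which the downstream fixation screen would then depend. Sampling is by
   inverse CDF (Φ⁻¹ of a uniform draw on [Φ(a), Φ(b)]), which vectorises.
   When the variance is zero (F_ST = 0, or p_A on a boundary) f_A = p_A
   exactly.
3. **True positives.** A locus seeded as a true positive has min(f_A + s, 1)
   substituted for f_A in line 1 of every replicate, after drift; the shift
   s = 0.2 by default. The shifted line is always line 1.
4. **Double binomial sampling.** A pool of n = 2N chromosomes is sampled from
   each line, x ~ Binomial(n, f_A); reads are then sampled from the pool,
   C_A ~ Binomial(CT, x/n). The default pool is N = 100 diploids. Read depth
   CT per cell is, by coverage mode:
   * `variable` — negative binomial with mean 200 and size 2, rejection-
     resampled until CT ≥ 10 (rejection preserves the shape above the cutoff;
     the loop aborts with a diagnostic if the bound is effectively
     unattainable);
   * `fixed` — a constant (100 or 200 in the study designs);
   * `neff` — variable coverage whose counts are then rescaled cell-wise to
     the effective sample size n_eff = (n·CT − 1)/(n + CT), the number of
     effectively independent observations after double sampling. Rescaling
     rounds the target half-to-even to an integer T and sets
     C_A' = round(T·C_A/CT), C_a' = T − C_A', so each cell sums to T exactly.

A locus whose 2k cells are all C_A = 0 or all C_a = 0 is redrawn from stage 1
(fresh p_A); the screen acts on read counts because continuous frequencies
almost never hit the boundary exactly. Redraw loops are bounded (1000 rounds)
with diagnostics. All randomness flows from one seeded generator, loci drawn
sequentially, so a dataset is reproducible from its parameter set alone. Of
n_loci loci, exactly round(tp_fraction·n_loci) — the leading block — are
flagged true positives.

## The tests

Each test sees one locus; strata are replicates, rows treatment lines, columns
alleles. Zero handling follows one rule: if any of the 2k cells holds a zero,
1 is added to every allele count of the locus (equivalently: to every cell of
every stratum), raising each cell's total by 2. On this layout the
contingency-table wording and the GLM wording of the rule coincide. The linear
model, fitted to frequencies, needs no adjustment and uses raw counts.

* **CMH.** Statistic (|Σa_k − ΣE_k| − ½)²/ΣV_k with E_k, V_k the conditional
  hypergeometric mean and variance per stratum; df = 1. The ½ continuity
  correction is skipped when |Σa_k − ΣE_k| < ½ (it would overshoot zero) —
  the convention of the R routine this field uses, and required to reproduce
  the worked example's 55.66. Effect: Mantel–Haenszel common odds ratio
  Σ(a_k d_k/n_k)/Σ(b_k c_k/n_k).
* **Woolf.** Σw_k(ln OR_k − ln ŌR)², w_k = (1/a+1/b+1/c+1/d)⁻¹, df = k − 1;
  the classical 1955 form. The +1 rule replaces the Haldane ½ correction.
* **Consistency call.** p_main if the heterogeneity p exceeds the chosen α,
  else 1.0 — an inconsistent locus can never be called. For false-positive
  curves the veto is applied per grid α; for the top-1% ranking it is applied
  once at α = 0.05. The same gate defines the "consistent SNP" reading of the
  G-test and of binomial model 1 (overall effect plus non-significant
  interaction).
* **Replicated G-test.** Per-stratum G = 2ΣO·ln(O/E) sum to G_T (df = k);
  the pooled (summed over replicates) table gives the line-by-allele main
  effect G_P (df = 1); heterogeneity G_H = G_T − G_P (df = k − 1). The
  partition is exact; no Williams correction (the +1 rule is the only
  adjustment, matching the study design).
* **Binomial GLM, model 1** (`treatment + replicate + interaction`, logit
  link). Terms are tested by sequential deviance drops in formula order
  against χ². The full model is saturated (2k parameters, 2k grouped
  observations), so the interaction drop equals the additive model's residual
  deviance. The treatment-only and null deviances have closed forms (group
  fits are the pooled group proportions); the additive model is fitted by a
  batched IRLS (relative deviance tolerance 1e-8, 25 iterations max;
  non-convergence is flagged and the locus excluded from rate estimates with
  a reported count).
* **Binomial GLM, model 2** (`treatment` only). The two-group logit model is
  saturated in groups, so the MLE and its binomial-theory standard error have
  closed forms; the p-value is the Wald normal test — the z column of a
  standard binomial summary. (A t reference is sometimes quoted for this
  model; the normal is used here and documented, since dispersion is fixed at
  1.)
* **Quasibinomial GLM** (model 2 only; the interaction model would leave no
  residual df). Point estimates equal the binomial fit; φ̂ = Pearson X²/(2k−2)
  scales the standard errors by √φ̂ and the treatment effect is referred to
  t with 2k − 2 df. A perfectly fitted locus (X² = 0) yields t = ±∞ (p = 0)
  or 0/0 (p missing), as in the reference implementation.
* **Linear model.** OLS of C_A/CT on the treatment indicator; slope = mean
  frequency difference (line 2 minus line 1), t-test with 2k − 2 df. A locus
  with zero residual variance is flagged degenerate (p missing) unless the
  slope is also zero (p = 1), keeping downstream rate estimates well defined.

Sign convention throughout: effects are line 2 minus line 1 on the log-odds
(GLMs) or frequency (LM) scale for the 'A' allele.

All per-locus functions delegate to batch implementations operating on
(n_loci, k, 2) arrays; the closed forms and the batched IRLS are what make
10⁵–10⁶-locus studies run in seconds. Every statistic is verified against two
independent routes in the test suite: R's mantelhaen.test/glm/lm via Rscript,
and statsmodels/brute-force likelihood computations.

## Benchmarking

False-positive rates are the fraction of null loci with p ≤ α at each α in
{0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.5}, computed on null loci
only (seeded true positives would bias the small-α estimates at a 1%
contamination). The true-positive rate is the fraction of seeded true
positives at or below the 1st percentile of the pooled p-value distribution,
ties inclusive; loci with missing p-values are excluded from ranking and
denominator, with counts reported.

Corrections: Bonferroni (p ≤ α/m), Benjamini–Hochberg step-up, and Storey
q-values with π̂₀ estimated on the λ grid 0.05–0.95 and smoothed by a cubic
(degree-3 least-squares) fit evaluated at λ = 0.95 — a deterministic stand-in
for the natural-spline smoother of the original recipe; a fixed-λ = 0.5
fallback is available. π̂₀ estimates above 1 are capped with a warning, and
q-values are the usual reverse cumulative minima of π̂₀·m·p_(j)/j.

## Sync pipeline

popoolation2 sync files are parsed strictly by default (malformed lines raise
with the line number) or leniently (skip with a logged warning) for real-world
files. Biallelic calling sums A/T/C/G counts across pools and requires exactly
two alleles at or above min-count (default 10; the sum-across-pools reading
follows the popoolation2 convention); the major allele becomes the locus's 'A'
allele, giving one consistent orientation. Coverage filtering (defaults 10 and
500) counts only the two called alleles, per pool. Counts can pass through
raw, be rescaled to a fixed total, or to each cell's own n_eff given the
number of chromosomes per pool. The simulator exports the same format ('A'
allele as nucleotide A, alternative as T), and the round trip is lossless in
raw mode — the pipeline's p-values equal those computed directly on the
simulated tables.

## Study conditions and problem sizes

The packaged studies run at 10⁵ loci (the acceptance script and tests), a
scaled-down version of the 10⁶-locus design; at this size the Monte-Carlo
standard error of an FPR at α is √(α(1−α)/n) and of a TPR about 1.5
percentage points. Default parameters are the study conditions: θ = 0.2,
F_ST = 0.2 (0.1 and 0.3 are also realistic for tens to ~100 generations of
experimental evolution), k ∈ {2, 3, 4, 10}, N = 100 diploids, negative-
binomial coverage (mean 200, size 2, minimum 10) or fixed 100/200 or n_eff.

## What the simulation does and does not capture

The generator reproduces the two statistical pathologies that matter for test
choice — between-replicate heterogeneity from drift, and pseudoreplication
from reads oversampling a finite pool — under free recombination:

* loci are independent (no linkage, no haplotype structure);
* selection is a fixed additive shift on one line, not a response surface;
* no sequencing error, mapping bias or reference bias;
* single-generation drift summarised by F_ST rather than a forward
  Wright–Fisher process.

Passing benchmarks here therefore speaks to the *statistical* behaviour of the
tests under realistic count noise, not to genome-scan performance on linked,
selected, error-prone real data.

Two empirical notes from the packaged studies, both visible in the test suite:
the quasibinomial GLM and the LM track the 1–1 FPR line closely on the log–log
scale but are measurably conservative at moderate α (e.g. FPR ≈ 0.04 at
α = 0.05 for k = 4, fixed CT = 200) — with six residual df and a boundary-heavy
frequency spectrum the t reference is not exact; and the top-1% true-positive
rates are sensitive to how the seeded shift interacts with the U-shaped
ancestral spectrum, because loci with p_A near 0 carry almost no drift
variance (F_ST·p(1−p) → 0) and a +0.2 shift there is a nearly noise-free,
perfectly consistent signal that every test ranks highly and that survives
heterogeneity gating. Alternative constructions (clamped truncation; shifting
the drift mean rather than the drifted frequency) were evaluated and change
these rates only moderately; the renormalised-truncation, shift-after-drift
construction documented above is the one implemented.
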