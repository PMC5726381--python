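# poolfreqtest

Simulation and statistical testing of **consistent allele-frequency
differences** in replicated pool-seq experiments.

## The problem

Evolve-and-resequence (E&R) and other pooled-sequencing designs compare the
allele frequencies of two treatment groups across *k* replicated lines, SNP by
SNP, to find loci that respond **consistently** to selection. Each SNP is a
2 × 2 × *k* contingency table of allele counts (allele × treatment line ×
replicate). The field's default analysis, the Cochran–Mantel–Haenszel (CMH)
test, assumes homogeneous odds ratios across replicates and independent
counts — but genetic drift makes frequency differences heterogeneous between
replicates, and pool-seq read counts are pseudoreplicated draws from a finite
pool of *n* = 2*N* chromosomes. Both violations turn heterogeneity into
spurious "consistent" signal.

`poolfreqtest` provides:

* a **neutral drift simulator** for replicated pool-seq SNP data: ancestral
  frequency *p*<sub>A</sub> ~ Beta(4*N*<sub>e</sub>*u*, 4*N*<sub>e</sub>*v*);
  per-line frequency from a truncated normal with mean *p*<sub>A</sub> and
  variance *F*<sub>ST</sub>·*p*<sub>A</sub>(1 − *p*<sub>A</sub>); pool
  sampling Binomial(*n*, *f*); read sampling Binomial(*CT*, *x*/*n*) with
  negative-binomial, fixed or effective-sample-size coverage; optional seeded
  true positives (a consistent +0.2 frequency shift on one line);
* the **test suite** compared in the pool-seq literature, vectorised across
  loci: CMH (continuity-corrected) with the Mantel–Haenszel common odds ratio,
  the Woolf test of odds-ratio homogeneity and their combined consistency
  call; the replicated G-test partition (pooled effect + heterogeneity);
  binomial GLMs (`y = treatment + replicate + treatment:replicate` with
  sequential likelihood-ratio tests, and `y = treatment` with a Wald test);
  the **quasibinomial GLM** (Pearson dispersion φ̂ = X²/(2k−2), t-tests); and
  an ordinary linear model on frequencies;
* **benchmarking machinery**: empirical false-positive-rate curves over an α
  grid, true-positive recovery in the bottom 1% of the p-value distribution,
  and Bonferroni / Benjamini–Hochberg / Storey q-value corrections;
* a **popoolation2 sync reader** with biallelic SNP calling, coverage filters
  and count rescaling (raw, fixed total, or
  *n*<sub>eff</sub> = (*n*·*CT* − 1)/(*n* + *CT*)), so the same tests run on
  real data.

## Worked example

The following inconsistent table — the 'A' frequency difference points one way
in two replicates and the other way in the third — is declared highly
significant by the CMH test, and caught by the Woolf heterogeneity check:

```python
import numpy as np
from poolfreqtest import LocusTable, cmh_test, woolf_test, cmh_plus_woolf_call

table = LocusTable(
    counts_a=np.array([[66, 90], [72, 60], [69, 6]]),    # 'A' counts, line 1/2
    coverage=np.array([[71, 93], [75, 65], [90, 78]]),   # total counts per cell
)
cmh = cmh_test(table)
print(f"CMH chi-squared = {cmh.statistic:.2f}, df = {cmh.df}, "
      f"p = {cmh.p_main:.2e}, common OR = {cmh.effect:.2f}")
print(f"Woolf heterogeneity p = {woolf_test(table).p_main:.2e}")
print(f"consistency call at alpha = 0.05: p = {cmh_plus_woolf_call(table)}")
```

prints

```
CMH chi-squared = 55.66, df = 1, p = 8.63e-14, common OR = 6.98
Woolf heterogeneity p = 5.64e-07
consistency call at alpha = 0.05: p = 1.0
```

The combined call returns 1.0: despite the tiny CMH p-value the locus is not a
consistent difference, exactly the failure mode the quasibinomial GLM avoids.

The same workflow scales to full simulation studies from the shell:

```bash
poolfreqtest simulate --n-loci 100000 --tp-fraction 0.01 -k 4 --seed 1 --out run
poolfreqtest test --dataset run.counts.tsv --tests all --out results.tsv
poolfreqtest evaluate --results results.tsv --truth run.truth.tsv --out report.tsv
poolfreqtest sync --sync data.sync --pairs 1:4,2:5,3:6 --rescale neff:1000 \
    --tests glm_quasi --out sync_results.tsv
```

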