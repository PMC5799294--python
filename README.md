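# txdecomp

Transcriptional decomposition of binned expression data into positionally
dependent and positionally independent components, with downstream calling of
expression-associated domain (XAD) boundaries, expression-only prediction of
enhancer–promoter (EP) interactions, and trait-SNP enrichment statistics.

## The problem

Steady-state RNA output at a locus mixes two signals. Part of it tracks the
locus's chromosomal neighbourhood — genes inside the same topologically
associating domain (TAD) or chromatin compartment tend to be coordinately
active — and part of it is locus-specific regulation that does not care about
position. `txdecomp` separates the two from expression data alone (replicated
CAGE or RNA-seq tag counts in fixed genomic bins, 10 kb by default), so that
domain structure, boundaries and regulatory interactions can be inferred for
cell types where chromatin-conformation data do not exist.

## The model

For bin *i* with replicate counts *Y*<sub>ir</sub> and library depths
*E*<sub>r</sub>, the mean log expression is decomposed as

    nu_i = alpha + PD_i + PI_i,        mu_ir = E_r * exp(nu_i)

* **PD** (positionally dependent): a first-order random walk,
  PD<sub>i</sub> − PD<sub>i+1</sub> ~ N(0, τ<sub>rw</sub><sup>−1</sup>),
  capturing expression shared between neighbouring bins. The RW1 structure
  matrix is scaled so its generalised inverse has unit average diagonal,
  making 1/τ<sub>rw</sub> the average marginal prior variance.
* **PI** (positionally independent): iid N(0, τ<sub>iid</sub><sup>−1</sup>)
  effects, capturing bin-local regulation.
* **Counts**: a hurdle negative binomial — an explicit zero mass *p* and a
  zero-truncated NB(μ, k) on the positive counts — accommodating the extreme
  sparsity of tag counts in heterochromatic or poorly mappable bins. A
  mixture-ZINB family and a Gaussian family (used for exact validation) are
  also available.

Inference is Laplace-approximate MAP over the latent field (sparse Newton
iterations) with empirical-Bayes optimisation of the hyperparameters
(τ<sub>rw</sub>, τ<sub>iid</sub>, k); PD carries a per-chromosome sum-to-zero
constraint so the intercept absorbs the level. On a Gaussian likelihood the
fit is exact (it equals the penalised sparse linear solve).

Downstream, the fitted components feed:

* **XAD boundaries** — ranked local maxima of the boundary score
  X = PD·|ΔPD|/PD<sub>stab</sub>, allocated across chromosomes in proportion
  to positive-PD content, split into up/down jumps, cross-cell filtered;
  plus aggregate profiles around boundaries and the Hi-C directionality index
  for validation against contact maps.
* **EP interaction prediction** — bait–target pairs at 6–200 bin separation
  described by ~30 expression-only features (component values, differences,
  SDs, stabilities, XAD insulation, eRNA output, directionality, cross-cell
  Kendall correlations, distance), classified by a 10-fold cross-validated
  random forest with per-distance SMOTE balancing inside each training fold
  and per-distance-band F1-optimised probability cutoffs.
* **Trait-SNP enrichment** — Pearson χ² on 2×2 tables of trait SNPs vs
  foreground bins (positive components, boundary neighbourhoods, target
  enhancers), BH-corrected per component.

## Worked example

Simulate replicated counts over a planted RW1 + iid latent structure and
recover it:

```python
import numpy as np
from txdecomp.simulate import simulate_counts
from txdecomp.model import DecompositionModel

Y, depths, truth = simulate_counts(
    n_bins=500, n_reps=3, tau_rw=1.0, tau_iid=4.0, k=5.0, p0=0.3, seed=1
)
res = DecompositionModel(Y, depths=depths, family="hurdle").fit()
print(res.summary())
print("correlation with planted PD:",
      round(float(np.corrcoef(res.pd, truth.pd)[0, 1]), 3))
```

prints

```
Transcriptional decomposition results
==============================================
family:          hurdle
bins:            500
replicates:      3
converged:       True (2 Newton steps)
log marginal:    -4844.001
----------------------------------------------
alpha:           -12.2110 (sd 0.0363)
tau_rw:          1.356  [estimated]
tau_iid:         3.665  [estimated]
k (NB size):     4.82  [estimated]
p0 (zero mass):  0.3007
----------------------------------------------
PD: mean -0.0000, sd 1.3188; PI: mean -0.0000, sd 0.3469

correlation with planted PD: 0.99
```

The estimated precisions sit near the planted values (τ_rw = 1, τ_iid = 4,
k = 5, p0 = 0.3): the smoothness penalty of the random walk, the variance of
the independent effects and the NB dispersion are all identified from the
replicated counts, and the recovered PD track correlates at 0.99 with the
planted one. `res.to_frame()` gives the per-bin posterior means and SDs;
`txdecomp.xad.detect_boundaries` turns PD tracks from several cell types into
ranked XAD boundary calls.

A command-line layer mirrors the library (`txdecomp simulate-counts`,
`decompose`, `xad`, `di`, `train`); every subcommand is byte-reproducible
under a fixed seed.

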