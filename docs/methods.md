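# Methods

`fetalfrac` estimates the fetal fraction (FF) of cell-free DNA in maternal
plasma from shallow whole-genome paired-end sequencing, using the fragment
*length* distribution, the chrY read count, or both, and evaluates those
estimators against the Y-based reference the way clinical cohorts are
evaluated: many random train/test splits with paired folds.

## The estimation problem

In a pregnancy with a male fetus, the fraction of reads mapped to chrY
grows linearly in FF between two baselines (residual female-fetus
mismapping at FF = 0, adult-male plasma at FF = 1), so

    FF_Y = (%chrY − female%chrY) / (male%chrY − female%chrY)

is an essentially assumption-free reference — but it only exists for male
fetuses. Fetal (placental) cfDNA fragments are, however, systematically
shorter than maternal ones, so the 171-vector of fragment-length
proportions L50..L220 carries FF information regardless of fetal sex.
The package implements five length-profile estimators:

* **FRAC** — the ratio of summed proportions over a short interval I1 to
  those over a second interval I2, with an exhaustive search over all
  consecutive-interval pairs (overlap allowed) for the pair whose ratio
  best correlates with the reference, plus an OLS calibration of the raw
  ratio to FF units (the ratio itself is dimensionless; the calibration
  exists so that MSE/MAE can be reported on the FF scale).
* **NLRM** — per-length weights inside the numerator and denominator of
  that ratio, `FF_i = Σ_r M_r L_{r,i} / Σ_p N_p L_{p,i}`, fitted by
  quasi-Newton least squares. The ratio is invariant to a common rescaling
  of all weights, so the first denominator weight is pinned to 1; the
  remaining |I1|+|I2|−1 weights are free.
* **LRM** — ordinary least squares of FF on all 171 proportions
  (minimum-norm: proportions sum to one, so the design is always
  rank-deficient with an intercept).
* **SVR** — linear-kernel ε-insensitive support-vector regression on
  standardized proportions, C = 1.0, ε = 0.01, tol = 0.001.
* **MLP** — a multilayer perceptron with two tanh hidden layers of 25
  units on standardized proportions, trained with an adaptive-gradient
  optimizer (adam), seeded.

A linear **combiner** regresses the Y-based reference on the SVM
prediction, the externally supplied SeqFF value (a position-based
estimator whose pretrained model this package deliberately does not
reimplement; its output is an input column or a simulator surrogate), and
optionally the weak sample attributes gestational age (GA), maternal BMI
and DNA library concentration (LC). Because the two main predictors read
nearly unrelated fragment attributes (lengths vs. genomic positions),
their combination outperforms either alone.

## Numerical choices

* **Standardization** uses population (divide-by-N) variance fitted on the
  training fold only; constant features get scale 1 and map to 0.
* **Interval search** enumerates interval pairs on a stride grid
  (endpoints on `{lo, lo+stride, …}`); at stride 1 over [50, 220] there
  are 14 706² ≈ 2.2 × 10⁸ pairs, at stride 4 about 9 × 10⁵, which runs in
  seconds via prefix sums and a vectorized Pearson correlation. Ties
  (within 10⁻¹²) break toward smaller total width, then lexicographically
  smaller (a1, b1, a2, b2).
* **NLRM optimization** minimizes the *mean* squared residual (per-sample
  scale) by L-BFGS with the analytic gradient, from the all-ones start
  (the FRAC solution), gradient tolerance 10⁻⁸, relative function
  tolerance 10⁻¹⁰, at most 500 iterations (configurable). A quadratic
  penalty activates if any sample's weighted denominator falls below 10⁻⁶
  of its initial value. The per-sample scale matters: on the raw-SSE scale
  the 61-weight problem is so ill-conditioned that quasi-Newton iterations
  crawl for thousands of steps without meeting any gradient tolerance.
  Exhausting the iteration budget raises an error carrying the
  best-so-far weights.
* **SVR solver.** The SVR objective is solved in the primal by L-BFGS on
  a Huber-smoothed ε-insensitive loss (smoothing width 2 × 10⁻³). With
  171 features and thousands of samples this is two orders of magnitude
  faster than SMO on the dual while agreeing with libsvm to ~10⁻³ in
  held-out predictions; `solver="libsvm"` selects sklearn's SVR, which
  the test suite uses as an independent cross-check of the primal route.
* **MLP defaults** (max_iter 3000, learning rate 3 × 10⁻³, tol 10⁻⁹,
  patience 50) are chosen so that FF-scale targets (σ ≈ 0.04) actually
  converge; sklearn's stock tolerances stop training almost immediately
  at this target scale.
* **GC correction** fits a LOESS curve (span 0.3) of per-bin fragment
  count on per-bin GC over usable autosomal bins (GC defined where ≥ 50%
  of reference bases are non-N, count > 0) and reweights each bin by
  `global_mean / fitted(GC)`. Default bin size 20 kb. chrX is corrected
  like an autosome; chrY totals always pass through uncorrected because
  its small mappable fraction leaves too few reads for a stable fit.
* **Fragment length** is the span from the leftmost to the rightmost
  mapped base of a properly paired, primary, non-duplicate read pair with
  MAPQ ≥ 40 — i.e. the absolute template length; each fragment is counted
  once from its first-in-pair record.
* **Out-of-range FF estimates** (Y-based or combined) are returned
  unclipped with an in-range flag, so downstream regressions are not
  censored.

## Evaluation protocol

`repeated_split_evaluate` draws, per repeat, a uniform random 80/20
partition (floor on the training size: 2454 samples → 1963/491); every
estimator is fitted on the identical training fold — including its
standardizer and any out-of-fold sub-predictions — and scored on the
identical test fold by Pearson r, MSE and MAE against the Y-based
reference. The master seed spawns per-repeat seeds (`SeedSequence`), so
results are byte-reproducible and method comparisons are paired. Combiner
training uses 5-fold out-of-fold SVM predictions by default to avoid
leaking the training fit into the combiner weights (`out_of_fold=False`
gives the naive variant).

The weighting experiment duplicates training samples whose reference FF
is below 10% (k = 1..4 copies; equivalently integer sample weights, an
algebraic identity that is tested) and reports test MAE separately for
the low and high strata. Samples exactly at the threshold count as low.

## The synthetic cohort

No patient data ships with the package, so the simulator generates a
cohort with the statistical structure the estimators assume.
Per sample, with FF drawn from a truncated normal (mean 0.10, sd 0.04,
bounds [0.02, 0.30] — the low bound keeps the low-FF stratum populated):

* **Lengths.** A two-component mixture: maternal fragments ~ discretized
  normal (166 ± 9 bp), fetal (143 ± 9 bp), truncated to [50, 220].
  Sequencing depth is a multinomial draw of 5 × 10⁵ fragments per sample
  (unit tests use 10⁴; `analytic_profiles` gives the infinite-depth
  limit). Mean fragment length therefore decreases in FF.
* **Two FF-information channels.** The mixing proportion expressed in the
  bulk length shift is FF plus Gaussian noise (sd 0.025, "fragmentation
  heterogeneity"); independently, a 10-bp nucleosomal ladder below 134 bp
  is modulated with amplitude 1.5 × (FF + noise, sd 0.03). Only
  estimators with per-length weights (NLRM within its window, LRM/SVR/MLP
  everywhere) can read and combine both channels; a contiguous
  unit-weight interval ratio essentially reads the first.
* **Nuisance modes.** Per-sample shift of both component means (sd
  1.5 bp), per-sample width jitter (sd 0.8 bp), and eight smooth
  multiplicative "batch" bumps on the length axis (per-sample N(0, 0.05)
  coefficients). A full-profile linear model can project these out; a
  single interval ratio cannot cancel them all.
* **chrY.** `chrY = f + FF·(m − f) + noise` with baselines f = 2 × 10⁻⁴,
  m = 2 × 10⁻³ and noise sd 2 × 10⁻⁵ (counting noise at shallow depth);
  inverting this line is the Y-based reference, which then correlates
  ≈ 0.96 with true FF — the reference is treated as ground truth exactly
  as in clinical practice, noise included.
* **SeqFF surrogate** = FF + independent noise calibrated (closed form
  `sd·sqrt(1/ρ² − 1)`) to correlate 0.877 with true FF.
* **Attributes** GA/BMI/LC are linear-Gaussian in standardized FF with
  target correlations 0.1 / −0.33 / −0.22 and marginals 14 ± 2 weeks,
  25 ± 4 kg/m², 10 ± 3 units.

The channel and nuisance parameters were fixed in one calibration pass so
that the cohort reproduces the qualitative landscape reported for
clinical data — SVR tracking true FF at r ≈ 0.85 (within the design band
0.75–0.95), median test correlations ordered FRAC < NLRM ≤ LRM ≈ SVR <
SeqFF < combined, a combined estimator that beats both single predictors
in ≈ 100/100 paired splits, and a weighting experiment whose low-FF MAE
falls monotonically in the multiplier while high-FF MAE rises — and were
not adjusted afterwards. The ladder channel is on by default precisely
because without a second, weight-readable information channel a searched
interval ratio is statistically sufficient and the more flexible models
can never beat it — a two-component mixture alone cannot reproduce the
clinical ranking.

What passing these tests does *not* show: the simulator's profiles are
parametric idealizations (no GC-length interaction, no mappability
structure, no read-level errors, no trisomic genomes, no female-fetus
chrX signal); absolute correlation levels on real cohorts depend on
library preparation and depth, and the searched optimal intervals here
((130, 138)/(154, 158) at the default seed) are properties of the
synthetic length distributions, not of any real cohort.

## Problem sizes used by the shipped experiments

The repeated-split experiments run at n = 2000 samples, 100 splits, with
the default depth; the attribute-correlation check at n = 5000 (attribute
structure is depth-independent, so it uses nominal depth); the
interval-search-vs-brute-force equivalence on windows of ≤ 8 lengths,
where exhaustive enumeration is exact. The MLP is reported from a single
80/20 split: at ~8 s per seeded fit the full 100-repeat protocol buys no
additional insight for its cost, and its single-split correlation sits in
the same range as LRM/SVR.

## Known limitations

* The Y-based reference and hence all supervised targets exist only for
  male-fetus cohorts; applying trained length models to female-fetus
  samples is an extrapolation the package does not validate.
* SeqFF is consumed, never computed: feeding the combiner requires an
  externally produced SeqFF column (or the surrogate).
* The neural-network configuration this architecture reproduces is
  described with a 55-unit input layer, which is inconsistent with the
  171-feature input; the MLP here takes all 171
  features and keeps only the hidden architecture (25 + 25, tanh). A
  feature-selection step may have existed but is not described, so it is
  not guessed at.
* `%chrY` uses raw (uncorrected) totals in numerator and denominator by
  default; GC-corrected denominators are a config choice.
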