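# Methods

## Estimation model

For each target individual the vector of counted-allele dosages
*y* ∈ {0,1,2}<sup>M</sup> is regressed on the design matrix *X* whose
column *k* is twice the allele-frequency vector of founder population *k*
(the expected dosage of a pure population-*k* individual under
Hardy–Weinberg equilibrium). The genome proportions are the least-squares
coefficients constrained to the unit simplex:

    b̂ = argmin (y − Xb)′(y − Xb),   b ≥ 0,   Σb = 1  (or Σb ≤ 1).

Key assumptions: founder frequencies are known constants (estimated once
from labeled reference individuals and not updated during fitting);
Hardy–Weinberg holds within founder populations; residuals are treated as
homoscedastic and uncorrelated across markers. Linkage disequilibrium
between markers is *not* modelled — it reduces the effective number of
independent observations and hence the efficiency, but not the
unbiasedness, of the estimator. A generalised-least-squares extension with
a non-diagonal residual covariance would account for it and is out of
scope here.

The sum-to-one (equality) mode is the natural choice when the founder list
is believed complete. The sum-at-most-one (inequality) mode lets the
unassigned remainder absorb genome from unlisted populations and is the
default in the under- and miss-specified experiment designs. On realistic
cohorts the two modes give nearly identical summary statistics; their
per-cell estimation errors correlate above 0.99.

## Solver

The objective reduces to the N-dimensional quadratic b′Gb − 2c′b with
G = X′X and c = X′y, so cost is essentially independent of the number of
markers once G and c are formed. We minimise it with SLSQP
(scipy.optimize) from the barycentre and then *polish* the result exactly:
the active set suggested by the SLSQP point is frozen, the corresponding
KKT system is solved by a direct linear solve, and the polished point is
accepted only if it is primal feasible and its Lagrange multipliers have
the correct signs. This yields KKT residuals at the 1e-8 level on
well-conditioned problems. Numerical contracts:

* constraint satisfaction to 1e-6 on output; negative coefficients within
  1e-8 of zero are clipped to exactly 0 and equality-mode vectors are then
  renormalised to sum exactly 1;
* missing dosages are deleted pairwise (the marker row is dropped for that
  individual only);
* if the reduced Hessian on the active support is singular beyond 1e-10
  (e.g. duplicated design columns), the returned minimiser is valid but
  individual coefficients are not identifiable; the estimate is flagged
  `degenerate`;
* the solver is deterministic for fixed inputs.

### Verification oracle

`grid_oracle` minimises the same objective over every point of the simplex
grid at a chosen resolution (inequality mode adds a zero-design slack
coordinate, turning the sum constraint into an equality). Moderate grids
are enumerated literally; for very large grids (e.g. the ~1.7×10⁸ points
of the sum≤1 region of three populations at step 0.001) the innermost grid
axis is minimised in closed form — the objective restricted to that axis
is a quadratic with constant curvature, so its integer minimiser lies at
the clipped floor/ceil of the stationary point. Both paths return the
identical grid minimiser with ties broken toward the lexicographically
smallest vector, and they are cross-checked against each other in the test
suite. Note the oracle's minimum sits *above* the continuous optimum by up
to step²-level discretisation error; solver correctness is therefore
asserted as "never worse than the oracle" rather than two-sided equality.

## Founder panel

Frequencies are plain mean dosage / 2 per (marker, population) cell with
missing calls excluded — no pseudo-counts or shrinkage, since the model
treats them as known constants and any regularisation would change X. A
cell with zero observations is an error (the caller may drop the marker).
Monomorphic markers are retained; an optional frequency filter (e.g. keep
0.01 ≤ p ≤ 0.99 across the whole reference sample) is exposed as
preprocessing. The counted allele is fixed per marker at panel
construction; `align_markers` harmonises target data to it (flipping
counts as 2−x where the counted allele is swapped, dropping irreconcilable
markers) so that per-file "minor allele" conventions can never corrupt the
design.

For the miss-specified (type-2) design the panel is reduced to two
columns: the focal population's expected allele content, and the mean
allele content of `n_sample` genotypes (default 500) drawn uniformly
without replacement from all non-focal reference individuals. The second
column is computed from the sampled genotypes directly, so it reflects the
realised population mix of the sample rather than equal population
weights.

## Admixture simulator

The simulator emulates how admixed validation cohorts are built from real
reference panels:

1. **Random phasing.** Each founder genotype is split into two
   haplotypes; heterozygous markers assign the counted allele to either
   haplotype with probability 1/2 independently per marker. (Phase is
   irrelevant to dosage-based estimation but determines which alleles
   travel together through crossovers.) Missing founder genotypes are
   imputed by a Hardy–Weinberg draw from the population frequency before
   phasing.
2. **Gametes.** A gamete copies from one of the two parental haplotypes,
   starting from a fair coin, switching source at exactly *n* crossover
   breakpoints (default 25; 5 as the low-recombination variant) drawn
   uniformly without replacement from the M−1 inter-marker intervals of
   the single concatenated marker sequence. No chromosome structure or
   genetic map is used, and the crossover count is fixed rather than
   Poisson.
3. **Random mating.** Sexes are assigned uniformly at random. Each round
   draws `n_pairs` sires and dams with replacement (round 1 from the
   founders, later rounds from the previous round's offspring — so a
   parent can appear in several matings and selfing of an offspring pair
   member is possible) and produces one offspring per pair. The cohort is
   all rounds' offspring. The cattle-style preset is 5 rounds × 1,000
   pairs (5,000 admixed); the human-style preset is read as generation 1:
   400 parents → 200 offspring (one expected progeny per parent), then
   200 parents → 200 offspring per generation (two expected progeny per
   parent), totalling 1,000 across F1–F5.
4. **Truth tracking.** Every allele carries its founder-population origin
   label, so an offspring's true proportions are exact rationals with
   denominator 2M that sum to one; these are what every evaluation metric
   is computed against.

Synthetic founders, when no real reference data are supplied, follow a
Balding–Nichols model: ancestral frequencies uniform on [0.05, 0.95],
population frequencies Beta-distributed around them at a chosen
differentiation F<sub>ST</sub>, genotypes binomial(2, p). The optional
planted-relative feature redraws the last population around another
population's realised frequencies at a small divergence (default study
uses 0.02, giving a frequency-column correlation near 0.97) to emulate
closely related breed pairs.

What the generator does **not** emulate: linkage disequilibrium within
founder populations (genotypes are independent across markers given the
frequencies), chromosome structure, genetic-map heterogeneity, mutation,
selection, or non-random mating. Passing tests therefore demonstrate
correctness of the estimator under its own assumptions and robustness to
founder-set misspecification — not robustness to strong LD, which real
dense panels will exhibit.

## Experiment designs and study sizes

* **Fully specified**: all founder columns in X; scored over every cell.
* **Type-1 (under-specified)**: one truly contributing population removed;
  inequality constraint; the removed population's cells are not scored;
  results are reported per category of the removed population's true share
  (0%, >0–≤25%, >25–≤50%, >50–≤75%, >75–<100%, 100%, boundaries exactly as
  printed, upper-inclusive), together with the mean estimation excess per
  remaining population, which identifies the population absorbing the
  omitted genome (expected: the closest relative by frequency
  correlation).
* **Type-2 (miss-specified)**: two-column design (focal + sampled
  background); inequality constraint; scored on the focal column over
  individuals whose true focal share is > 0.

The packaged study (tests and `scripts/acceptance.py`) runs these designs
at a desk scale chosen to keep the full pipeline in the tens of seconds:
8 founder populations (one a planted relative), 4,000 markers, 100
reference individuals per population, F<sub>ST</sub> 0.1, and 5 rounds ×
200 pairs (1,000 admixed individuals) at 25 crossovers. At this scale the
fully-specified design reaches R ≈ 0.97 with MSE ≈ 0.0013 and no
detectable bias in equality mode, the type-1 0%-category matches the full
model within 0.01 MAE with the planted relative absorbing roughly half of
the omitted genome share, and the type-2 focal correlation is ≈ 0.96 —
the same regime the method exhibits on full-size cattle and human
cohorts.

Correlations (the R statistic and the error correlation between estimate
sets) are Pearson correlations of the flattened L×N tables centred at
their grand means — not per-population centring — and are reported as
missing (NaN, with a warning) when either flattened vector has zero
variance.

## Known limitations

* No standard errors or confidence intervals for b̂ are provided.
* LD-aware (generalised least squares) estimation is not implemented.
* PLINK binary (.bed) input is not supported, only text .ped/.map;
  strand-ambiguous (A/T, C/G) markers are reconciled by allele label only
  and dropped when labels cannot be matched.
* With near-duplicate founder columns individual coefficients become
  weakly identified; the solver still returns a global minimiser but the
  split between the correlated columns is noisy (flagged `degenerate`
  only when the reduced Hessian is numerically singular).
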