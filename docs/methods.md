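# Methods

## Sample design and time axis

A *kinetic* is one biological-replicate time course: by default nine samples
over one day at 3-h spacing with a duplicated dawn point,
tods = (0, 3, 6, 9, 9, 12, 15, 18, 21), under a 12:12 schedule with lights on
at 9 h and off at 21 h (half-open convention: the 9-h samples are light, the
21-h sample is dark). Three kinetics are laid end to end on a concatenated
axis t = 24·(k−1) + tod, so a Fourier fit over the full 72-h span treats
biological replicates as consecutive days. This is what makes harmonic 3 of
the 72-h fundamental the 24-h diel component; the harmonic numbering
everywhere in the package assumes it. The period defaults to 24 h × (number
of kinetics) and both the harmonic set and the period are configurable.

## Synthetic data

The generator emulates a normalised two-colour microarray time course at the
level the analysis consumes: a genes × samples log₂ matrix.

- Rhythmic gene in phase-group c:
  baseline + (amplitude_c/2)·cos(2π(tod − phase_c)/24) + N(0, noise_sd²),
  i.i.d. across samples. Defaults: baseline 6.0 log₂ units over a unit linear
  background, noise_sd 0.3 log₂ units. The baseline is required for internal
  consistency: without it a ±1 log₂ oscillation around zero would sit below
  the 2.6× detection limit and the generator's "expressed" genes would fail
  its own screen.
- Arrhythmic genes: N(baseline, noise_sd²) at every sample.
- Non-expressed genes: drawn uniformly in (0, 2.6 × background) on the
  linear scale, so they fail the detection rule at every sample by
  construction (only the threshold, not the sub-background signal model, is
  dictated by the screened analysis).
- Missing values masked i.i.d. at rate `missing_frac` (default 0 in the API,
  0.02 in the CLI demo).

All draws flow from one `numpy` Generator seeded by the caller; identical
arguments give byte-identical matrices. What the generator does **not**
emulate: dye bias, print-tip structure, spatial artefacts, heteroscedastic
noise, correlated replicates, or non-sinusoidal waveforms (richer shapes can
be injected through extra harmonics but the default is a cosine). Passing
recovery tests on these data therefore demonstrates correctness of the
algorithms under the model's own assumptions, not robustness to real-array
artefacts.

## Screening cascade

1. **Missingness**: drop genes missing in strictly more than 70 % of samples.
2. **Detection**: expressed iff linear signal (2^value) ≥ 2.6 × the
   per-sample background at least once; the comparison is inclusive (a tie
   counts as expressed). Genes with no observed values are flagged
   not-expressed with a warning.
3. **ANOVA**: per gene, a two-way fixed-effects model
   y ~ time-of-day + kinetic (no interaction); F and p test the time-of-day
   effect (type-II sum of squares), selected iff p < 10⁻³. An equivalent
   global gene-oriented ANOVA over (gene, kinetic, replicate) factors, for
   balanced designs, into exactly these per-gene tests, which are verifiable
   against permutation and `statsmodels` oracles.
   Complete genes share projection matrices and run vectorised; genes with
   missing entries fall back to per-gene least squares. Degenerate genes:
   zero residual variance gives p = 0 if the between-time variance is
   positive, else (constant gene) F = 0, p = 1. A design in which some
   time-of-day level occurs in fewer than two kinetics is rejected up front
   with the level named.
4. **PCA dispersion**: genes are observations over sample dimensions; each
   gene is centred on its own mean and missing entries are mean-imputed
   (zero after centring). The score is the squared projection onto the first
   two principal axes (computed by SVD of the row-centred matrix — no
   column centring, which would change the projection being scored); the
   top `n_select` genes are kept, ties broken by input order.
5. **Amplitude strata**: amplitude = max − min of the per-time-of-day median
   profile (the median absorbs single-replicate outliers); histogram over
   unit bins [0,1) … [8,9], right-open except the last, values above 9
   clipped into the top bin.

## Model core

Cluster evidence: for stacked observations Y (each member gene contributes
its own copy of the basis rows, rows with missing values dropped, never
imputed),

- posterior precision A = BᵀB + v₀⁻¹I, posterior mean
  β̂ = A⁻¹(BᵀY + v₀⁻¹m₀),
- aₙ = a₀ + n/2, bₙ = b₀ + ½(YᵀY + m₀ᵀm₀/v₀ − β̂ᵀAβ̂),
- log evidence = −(n/2)log 2π + ½(log det A⁻¹ − p log v₀)
  + a₀ log b₀ − aₙ log bₙ + log Γ(aₙ) − log Γ(a₀),

evaluated via Cholesky factorisation. Only the sufficient statistics
(BᵀB, BᵀY, YᵀY, n) enter, so merging clusters is addition of statistics —
the property the agglomerative search exploits.

Hyperparameter defaults: m₀ = 0, v₀ = 100, a₀ = b₀ = 0.001 — weakly
informative on log₂-ratio data while keeping the evidence proper; the prior
coefficient covariance is isotropic (σ²v₀I) rather than design-dependent.
All four are config-exposed. The tests cross-check the closed form against a
brute numerical integration that never completes the square (prior-centred
Gauss–Hermite quadrature over β nested in adaptive quadrature over log σ²).

## Agglomerative search

Every gene starts as a singleton. "Most similar in covariance structure" is
operationalised as the merge with the largest evidence gain
Δ = log ev(i∪j) − log ev(i) − log ev(j): it is the only similarity consistent
with scoring partitions by summed log evidence, and under the conjugate
model it reduces to similarity of fitted covariance structure. The score is
recorded at initialisation and after each of the G−1 merges; the partition
attaining the maximum recorded score is returned (earliest step on ties).
Pairwise gains are cached with O(G²) memory and only pairs touching the last
merge are recomputed; ties between candidate merges break to the
lexicographically smallest pair in cluster-creation order, which makes runs
exactly reproducible. The partition prior is uniform by default (score =
Σ log evidences); a Crowley/DP-style cohesion term α^{#clusters}·∏Γ(n_c) is
available behind `partition_prior="cohesion"`. Pooled mode shuffles genes
with the run seed and splits them into ⌈G/pool_size⌉ near-equal pools
clustered independently; no cross-pool reconciliation is attempted, and the
pooled mode is an option for memory-constrained settings rather than the
default (direct agglomeration handles thousands of genes).

## Rhythm scoring

THR = (a₃² + b₃²) / Σ_{i∈H}(aᵢ² + bᵢ²) over the included harmonic set
H = {1, 3, 6, 9}, constant term excluded: the mean level carries no rhythm
information, and the data fed to clustering are per-gene normalised anyway.
Both the numerator harmonic and the denominator set are overridable for
non-default designs. Classification is strict: THR > 0.4 rhythmic,
THR > 0.6 robust. A cluster with exactly zero harmonic power is flagged flat
with THR 0. The phase is (24/2π)·atan2(b₃, a₃) mod 24 — the time of day at
which the fitted diel component peaks — undefined (reported as NA) when
a₃ = b₃ = 0. The polar table/plot encodes angle = 2π·phase/24, radius = THR
and dot size linear in cluster size, with the dark phase shaded.

A known property worth stating: for a genuinely flat cluster the fitted
harmonic coefficients are pure noise, so its THR is approximately
Beta(1, 3)-distributed (two numerator against eight denominator degrees of
freedom) *regardless of noise level or cluster size* — about one flat
cluster in five will exceed 0.4 by chance. THR separates rhythmic waveform
shapes; it is not a calibrated test against flatness. Screens that remove
non-differential genes before clustering (as the full pipeline does) largely
avoid the situation.

## Problem sizes and numerical choices

The recovery benchmarks run 6 phase groups × 40 genes (240 genes × 27
samples) per seed and the null-calibration suite 2000 genes, sizes at which
the full greedy trajectory is exact (no pooling) and the suite completes in
a few minutes on one CPU. Partition-score identities are asserted to 1e-8;
analytic THR cases use an essentially flat prior (v₀ = 10⁹) since shrinkage
under the default prior perturbs coefficient ratios at the 1e-4 level,
which is invisible in practice but larger than the analytic tolerances.
Evidence computations guard bₙ with a tiny floor against cancellation on
exactly-representable data. SVG output fixes the matplotlib hash salt and
omits the date so repeated runs are byte-identical.

## Known limitations

- The per-gene ANOVA assumes Gaussian noise and a balanced-enough design;
  its p-values are exact under those assumptions (verified by calibration),
  but permutation p-values on the same data differ by a data-conditional
  term of order 1/√n — the two agree statistically, not gene-by-gene.
- Greedy agglomeration is not guaranteed to find the global partition
  optimum; on clearly separated instances it does (verified exhaustively at
  8 genes), and on hard instances it is a lower bound.
- THR's flat-cluster behaviour described above.
- On real data the number of clusters in the best partition depends
  sensitively on the prior hyperparameters; the defaults here are weakly
  informative choices, not values fitted to any dataset, so cluster counts
  from other analyses of similar designs should not be expected to match.
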