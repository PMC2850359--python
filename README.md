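# dielbfc

Screening, Bayesian Fourier clustering and rhythmicity scoring for
light/dark-entrained (diel) transcriptome time courses.

Genome-wide expression surveys of organisms entrained to a 12:12 light/dark
cycle — the motivating case is the marine picoalga *Ostreococcus tauri*
sampled every 3 h over three replicate days — produce a gene × sample matrix
of log₂ expression in which most transcripts rise and fall with the
photoperiod. `dielbfc` re-implements that analysis as a tested, reusable
pipeline for anyone working with bulk diel/circadian time courses:

1. **Screening** — remove genes with excessive missing data (> 70 % of
   samples), keep genes detected above background (linear signal ≥ 2.6 ×
   background at least once), select differentially expressed genes with a
   per-gene two-way ANOVA (time-of-day effect adjusted for the replicate
   kinetic, *P* < 10⁻³), and keep the `n_select` genes with the best
   dispersion on the first two principal axes. Amplitudes (Δlog₂
   peak-to-trough of the per-time-point median profile) are binned into
   unit-width strata.
2. **Bayesian Fourier clustering (BFC)** — each cluster's stacked curves
   follow the linear model **Y = Bβ + ε**, ε ~ N(0, σ²I), where **B** is a
   Fourier design over the concatenated 3-day axis (harmonics {1, 3, 6, 9}
   plus the constant: 9 parameters; harmonic 3 of the 72-h fundamental is the
   24-h diel component). With the conjugate normal–inverse-gamma prior
   β | σ² ~ N(m₀, σ²v₀I), σ² ~ InvGamma(a₀, b₀) the marginal likelihood
   (evidence) is closed-form. Starting from singletons, the pair of clusters
   whose merge most increases the partition score (sum of cluster log
   evidences) is joined until one cluster remains; the best-scoring partition
   along the trajectory is returned. A pooled mode clusters random gene pools
   independently for very large gene sets.
3. **Rhythm scoring** — each cluster gets a third harmonic ratio,
   THR = (a₃² + b₃²) / Σ_{i∈{1,3,6,9}} (aᵢ² + bᵢ²), the fraction of fitted
   harmonic power in the 24-h component; THR > 0.4 is rhythmic, > 0.6
   robustly rhythmic. The phase (time of day at which the diel component
   peaks) places each cluster on a polar clock plot with radius = THR and dot
   size ∝ cluster size.

A first-class synthetic-data module generates matrices with the same
statistical structure (3 kinetics × 9 time points with a duplicated dawn
sample, rhythmic cosine genes of chosen phase/amplitude, arrhythmic and
non-expressed genes, missing values) together with ground-truth labels, so
every stage is exercised without any external download.

## Worked example

```sh
dielbfc simulate --out-dir demo --seed 1
dielbfc run --expression demo/expression.tsv --sample-sheet demo/samples.tsv \
            --out-dir demo/out --seed 1
```

which prints the stage summary

```json
{
  "anova_selected": 100,
  "clusters": 4,
  "dropped_missingness": 0,
  "expressed": 130,
  "genes_in": 140,
  "n_samples": 27,
  "pca_selected": 100,
  "rhythmic_clusters": 4,
  "robust_clusters": 4
}
```

The simulated cohort has 140 genes: 100 rhythmic (4 phase groups × 25),
30 arrhythmic and 10 non-expressed. The detection filter removes exactly the
10 non-expressed genes (130 expressed); the ANOVA keeps the 100 genes with a
time-of-day effect; clustering recovers the 4 phase groups, all robustly
rhythmic. `demo/out/rhythm.tsv` reports each cluster's size, THR and peak
time, e.g.

```text
cluster_id  size  thr       phase_h    rhythm_class
P1_C1       25    0.998095  0.012969   robust
P1_C2       25    0.999540  18.038337  robust
```

— THR ≈ 1 (essentially all harmonic power is diel) and phases within a few
minutes of the injected 0 h and 18 h peaks. `demo/out/polar.svg` is the
clock-face summary, and `screen.tsv`, `clusters.tsv`, `trajectory.tsv` and
`amplitude_histogram.tsv` carry the per-gene screening report, the cluster
assignment, the merge trajectory with scores, and the Δlog₂ amplitude
strata. The same API is available from Python (`dielbfc.make_design`,
`simulate_expression`, `run_agglomeration`, `thr`, …).

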