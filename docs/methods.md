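# Methods

## The problem being diagnosed

Let xᵢ be a gene's log2, RMA-normalized expression across the samples of a
compendium, and r̂ᵢⱼ an association estimate (Pearson, Spearman, mutual
information) for a pair of genes. For genes that act as on/off switches,
r̂ᵢⱼ only reflects co-regulation when the compendium contains samples from
*both* expression states of both genes: the between-state shift is signal,
the within-state spread is noise. A compendium that catches a gene almost
always in one state yields an association estimate dominated by noise —
a sampling-bias problem that grows, not shrinks, as more same-state
samples are added. corrflag quantifies state occupancy per gene, flags
pairs whose estimates are suspect, and measures between-compendium
disagreement.

## Association metrics (`assoc`)

Pearson and Spearman are delegated to scipy (`pearsonr`, `spearmanr`;
Spearman is Pearson on midranks, which the test suite verifies against an
explicit midrank construction). Mutual information uses the plug-in
(maximum-likelihood) estimator on an equal-width binned joint histogram:
each vector is discretized into `n_bins` (default 10) equal-width bins
over its own observed range, and MI is computed in bits (log base 2,
configurable). This estimator is biased upward at small n (the tests bound
the bias at ≤ 0.05 bits for n = 10⁴ independent normals); no bias
correction is applied because the diagnostics compare MI values computed
the same way, not absolute magnitudes.

Correlation on a constant vector is undefined; per-pair scans report NaN
with reason `constant_gene` rather than a silent 0, so degenerate genes
remain visible. Pairs are unordered and canonicalized lexicographically;
self-pairs are rejected. Per-gene dispersion is the sample standard
deviation (n − 1 denominator) of the gene's row.

## Two-state calling (`mixture`)

Each gene's expression distribution is modeled as a mixture of m
univariate, unequal-variance Gaussians. For each candidate m in 1..9
(skipping m with n < 5m), EM is run and the fit scored with

    BIC_m = 2·logL − (3m − 1)·log n        (higher is better)

with 3m − 1 free parameters (m means, m variances, m − 1 weights). Model
selection is deliberately biased toward the biologically motivated
two-state abstraction: **m = 2 is kept unless some other candidate beats
it by more than the BIC margin (default 10, "strong evidence"); otherwise
the argmax is taken, ties toward the smallest m.** If the m = 2 fit itself
failed, selection falls through to the plain argmax.

For a selected two-state gene, the "on" component is the one with the
larger mean; samples are hard-assigned by MAP posterior (state occupancy
is a count of samples, so soft posterior mass is not used); p_on is the
on fraction, and `min_state_pct = min(p_on, 1 − p_on)` is the
minority-state share tested by the 10% rule. A fixed-threshold classifier
(`classify_by_threshold`, on ⇔ value strictly above a user threshold) and
a joint both-on co-occupancy helper support threshold-style accounting
without a mixture fit.

### EM numerics

* Initialization: component means at the m interior quantiles of the data;
  5 restarts, restarts ≥ 1 jitter the quantiles with seeded N(0, (0.25·sd)²)
  noise. All randomness flows from the caller's seed, so fits are
  deterministic.
* Convergence: absolute log-likelihood gain < 1e-6, cap 200 iterations.
  These are looser than machine precision on purpose: the downstream
  decision compares BIC values at a margin of 10 units, which is
  insensitive to log-likelihood tail convergence below ~0.1, and the looser
  setting halves the cost of a full 1..9 sweep. Agreement of the resulting
  BICs with R's mclust (`modelNames="V"`) to < 0.01 on two-component data
  is asserted in the test suite.
* Degeneracy: component variances are floored at 1e-6 of the data
  variance; a restart that pins a variance at the floor (collapse onto
  few points) is discarded, and a candidate m whose restarts all collapse
  is recorded as failed and excluded from selection. A gene for which
  every candidate fails (e.g. a constant row) is reported as having no
  state fit, never dropped.
* m = 1 is closed-form (sample mean, MLE variance); no EM.

## Flagging rules (`flagging`)

Per pair, with policy defaults:

* `low_sd`: min(SD_a, SD_b) < 0.5 log2 units. Applies to every pair,
  whether or not the two-state model fits — low overall spread means the
  compendium never substantially perturbed the gene.
* `state_underrepresented`: both genes validly two-state and
  min over the pair of `min_state_pct` < 0.10. By default the criterion is
  marginal per gene; `joint_state=True` instead applies the 10% rule to
  min(fraction both-on, fraction both-off) from the MAP assignments, a
  stricter criterion that catches pairs that are individually balanced but
  never switch together.
* `constant_gene`: zero SD or no state fit; always flagged.

Boundary conventions throughout: "below" thresholds are strict `<`;
"at least 10%" is `≥`. Both flag rules are monotone in their thresholds
(raising a threshold can only flag more pairs), which the suite checks as
a property.

The 10% rule was calibrated on compendia of roughly 50–300 samples;
outside that range it is extrapolation, and the SD rule's 0.5 value is
specific to RMA-like log2 normalization.

## Between-compendium bootstrap (`bootstrap`)

For a pair (i, j) and compendia k, l: draw resampling plans (uniform with
replacement) of size n_k and n_l; on replicate z compute r_{k,z} and
r_{l,z} on the z-th resamples and form d_z = r_{k,z} − r_{l,z}; the CI is
the (2.5, 97.5) percentile pair of the valid d_z (numpy's inclusive
linear-interpolation percentile). A CI excluding zero at the 95% level is
evidence the two compendia estimate different associations; under a shared
true parameter the exclusion rate is ≈ 5%, which is the package's
calibration target (`scripts/acceptance.py` measures 5–7% at
n = 100, ρ = 0.5, 1000 pairs × 1000 replicates).

Design choices:

* **One plan per compendium, shared across all pairs of a call.** Each
  pair's marginal bootstrap distribution is unchanged, all-pairs runs cost
  O(reps·(n + pairs)) instead of O(reps·n·pairs), and a single seed
  reproduces an entire comparison table byte-for-byte.
* Replicates where either resampled vector is constant leave the metric
  undefined; they are **dropped and counted** (redrawing would distort the
  resampling distribution). A pair with fewer than 50% valid replicates is
  reported as degenerate via an exception rather than a misleading CI.
* Percentile method only — no BCa or basic-interval variants.

The naive-vs-uninformative comparison asks whether the same pair's value
in compendium l predicts its value in compendium k better than a random
*different* pair's value in l does. Each of `n_draws` evaluations samples
an evaluated pair and a distinct random pair uniformly from the supplied
list; the uninformative approach wins iff |r_k(i,j) − r_l(y,z)| <
|r_k(i,j) − r_l(i,j)|, ties counting for the naive approach. Win fractions
approaching 0.5 mean cross-compendium values carry essentially no
information.

## Calibration and partial compendia (`evaluate`)

Sensitivity/specificity of a cutoff are computed within a gold-positive
pair set (typically likely-operon pairs, which should correlate):
pairs with correlation strictly below the meaningful-correlation threshold
(default 0.6) form the should-flag class; sensitivity is the fraction of
them flagged (statistic strictly below the cutoff), specificity the
fraction of high-correlation pairs left unflagged. `calibration_sweep`
tabulates both across cutoffs with the underlying confusion counts
(recomputable from the table, asserted in tests) and reports the cutoff
maximizing sensitivity + specificity, ties toward the smaller cutoff.
`CalibrationTable.from_counts` builds the same table from externally known
confusion counts. An empty class yields NaN rates, never a division error.

`binned_mean_correlation` cross-tabulates mean pair correlation by label
and by pair-level minimum state percent in bins
[0, .05), [.05, .1), [.1, .2), [.2, .3), [.3, .4), [.4, .5]; pairs without
a valid two-state call are excluded.

`partition_compendium` shuffles series (seeded), accumulates them greedily
until each partition holds ≥ `min_size` (default 50) samples, merges a
trailing remainder into the last closed partition (leftover handling is
this package's choice), and labels partitions A, B, C… by decreasing size.
Series are never split; the result is a set partition of the samples.

## Synthetic compendia (`synthetic`)

The generator realizes exactly the abstraction the diagnostics assume:
binary regulon switches with series-specific on-probability p, gene value
μ_off + state·Δ + N(0, σ²). Defaults: μ_off = 6, Δ = 4, σ = 0.4 — placing
values on the 2–15 log2 scale of RMA microarray data with an on/off
separation (10σ) typical of strongly regulated operons; 12 regulons of 3
genes plus 12 independent genes across 10 series of 50 samples (a
500-sample compendium, inside the 150–900 range of real bacterial
compendia); global p_on = 0.4. Pathway coupling links the two regulons of
a group so that their states correlate at exactly the coupling value
(default 0.3), giving the expected ordering operon > pathway > independent
pair correlation without asserting particular magnitudes.

An operon pair's expected Pearson correlation has the closed form

    ρ = s / (s + σ²),   s = p(1 − p)·Δ²

(≈ 0.96 at the defaults), verified within ±0.03 at n = 2000 in the tests.
`make_bias_scenario` sets p = 0 in a leading fraction of series, so
partial compendia assembled from them contain only within-state noise —
the generator's bias knob.

What the generator does **not** emulate: probe-level microarray noise,
RNA-seq count distributions, batch effects, continuous (dose-response)
regulation, regulon overlap, or varying per-gene noise. Passing tests
therefore demonstrate that the pipeline behaves correctly *when the
two-state abstraction holds*; on real data genes with continuous dynamics
are covered only by the SD rule, not the state rule.

## Problem sizes used in the self-checks

The test suite's end-to-end checks use: 1000 simulated pairs × 1000
bootstrap replicates at n = 100 for the null calibration; 50 bimodal
(Δ = 4σ, n = 500) plus 50 unimodal genes for mixture recovery; and six
12-gene, 400-sample compendia spanning on-probabilities 0.03–0.45 for the
binned-correlation trend — sizes chosen so each check estimates its
quantity well inside its tolerance.

## Known limitations

* The BIC-margin rule inherits EM's local-optimum risk; five quantile-
  anchored restarts make misconvergence rare for well-separated states
  but offer no guarantee for overlapping components.
* The plug-in MI estimator's upward bias means MI-based comparisons
  should use matched sample sizes (the bootstrap's paired resampling
  already ensures this).
* Flag decisions are binary; no confidence measure accompanies a flag.
* Bias is *flagged*, not corrected.
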