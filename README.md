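# corrflag

**Sampling-bias diagnostics for pairwise gene association in expression
compendia.**

Pairwise gene association — Pearson or Spearman correlation, mutual
information — computed across a large repository of expression samples is
the workhorse behind operon validation, regulatory-network inference and
co-expression clustering in bacteria. But a correlation estimate is only
meaningful if the compendium actually *perturbed* the genes in question.
Many genes behave as two-state switches (an "off" baseline and an "on"
induced level); if nearly all samples in a compendium catch a gene in one
state, the remaining variation is measurement noise and the estimated
association r̂ᵢⱼ is badly biased — and adding more same-state samples makes
it *worse*, not better.

corrflag is for anyone mining RMA-normalized (log2-scale) expression
compendia who wants to know which of their gene-gene correlations can be
trusted. It provides:

* **Association metrics** (`corrflag.assoc`): Pearson, Spearman (midranks),
  and plug-in mutual information on equal-width bins (base 2), for all
  C(G, 2) pairs or a supplied pair list.
* **On/off state calling** (`corrflag.mixture`): per-gene unequal-variance
  Gaussian mixtures fitted by EM for m = 1..9 components, scored with
  BIC = 2·logL − (3m − 1)·log n, keeping the two-state model unless another
  m beats it by more than 10 BIC units. For two-state genes it reports
  p_on and the minority-state share min(p_on, 1 − p_on).
* **Bias flagging** (`corrflag.flagging`): a pair is flagged when
  min(SD_a, SD_b) < 0.5 log2 units (always), or when both genes are
  two-state and either minority state occupies < 10% of samples.
* **Between-compendium comparison** (`corrflag.bootstrap`): a paired
  percentile bootstrap on the difference d_z = r_{k,z} − r_{l,z} over
  z = 1..1000 resamples; the 2.5/97.5 percentiles of d give a 95% CI.
  When compendia k and l estimate the same association, ~5% of CIs exclude
  zero; large exclusion rates diagnose sampling bias.
* **Cutoff calibration** (`corrflag.evaluate`): sensitivity/specificity
  sweeps of SD and state cutoffs against gold-standard operon pairs, plus
  partial-compendium construction from whole deposition series.
* **Synthetic compendia** (`corrflag.synthetic`): a generator with known
  regulon/operon/pathway structure and a controllable state-starvation
  knob, so the whole pipeline is testable without downloads.

## Worked example

Simulate a compendium of 8 two-state genes across 8 series of 50 samples,
where half the series never induce any gene (state-starved), and compare
the biased and unbiased halves:

```python
import numpy as np
from corrflag import (SyntheticSpec, make_bias_scenario, subset_samples,
                      flag_compendium, diff_ci_pairs, exclusion_rate,
                      FlagPolicy, pearson, gene_sd, fit_gene_states)

spec = SyntheticSpec(n_regulons=4, genes_per_regulon=2, n_independent_genes=2,
                     n_pathway_groups=1, n_series=8, samples_per_series=50, seed=7)
comp, truth = make_bias_scenario(spec, starved_series_fraction=0.5)

starved_series = {f"GSE{i:02d}" for i in range(4)}
starved = [s for s in comp.sample_ids if comp.series_of_sample[s] in starved_series]
balanced = [s for s in comp.sample_ids if s not in set(starved)]
part_s = subset_samples(comp, starved, name="starved")
part_b = subset_samples(comp, balanced, name="balanced")

a, b = truth.operon_pairs[0]
print(f"r balanced = {pearson(part_b.row(a), part_b.row(b)):.2f}, "
      f"r starved = {pearson(part_s.row(a), part_s.row(b)):.2f}")
print(f"SD of {a}: balanced {gene_sd(part_b, a):.2f}, starved {gene_sd(part_s, a):.2f}")

reports = flag_compendium(part_s, pairs=truth.operon_pairs, seed=1)
print(f"flagged in starved partial: {sum(r.flagged for r in reports)}/{len(reports)}")

cmp = diff_ci_pairs(part_s, part_b, truth.operon_pairs, "pearson",
                    FlagPolicy(), seed=2)
print(f"bootstrap CIs excluding zero: {exclusion_rate(cmp):.2f}")
```

Output:

```
r balanced = 0.96, r starved = -0.14
SD of op00g0: balanced 1.99, starved 0.40
flagged in starved partial: 4/4
bootstrap CIs excluding zero: 1.00
```

Read: the same true operon pair looks strongly co-expressed (r = 0.96) in
the compendium that samples both states and uncorrelated (r = −0.14) in
the state-starved one — and the bootstrap comparison says the disagreement
is far beyond chance (100% of CIs exclude zero, vs the ~5% null rate).
The flagging rules catch it: in the starved partial both genes' SDs drop
to ~0.4 < 0.5, so all four operon pairs are flagged as potentially biased,
while none are flagged in the balanced partial.

The same pipeline is available from the shell:

```sh
corrflag simulate --config spec.yaml --seed 7 -o sim/
corrflag states --matrix sim/matrix.tsv --seed 1 -o states.tsv
corrflag flag --matrix sim/matrix.tsv --pairs sim/pair_labels.tsv --seed 1 -o flags.tsv
corrflag compare --matrix-k A.tsv --matrix-l B.tsv --reps 1000 --seed 2 --summary -o cmp.tsv
```

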