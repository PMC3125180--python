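# apmsnet

Confidence-scored protein–protein interaction networks from replicated
affinity-purification / mass-spectrometry (AP-MS) pull-downs with a
no-bait control.

## The problem

A bait protein is affinity-tagged, purified on a column, and everything
that co-elutes is identified by LC-MS/MS. The catch: columns bind plenty
of proteins nonspecifically, elution peaks drift between runs, and for
small studies (a dozen baits, three biological replicates each) the
usual genome-scale quality heuristics do not apply. `apmsnet` implements
a scoring scheme built for exactly this setting: emPAI abundance tables
per (bait × replicate × elution fraction), an untagged-strain control
purification, and a handful of statistics that turn those into a
weighted, significance-annotated bait → prey network.

## The statistic

For protein *i* in the pull-down of bait *b*, with emPAI value
*x*(i, b, r, f) in replicate *r* and fraction *f*:

1. **Max over fractions** per replicate, m(i,b,r) = max_f x(i,b,r,f)
   (peaks drift between replicates, so fraction numbers don't align).
2. **Control subtraction**: a(i,b,r) = max(m(i,b,r) − c(i), 0), where
   c(i) is the median across control replicates of the protein's
   fraction maxima in the no-bait purification (absent replicates
   count as 0).
3. **Median-max**: MM(i,b) = median_r a(i,b,r).
4. **Pseudo-confidence score**: s(i,b) = MM(i,b) / MM(b,b), normalizing
   by the bait's own median-max (or by the top prey when the bait
   protein itself was not detected).

The **high-confidence** edge set keeps (b, i) only when *i* was seen in
all three replicates of *b* with a non-zero raw median-max at least the
control's median-max for that protein; equality with a non-zero control
value is kept but flagged "dashed".

Each pair also gets a **bootstrap p-value**: the prey's three replicate
maxima are resampled (3 draws with replacement, 10,000 rounds) against
draws from a null pool of all other-bait and control replicates whose
full profiles correlate at Pearson R < 0.3 with every replicate of the
focal bait; p = 1 − (wins)/10,000, with ties favouring the null.

Validation statistics: the reciprocal confirmation rate between baits,
functional-role agreement of interacting pairs against a 100,000-fold
label-permutation null, bait–bait pull-down profile correlations,
reciprocal-best-hit ortholog coverage against a reference interaction
set, and a Welch t-test comparing co-expression (centered Pearson R of
expression profiles) of interacting vs non-interacting pairs.

A synthetic-data generator plants protein complexes, a sticky-protein
background shared with the control, replicate-jittered elution peaks,
lognormal noise with dropout, and co-expressed complex members — so the
whole pipeline is testable end to end with known ground truth.

## Worked example

```python
import numpy as np
from apmsnet import ScoringConfig, build_network, degree_summary, \
    generate, reciprocal_rate, score_all, study_design, evaluate_recovery

cfg = study_design()          # 12 baits, 90 prey, 134 planted interactions
cfg.noise_sigma = 0.0         # noiseless limit
cfg.dropout = 0.0
cfg.sticky_set = ()
ds = generate(cfg, np.random.default_rng(11))

_, _, table = score_all(ds.matrix, ScoringConfig(require_control=False))
net = build_network(table, ds.roles)
print(degree_summary(net))
print("reciprocal:", reciprocal_rate(net))
print("recovery:", evaluate_recovery(net, ds.truth))
```

prints

```
{'n_baits': 12, 'n_prey': 90, 'n_edges': 134, 'mean_prey_per_bait': 11.2, 'mean_baits_per_prey': 1.5}
reciprocal: (3, 6, 0.5)
recovery: (1.0, 1.0, 1.0, 0.0)
```

i.e. on clean data the filter returns exactly the planted network — 134
directed bait → prey edges over 12 baits and 90 prey (11.2 prey per
bait, 1.5 baits per prey), three of six possible reciprocal bait pairs
confirmed, and perfect precision/recall with zero sticky contamination.
With the default noise model (lognormal σ = 0.5, 5% dropout) the same
pipeline recovers most planted edges and all validation statistics
remain directionally correct; run it via

```sh
apmsnet run --config run.yaml --out-dir run --seed 7
```

with a YAML config such as

```yaml
simulate: {study_scale: true}
bootstrap: {n_boot: 10000, r_threshold: 0.3}
network: {n_perm: 100000}
```

or stage by stage (`apmsnet simulate|score|bootstrap|network|coexpr|orthology`).
Every run writes TSV stage outputs, the network in Pajek/SIF/GraphML/TSV
(dashed edges carry the sentinel Pajek width 0.001), and a
`manifest.json` tying each statistic to its stage file.

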