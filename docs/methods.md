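# Methods

## Scope and model

`apmsnet` scores bait–prey interactions from replicated AP-MS pull-down
experiments quantified by emPAI (exponentially modified Protein
Abundance Index), emPAI = 10^(N_observed/N_observable) − 1, where the
counts are distinct observed vs observable tryptic peptides. The
pipeline assumes the study design it was built around: each tagged bait
purified in three biological replicates, each eluted over about six
fractions, plus a no-bait control purification from the untagged strain
processed identically.

The scoring statistic is deliberately simple and rank-free:

* max over elution fractions per replicate — the same fraction number
  samples different parts of the elution profile in different runs, so
  per-fraction alignment would be meaningless;
* subtraction of the control baseline (median across control replicates
  of the protein's fraction maxima, unobserved replicates counted as 0),
  floored at 0 since negative abundances are not interpretable;
* median across the biological replicates ("median-max");
* normalization by the bait protein's own median-max, giving a
  pseudo-confidence score in which the bait scores exactly 1 and prey
  scores are relative co-purification strengths. When the bait protein
  itself is undetected (small, trypsin-refractory proteins can have very
  few observable peptides), the top prey is the normalizer.

The high-confidence filter and the comparison against the control use
the *unadjusted* median-max on both sides: comparing post-subtraction
values to the baseline would count the control twice. Equality with a
non-zero control value is retained but flagged "dashed" (exported with
the sentinel Pajek edge width 0.001); for column-sticky baits — bait
proteins that themselves appear in the control above a configurable
prominence threshold (default: any non-zero control median-max) — the
equality case additionally requires the prey to have been observed in
every control replicate.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `k_reps` | 3 | biological replicates required per bait |
| `median_missing` | `zero` | replicate medians count absences as 0 (`drop` medians only observed values) |
| `n_boot` | 10,000 | bootstrap rounds per (bait, prey) |
| `r_threshold` | 0.3 | Pearson cutoff for null-pool admission |
| `sample_size` | 3 | values drawn per side per bootstrap round |
| `n_perm` | 100,000 | role-label permutations |
| `evalue_cutoff` | 1e-4 | reciprocal-best-hit threshold (both directions) |
| emPAI `missed_cleavages` | 1 | fully tryptic peptides with ≤1 missed site |
| emPAI length bounds | 6–30 residues | observable-peptide filter |

The observable-peptide criterion used by commercial search engines is
not recoverable from their output, so it is explicit configuration
here; the defaults (length 6–30, one missed cleavage, no mass filter)
are conventional for tryptic LC-MS/MS. Monoisotopic masses come from the
standard residue table; `X` residues carry zero mass and disqualify a
peptide from mass filtering.

## Bootstrap significance

For each (bait, prey) pair the three per-replicate fraction maxima are
compared against the same prey's values across a null pool: every
replicate of other baits and of the control whose dense protein profile
(max-over-fractions, zeros for unobserved) correlates at R <
`r_threshold` with *every* replicate profile of the focal bait. Each
round draws 3 values with replacement from each side and scores a win
when the bait median strictly exceeds the pool median; p = 1 − wins/B.
Ties favour the null, which makes the test conservative whenever the
prey is shared with the control; the smallest attainable non-zero p is
1/B. Randomness comes from a per-pair `numpy` generator seeded by
SeedSequence over (seed, crc32(bait), crc32(prey)), so results are
independent of row order and byte-reproducible.

Profile-level (rather than prey-level) correlation screening was chosen
because the replicate profile is the only per-replicate object the
data model defines; it is also what the pool members are drawn from.

## Permutation test for role agreement

Functional agreement is the fraction of network edges whose endpoints
share a role label; unannotated endpoints count in the denominator and
never agree (annotation catalogs are incomplete; `drop_unannotated`
flips this). The null permutes the label assignment (including "no
label") across the proteins of the network, preserving the multiset,
and p is the fraction of permutations whose agreement is **at least**
the observed value. Counting ties toward the null is the conservative
convention: a network whose agreement cannot be exceeded (every node
one role) gets p = 1 rather than a spuriously significant 0.

## Co-expression comparison

Pair co-expression is the centered Pearson correlation of two genes'
expression profiles over their shared non-missing conditions (pairwise
deletion, minimum overlap 3). Interacting pairs are the network edges;
the non-interacting contrast set is every observed (bait, prey)
combination that did not pass the high-confidence filter — proteins
demonstrably present in the experiment but not called interactors —
rather than all genome pairs. The two distributions are compared with a
Welch two-sample t-test (unequal variances, Welch–Satterthwaite df,
two-tailed) and summarized as a 20-bin frequency polygon over [−1, 1].
Percentile-rank abundance uses rank/n × 100 with average ranks for ties
and the maximum mapped to 100.

## Synthetic data: what it emulates, what it does not

The generator plants protein complexes (a designated bait plus
co-members), giving each complex a Gaussian elution peak (SD 1 fraction)
whose center jitters ±1 fraction between replicates — the phenomenon
that motivates the max-over-fractions step. Bait abundance is lognormal
around emPAI 4; prey abundances are a lognormal fraction (mean 0.35) of
their bait's; every value carries multiplicative lognormal noise
(σ = 0.5) and each (protein, replicate) drops out independently with
probability 0.05; values below 0.01 are unobserved. Sticky background
proteins get a fixed per-protein column affinity realized in *every*
pull-down and in the control; in bait pull-downs they appear at 0.7× the
control level, modelling competition with the tagged complex for column
capacity — this is why control subtraction removes them exactly in the
noiseless limit. Roles are drawn so complex co-members share a label
with probability 0.75 (20% of background proteins unannotated), and
expression comes from a latent-factor model: all genes load √0.1 on a
global factor (baseline pair R ≈ 0.1) and complex members load ≈0.45
(split across complexes for shared members) on a per-complex factor,
which reproduces the interacting ≈ 0.2 vs non-interacting ≈ 0.1
co-expression contrast of the study design.

The default `study_design()` plants the published network's shape: 12
baits, 90 distinct prey endpoints, 134 directed bait → prey edges, three
reciprocal bait pairs among six half-observed ones, 44 prey shared by
two baits, and 12 sticky background proteins.

What the generator does **not** emulate: peptide-level detectability
and protein inference ambiguity (emPAI values are drawn directly by
default; a peptide-level route through the emPAI module exists for
end-to-end coverage of that code path via `quantify`), saturation of the
emPAI scale at 9, correlated dropout across complex members, batch
effects between replicates, and the long-tailed correlation spread of
real microarray compendia (the synthetic pair-R spread is narrower than
real data's ±0.3). Passing tests therefore demonstrate the statistics'
correctness and calibration under the declared noise model, not
performance guarantees on real LC-MS data.

## Numerical choices and degenerate inputs

* Replicate medians treat absent observations as 0 by default
  (`median_missing="zero"`), consistent with using all control
  observations regardless of replicate count; `"drop"` is available.
* Replicate-agreement denominator is Jaccard (|∩|/|∪|); `min` is
  selectable.
* Pearson correlations against a constant vector are reported as NaN,
  and NaN correlations count as "dissimilar" for null-pool admission.
* An empty null pool raises with advice to raise `r_threshold`; a bait
  whose pull-down has no non-zero median-max yields an empty score
  slice with a warning.
* Self-edges are excluded from the network edge set and from all edge
  counts; bait nodes always remain, carrying their own normalized score
  as `bait_prominence`.
* Reciprocal-best-hit ties are broken by minimum e-value, then maximum
  bitscore, then lexicographic subject id; self–self reference
  interactions are excluded from ortholog coverage on both sides.
* All writers order output deterministically; re-running any stage with
  the same inputs, config and seed is byte-identical.

## Problem sizes used in the shipped checks

The acceptance run and the test suite use the study-scale dataset
(about 105 observed proteins, 12 × 3 pull-down runs plus 3 control runs,
~290 scored pairs) with B = 10,000 bootstrap rounds and 100,000
permutations — the full-size analysis, which completes in seconds.
Property tests use smaller universes (20–30 proteins, 2 baits) and
reduced replications where the property concerns averages over seeds.

## Known limitations

* The high-confidence filter requires exactly `k_reps` replicates per
  bait and errors otherwise; partial designs need explicit subsetting.
* The bootstrap tests each pair marginally; no multiplicity correction
  is applied (the p < 0.001 convention is the intended use).
* RBH orthology is sequence-only; paralog families and many-to-many
  orthology are out of scope.
* emPAI is computed from distinct peptide sequences; spectral counts,
  modification states and charge states are deliberately collapsed.
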