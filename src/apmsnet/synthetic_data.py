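"""Synthetic pull-down data with planted ground truth.

Emulates the study design end to end: triplicate affinity pull-downs of
a dozen baits eluted over six fractions, planted protein complexes
(bait + co-members), a sticky-protein background shared with a no-bait
control, multiplicative lognormal abundance noise with dropout, role
labels that complex co-members tend to share, and expression profiles
from a latent-factor model in which co-complex genes are more correlated
than background pairs.

Key generator behaviours and why:

* Each complex elutes as a discretized Gaussian peak whose center
  jitters by one fraction between replicates — the reason the scoring
  statistic takes the max over fractions rather than matching fraction
  numbers across replicates.
* Sticky proteins get a fixed per-protein column affinity, realized in
  every pull-down AND in the control; in bait pull-downs they appear at
  a fraction (``sticky_pulldown_factor``) of their control abundance,
  reflecting competition with the tagged complex for column capacity.
  Control subtraction therefore removes them cleanly in the noiseless
  limit.
* Expression: every gene loads on a shared global factor (baseline
  co-expression of a small genome) and co-complex genes additionally
  load on a complex factor, so interacting pairs are more correlated
  than non-interacting ones.

The default study-scale design (:func:`study_design`) plants 12 baits,
90 distinct prey endpoints and 134 directed bait->prey interactions with
3 reciprocal bait pairs among 6 half-observed ones, mirroring the scale
of the pull-down study this pipeline models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (CONTROL_ID, ExpressionMatrix, PulldownMatrix,
                         RoleAnnotation)

ROLE_VOCABULARY = [
    "Energy metabolism",
    "Protein synthesis",
    "Protein fate",
    "Central and intermediary metabolism",
    "Transcription",
    "DNA metabolism",
    "Cellular processes",
    "Transport and binding proteins",
]


@dataclass
class Complex:
    """A planted complex: a designated bait and its co-members (the prey)."""

    bait: str
    members: tuple[str, ...]


@dataclass
class SimConfig:
    """Generator settings; defaults follow the study design it emulates.

    Triplicate pull-downs over six elution fractions; bait proteins are
    the most abundant species in their own pull-downs; prey abundances
    are a lognormal fraction of the bait's; multiplicative lognormal
    noise (sigma 0.5) and 5% per-(protein, replicate) dropout model
    run-to-run LC-MS variability.
    """

    n_proteins: int = 200
    n_replicates: int = 3
    n_fractions: int = 6
    complexes: list[Complex] = field(default_factory=list)
    sticky_set: tuple[str, ...] = ()
    bait_empai_mean: float = 4.0
    prey_ratio_mean: float = 0.35        # prey emPAI as a fraction of the bait's
    prey_ratio_sigma: float = 0.4
    sticky_empai_mean: float = 1.5
    sticky_pulldown_factor: float = 0.7  # sticky abundance in pull-downs vs control
    elution_width: float = 1.0           # fractions; Gaussian peak SD
    peak_jitter: int = 1                 # max replicate-to-replicate center shift
    noise_sigma: float = 0.5             # lognormal sigma on every abundance
    dropout: float = 0.05                # P(protein missing from a replicate)
    detection_floor: float = 0.01        # emPAI below this is not observed
    n_conditions: int = 106
    global_loading: float = 0.316        # sqrt(0.1): baseline gene-gene R ~ 0.1
    complex_loading: float = 0.45        # co-complex pair R ~ 0.2 after the
                                         # multi-complex loading dilution
    role_share_prob: float = 0.75        # P(co-member shares the complex role)
    unannotated_prob: float = 0.2
    rng_seed: int = 0

    def protein_ids(self) -> list[str]:
        named = [c.bait for c in self.complexes]
        named += [m for c in self.complexes for m in c.members]
        named += list(self.sticky_set)
        ordered = list(dict.fromkeys(named))
        i = 0
        while len(ordered) < self.n_proteins:
            pid = f"P{i:04d}"
            if pid not in ordered:
                ordered.append(pid)
            i += 1
        if len(ordered) > self.n_proteins:
            raise ValueError(
                f"complexes and sticky set name {len(ordered)} proteins but the "
                f"universe holds only {self.n_proteins}"
            )
        return ordered

    def baits(self) -> list[str]:
        return [c.bait for c in self.complexes]


@dataclass
class SyntheticTruth:
    """Planted directed bait -> prey edges plus the sticky background."""

    edges: set[tuple[str, str]]
    sticky_set: set[str]
    config: SimConfig


@dataclass
class SyntheticDataset:
    matrix: PulldownMatrix
    truth: SyntheticTruth
    roles: RoleAnnotation
    expression: ExpressionMatrix


def study_design(n_background: int = 60) -> SimConfig:
    """The default study-scale configuration.

    Plants 12 baits (B01..B12) with 134 directed interactions over 90
    distinct prey endpoints: three reciprocal bait pairs (both
    directions), three one-way bait pairs, and 81 non-bait prey of which
    44 are shared by a second bait.  Twelve sticky proteins populate the
    no-bait control.
    """
    baits = [f"B{i:02d}" for i in range(1, 13)]
    edges: list[tuple[str, str]] = []
    # 3 reciprocal bait pairs (6 edges) and 3 one-way bait pairs (3 edges)
    for a, b in [(0, 1), (2, 3), (4, 5)]:
        edges += [(baits[a], baits[b]), (baits[b], baits[a])]
    for a, b in [(6, 7), (8, 9), (10, 11)]:
        edges.append((baits[a], baits[b]))
    # 81 non-bait prey; each has a primary bait, the first 44 also a second
    prey = [f"Y{i:03d}" for i in range(1, 82)]
    for i, p in enumerate(prey):
        edges.append((baits[i % 12], p))
        if i < 44:
            edges.append((baits[(i + 1) % 12], p))
    members: dict[str, list[str]] = {b: [] for b in baits}
    for bait, p in edges:
        members[bait].append(p)
    complexes = [Complex(b, tuple(members[b])) for b in baits]
    sticky = tuple(f"S{i:02d}" for i in range(1, 13))
    n_named = len({b for b in baits} | set(prey) | set(sticky))
    return SimConfig(
        n_proteins=n_named + n_background,
        complexes=complexes,
        sticky_set=sticky,
    )


def _elution_weights(center: float, width: float, n_fractions: int) -> np.ndarray:
    f = np.arange(1, n_fractions + 1, dtype=float)
    w = np.exp(-((f - center) ** 2) / (2 * width ** 2))
    return w / w.max()  # peak fraction carries the full abundance


def generate(config: SimConfig, rng: np.random.Generator | int | None = None) -> SyntheticDataset:
    """Draw one synthetic dataset (pull-downs + control, truth, roles, expression)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.rng_seed if rng is None else rng)
    proteins = config.protein_ids()
    baits = config.baits()
    if len(set(baits)) != len(baits):
        raise ValueError("duplicate bait across complexes")

    def noisy(mean: float) -> float:
        if config.noise_sigma == 0:
            return mean
        return float(mean * rng.lognormal(0.0, config.noise_sigma))

    # fixed per-protein sticky column affinity, shared by control and pull-downs
    sticky_affinity = {
        s: (config.sticky_empai_mean if config.noise_sigma == 0
            else float(config.sticky_empai_mean * rng.lognormal(0.0, config.noise_sigma)))
        for s in config.sticky_set
    }
    complex_center = {
        c.bait: float(rng.uniform(2, config.n_fractions - 1)) for c in config.complexes
    }
    sticky_center = {s: float(rng.uniform(1, config.n_fractions)) for s in sticky_affinity}

    entries: dict[tuple[str, str, int, int], float] = {}

    def deposit(protein: str, run: str, rep: int, abundance: float, center: float) -> None:
        if abundance < config.detection_floor:
            return
        weights = _elution_weights(center, config.elution_width, config.n_fractions)
        for frac, w in enumerate(weights, start=1):
            value = abundance * w
            if value >= config.detection_floor:
                entries[(protein, run, rep, frac)] = value

    for c in config.complexes:
        base_center = complex_center[c.bait]
        for rep in range(1, config.n_replicates + 1):
            jitter = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1)) \
                if config.peak_jitter else 0
            center = min(max(base_center + jitter, 1), config.n_fractions)
            bait_abundance = noisy(config.bait_empai_mean)
            if not (config.dropout and rng.random() < config.dropout):
                deposit(c.bait, c.bait, rep, bait_abundance, center)
            for prey in c.members:
                if config.dropout and rng.random() < config.dropout:
                    continue
                ratio = config.prey_ratio_mean if config.noise_sigma == 0 else float(
                    config.prey_ratio_mean * rng.lognormal(0.0, config.prey_ratio_sigma))
                deposit(prey, c.bait, rep, bait_abundance * ratio, center)

    # sticky background in every pull-down (damped) and in the control (full)
    runs = [(b, config.sticky_pulldown_factor) for b in baits] + [(CONTROL_ID, 1.0)]
    for run, factor in runs:
        for rep in range(1, config.n_replicates + 1):
            for s, affinity in sticky_affinity.items():
                if config.dropout and rng.random() < config.dropout:
                    continue
                abundance = affinity * factor
                if config.noise_sigma:
                    abundance = noisy(abundance)
                deposit(s, run, rep, abundance, sticky_center[s])

    # ensure control replicates exist even with an empty sticky set: a control
    # run that detected nothing is still a run (represented by no entries)
    matrix = PulldownMatrix(entries)

    truth = SyntheticTruth(
        edges={(c.bait, m) for c in config.complexes for m in c.members if m != c.bait},
        sticky_set=set(config.sticky_set),
        config=config,
    )

    roles = _assign_roles(config, proteins, rng)
    expression = _expression(config, proteins, rng)
    return SyntheticDataset(matrix, truth, roles, expression)


def _assign_roles(config: SimConfig, proteins: list[str],
                  rng: np.random.Generator) -> RoleAnnotation:
    roles: dict[str, str] = {}
    complex_role = {
        c.bait: ROLE_VOCABULARY[i % len(ROLE_VOCABULARY)]
        for i, c in enumerate(config.complexes)
    }
    for c in config.complexes:
        roles[c.bait] = complex_role[c.bait]
        for m in c.members:
            if m in roles:
                continue
            if rng.random() < config.role_share_prob:
                roles[m] = complex_role[c.bait]
            else:
                roles[m] = str(rng.choice(ROLE_VOCABULARY))
    for p in proteins:
        if p in roles:
            continue
        if rng.random() < config.unannotated_prob:
            continue
        roles[p] = str(rng.choice(ROLE_VOCABULARY))
    return RoleAnnotation(roles)


def _expression(config: SimConfig, proteins: list[str],
                rng: np.random.Generator) -> ExpressionMatrix:
    """Latent-factor expression: a global factor all genes load on, plus one
    factor per complex shared by the bait and its co-members.  Genes in k
    complexes split their complex loading as lam/sqrt(k) to keep unit
    variance, so every interacting pair shares at least one factor."""
    n, c = len(proteins), config.n_conditions
    global_factor = rng.normal(size=c)
    complex_factors = {comp.bait: rng.normal(size=c) for comp in config.complexes}
    # per-complex co-regulation strength varies, widening the pair-R spread
    lam_scale = {
        comp.bait: float(rng.uniform(0.75, 1.25)) for comp in config.complexes
    }
    membership: dict[str, list[str]] = {}
    for comp in config.complexes:
        for p in (comp.bait, *comp.members):
            membership.setdefault(p, [])
            if comp.bait not in membership[p]:
                membership[p].append(comp.bait)
    g, lam = config.global_loading, config.complex_loading
    values = np.empty((n, c))
    for i, p in enumerate(proteins):
        signal = g * global_factor
        var = g ** 2
        for owner in membership.get(p, ()):
            loading = lam * lam_scale[owner] / np.sqrt(len(membership[p]))
            signal = signal + loading * complex_factors[owner]
            var += loading ** 2
        noise_sd = float(np.sqrt(max(1.0 - var, 0.0)))
        values[i] = signal + rng.normal(scale=noise_sd, size=c)
    df = pd.DataFrame(values, index=proteins,
                      columns=[f"cond{j:03d}" for j in range(1, c + 1)])
    return ExpressionMatrix(df)


def evaluate_recovery(predicted_edges, truth: SyntheticTruth
                      ) -> tuple[float, float, float, float]:
    """(precision, recall, F1, sticky contamination) of a predicted edge set.

    ``predicted_edges`` is an iterable of directed (bait, prey) pairs or
    an InteractionNetwork.  Contamination is the fraction of predicted
    edges whose prey is sticky background rather than a planted partner.
    Precision (and F1) are NaN for an empty prediction.
    """
    if hasattr(predicted_edges, "graph"):
        predicted = set(predicted_edges.graph.edges)
    else:
        predicted = set(predicted_edges)
    tp = len(predicted & truth.edges)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(truth.edges) if truth.edges else float("nan")
    if predicted and truth.edges and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = float("nan") if not predicted else 0.0
    contamination = (
        sum(1 for b, p in predicted
            if p in truth.sticky_set and (b, p) not in truth.edges) / len(predicted)
        if predicted else float("nan")
    )
    return precision, recall, f1, contamination
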