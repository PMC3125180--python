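"""Median-max scoring of bait pull-downs against a no-bait control.

The statistic works replicate by replicate: for each bait pull-down
replicate, take the maximum emPAI of each protein over the elution
fractions (elution peaks drift between replicates, so the same fraction
number can sample different parts of the profile); subtract the
control baseline (the median across no-bait control replicates of each
protein's per-replicate fraction maxima, unobserved replicates counted
as 0), flooring at 0; then take the median of the adjusted maxima across
the biological replicates — the *median-max* value.  Dividing every
prey's median-max by the bait protein's own median-max (or by the top
prey when the bait itself was not detected) gives the *pseudo-confidence
score*, the edge weight of the interaction network.

The high-confidence interaction set keeps a (bait, prey) pair only when
the prey was seen in all replicates of that pull-down and its raw
(pre-subtraction) median-max is non-zero and at least the control's
median-max for the same protein.  Equality with a non-zero control value
is retained but flagged ("dashed"), and column-sticky baits that
themselves show up in the control trigger a stricter rule for those
equality calls.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import CONTROL_ID, PulldownMatrix

#: Policies for the median across replicates when a protein is missing
#: from some replicates: count the missing slots as 0, or drop them.
MEDIAN_MISSING_POLICIES = ("zero", "drop")


@dataclass
class ScoringConfig:
    """Scoring knobs; defaults follow the triplicate study design."""

    k_reps: int = 3                     # required biological replicates per bait
    median_missing: str = "zero"        # how replicate medians treat absences
    adjustment_floor: float = 0.0       # adjusted maxima floored here
    sticky_bait_threshold: float = 0.0  # control median-max above which a bait
                                        # counts as column-sticky
    require_control: bool = True

    def __post_init__(self) -> None:
        if self.median_missing not in MEDIAN_MISSING_POLICIES:
            raise ValueError(f"median_missing must be one of {MEDIAN_MISSING_POLICIES}")


@dataclass
class MedianMaxRow:
    """Per (bait, protein) replicate maxima and their medians."""

    bait_id: str
    protein_id: str
    rep_max: tuple[float, ...]       # per-replicate fraction maxima, 0 = absent
    adj_rep_max: tuple[float, ...]   # after control subtraction and flooring
    median_max: float                # median of adj_rep_max (the score input)
    raw_median_max: float            # median of rep_max, pre-subtraction
    n_reps_present: int
    control_baseline: float


MedianMaxTable = dict[str, MedianMaxRow]  # protein -> row, for one bait


def max_over_fractions(matrix: PulldownMatrix, bait_id: str, replicate_id: int) -> dict[str, float]:
    """Per-protein maximum emPAI over elution fractions of one replicate.

    Proteins unobserved in every fraction are absent from the result.
    """
    if bait_id not in {k[1] for k in matrix.entries}:
        raise KeyError(f"unknown bait id {bait_id!r}")
    if replicate_id not in matrix.replicates(bait_id):
        raise KeyError(f"unknown replicate {replicate_id} for bait {bait_id!r}")
    out: dict[str, float] = {}
    for (protein, bait, rep, _frac), value in matrix.entries.items():
        if bait == bait_id and rep == replicate_id:
            if protein not in out or value > out[protein]:
                out[protein] = value
    return out


def _median(values: list[float], present: list[bool], policy: str) -> float:
    if policy == "zero":
        return statistics.median(values)
    observed = [v for v, p in zip(values, present) if p]
    return statistics.median(observed) if observed else 0.0


def control_baseline(matrix: PulldownMatrix, config: ScoringConfig | None = None) -> dict[str, float]:
    """Control baseline: median across no-bait replicates of fraction maxima.

    Every protein ever seen in the control gets a baseline regardless of
    how many control replicates it appeared in; replicates where it was
    absent contribute 0 under the default policy.  Proteins never seen in
    the control have baseline 0 (returned map omits them).
    """
    config = config or ScoringConfig()
    if not matrix.has_control():
        if config.require_control:
            raise ValueError(
                "no control replicates found under the reserved bait id; "
                "pass require_control=False to score without a control"
            )
        return {}
    reps = matrix.replicates(CONTROL_ID)
    per_rep = {rep: max_over_fractions(matrix, CONTROL_ID, rep) for rep in reps}
    proteins = {p for rep_map in per_rep.values() for p in rep_map}
    baseline: dict[str, float] = {}
    for protein in proteins:
        values = [per_rep[rep].get(protein, 0.0) for rep in reps]
        present = [protein in per_rep[rep] for rep in reps]
        baseline[protein] = _median(values, present, config.median_missing)
    return baseline


def control_presence_counts(matrix: PulldownMatrix) -> dict[str, int]:
    """Number of control replicates each protein was observed in."""
    if not matrix.has_control():
        return {}
    counts: dict[str, int] = {}
    for rep in matrix.replicates(CONTROL_ID):
        for protein in max_over_fractions(matrix, CONTROL_ID, rep):
            counts[protein] = counts.get(protein, 0) + 1
    return counts


def median_max(matrix: PulldownMatrix, bait_id: str,
               baseline: dict[str, float],
               config: ScoringConfig | None = None) -> MedianMaxTable:
    """Median-max table for one bait: adjusted and raw replicate medians."""
    config = config or ScoringConfig()
    reps = matrix.replicates(bait_id)
    per_rep = {rep: max_over_fractions(matrix, bait_id, rep) for rep in reps}
    proteins = {p for rep_map in per_rep.values() for p in rep_map}
    table: MedianMaxTable = {}
    for protein in sorted(proteins):
        values = [per_rep[rep].get(protein, 0.0) for rep in reps]
        present = [protein in per_rep[rep] for rep in reps]
        base = baseline.get(protein, 0.0)
        adjusted = [max(v - base, config.adjustment_floor) for v in values]
        table[protein] = MedianMaxRow(
            bait_id=bait_id,
            protein_id=protein,
            rep_max=tuple(values),
            adj_rep_max=tuple(adjusted),
            median_max=_median(adjusted, present, config.median_missing),
            raw_median_max=_median(values, present, config.median_missing),
            n_reps_present=sum(present),
            control_baseline=base,
        )
    return table


@dataclass
class ScoreRow:
    bait_id: str
    prey_id: str
    score: float
    normalizer_source: str  # "bait_median_max" or "max_prey"


def pseudo_confidence(mm_table: MedianMaxTable, bait_protein_id: str) -> dict[str, ScoreRow]:
    """Normalize one bait's adjusted median-max values into scores.

    The normalizer is the bait protein's own median-max when it was
    observed (so the bait's score is exactly 1), else the largest prey
    median-max in that pull-down.
    """
    if not mm_table:
        return {}
    bait_row = mm_table.get(bait_protein_id)
    if bait_row is not None and bait_row.median_max > 0:
        normalizer, source = bait_row.median_max, "bait_median_max"
    else:
        normalizer = max(row.median_max for row in mm_table.values())
        source = "max_prey"
    if normalizer <= 0:
        import logging
        logging.getLogger("apmsnet").warning(
            "all median-max values are 0 for bait %s; empty score slice",
            next(iter(mm_table.values())).bait_id)
        return {}
    bait_id = next(iter(mm_table.values())).bait_id
    return {
        protein: ScoreRow(bait_id, protein, row.median_max / normalizer, source)
        for protein, row in mm_table.items()
    }


#: Columns of the ConfidenceTable DataFrame.
CONFIDENCE_COLUMNS = [
    "bait", "prey", "score", "high_confidence", "dashed", "normalizer_source",
    "median_max", "raw_median_max", "control_baseline", "n_reps_present",
]


def score_all(matrix: PulldownMatrix, config: ScoringConfig | None = None,
              bait_proteins: dict[str, str] | None = None
              ) -> tuple[dict[str, MedianMaxTable], dict[str, float], pd.DataFrame]:
    """Median-max tables, control baseline and the full confidence table.

    ``bait_proteins`` maps bait run id -> bait protein id (identity by
    default).  The returned DataFrame has one row per observed
    (bait, prey) with scores and high-confidence/dashed flags.
    """
    config = config or ScoringConfig()
    baseline = control_baseline(matrix, config)
    mm_tables = {
        bait: median_max(matrix, bait, baseline, config)
        for bait in matrix.baits()
    }
    table = high_confidence_filter(mm_tables, baseline, matrix, config, bait_proteins)
    return mm_tables, baseline, table


def high_confidence_filter(mm_tables: dict[str, MedianMaxTable],
                           baseline: dict[str, float],
                           matrix: PulldownMatrix,
                           config: ScoringConfig | None = None,
                           bait_proteins: dict[str, str] | None = None) -> pd.DataFrame:
    """Score every observed (bait, prey) pair and flag the confident subset.

    A pair is high-confidence iff the prey appears in all ``k_reps``
    replicates of that bait, its raw median-max is > 0, and the raw
    median-max is >= the control's median-max for that protein.  Equality
    with a non-zero control baseline keeps the pair but flags it dashed.
    For column-sticky baits (bait protein itself prominent in the
    control), the equality case additionally requires the prey to have
    been seen in all control replicates.
    """
    config = config or ScoringConfig()
    bait_proteins = bait_proteins or {}
    ctrl_counts = control_presence_counts(matrix)
    n_ctrl_reps = len(matrix.replicates(CONTROL_ID)) if matrix.has_control() else 0

    rows = []
    for bait, mm_table in sorted(mm_tables.items()):
        reps = matrix.replicates(bait)
        if len(reps) != config.k_reps:
            raise ValueError(
                f"bait {bait!r} has {len(reps)} replicates, expected {config.k_reps}"
            )
        bait_protein = bait_proteins.get(bait, bait)
        scores = pseudo_confidence(mm_table, bait_protein)
        sticky_bait = baseline.get(bait_protein, 0.0) > config.sticky_bait_threshold
        for prey, row in sorted(mm_table.items()):
            base = baseline.get(prey, 0.0)
            keep = (
                row.n_reps_present == config.k_reps
                and row.raw_median_max > 0
                and row.raw_median_max >= base
            )
            dashed = keep and base > 0 and row.raw_median_max == base
            if dashed and sticky_bait and ctrl_counts.get(prey, 0) < n_ctrl_reps:
                keep = dashed = False
            score_row = scores.get(prey)
            rows.append({
                "bait": bait,
                "prey": prey,
                "score": score_row.score if score_row else 0.0,
                "high_confidence": keep,
                "dashed": dashed,
                "normalizer_source": score_row.normalizer_source if score_row else "",
                "median_max": row.median_max,
                "raw_median_max": row.raw_median_max,
                "control_baseline": base,
                "n_reps_present": row.n_reps_present,
            })
    return pd.DataFrame(rows, columns=CONFIDENCE_COLUMNS)


def replicate_agreement(matrix: PulldownMatrix,
                        config: ScoringConfig | None = None,
                        denominator: str = "jaccard") -> dict[str, dict[str, float]]:
    """Replicate agreement per pull-down, raw and after control subtraction.

    Agreement for a bait is the mean over replicate pairs of the overlap
    of their prey sets, with the Jaccard denominator |A∪B| by default or
    ``min(|A|, |B|)`` when ``denominator='min'``.  The adjusted variant
    keeps only proteins whose fraction maxima exceed the control baseline.
    """
    if denominator not in ("jaccard", "min"):
        raise ValueError("denominator must be 'jaccard' or 'min'")
    config = config or ScoringConfig()
    base = control_baseline(matrix, config) if matrix.has_control() else {}

    def pairwise(sets: list[set[str]]) -> float:
        pairs = [(a, b) for i, a in enumerate(sets) for b in sets[i + 1:]]
        vals = []
        for a, b in pairs:
            denom = len(a | b) if denominator == "jaccard" else min(len(a), len(b))
            vals.append(len(a & b) / denom if denom else 0.0)
        return sum(vals) / len(vals) if vals else float("nan")

    raw: dict[str, float] = {}
    adjusted: dict[str, float] = {}
    for bait in matrix.baits(include_control=True):
        reps = matrix.replicates(bait)
        if len(reps) < 2:
            continue
        rep_maps = [max_over_fractions(matrix, bait, rep) for rep in reps]
        raw[bait] = pairwise([set(m) for m in rep_maps])
        adjusted[bait] = pairwise([
            {p for p, v in m.items() if v - base.get(p, 0.0) > 0} for m in rep_maps
        ])
    return {"raw": raw, "adjusted": adjusted}
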