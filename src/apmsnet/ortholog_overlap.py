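"""Cross-species interaction conservation via reciprocal best hits.

Orthologs between two proteomes are called by reciprocal best BLAST-style
hits (each protein is the other's top match, both directions at e-value
<= 1e-4).  Given a reference interaction set in species B, the coverage
statistic is: of the reference pairs whose members both map to species-A
proteins participating in the study (and whose bait-side ortholog was
actually used as a bait), what fraction was also observed in species A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SimilarityHits
from .network_metrics import InteractionNetwork


@dataclass
class OrthologMap:
    """One-to-one partial map between two proteomes with per-pair e-values."""

    pairs: dict[str, str]  # species A id -> species B id
    evalues: dict[tuple[str, str], tuple[float, float]]  # (a, b) -> (e_ab, e_ba)

    def inverse(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs.items()}

    def __len__(self) -> int:
        return len(self.pairs)


def _best_hits(hits: SimilarityHits) -> dict[str, tuple[str, float]]:
    """Best subject per query: min e-value, ties by max bitscore then id."""
    df = hits.hits.copy()
    df["_bs"] = df["bitscore"].fillna(-np.inf)
    df = df.sort_values(["query", "evalue", "_bs", "subject"],
                        ascending=[True, True, False, True], kind="mergesort")
    best = df.drop_duplicates("query", keep="first")
    return {r.query: (r.subject, r.evalue) for r in best.itertuples()}


def reciprocal_best_hits(hits_ab: SimilarityHits, hits_ba: SimilarityHits,
                         evalue_cutoff: float = 1e-4) -> OrthologMap:
    """Ortholog map from two all-vs-all similarity tables.

    Pair (a, b) is kept iff b is a's best hit in A->B, a is b's best hit
    in B->A, and both e-values pass the cutoff.
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs: dict[str, str] = {}
    evalues: dict[tuple[str, str], tuple[float, float]] = {}
    for a, (b, e_ab) in sorted(best_ab.items()):
        back = best_ba.get(b)
        if back is None:
            continue
        a_back, e_ba = back
        if a_back == a and e_ab <= evalue_cutoff and e_ba <= evalue_cutoff:
            pairs[a] = b
            evalues[(a, b)] = (e_ab, e_ba)
    return OrthologMap(pairs, evalues)


def interaction_coverage(network_a: InteractionNetwork,
                         reference_edges_b: list[tuple[str, str]],
                         ortholog_map: OrthologMap,
                         bait_set_a: set[str] | None = None
                         ) -> tuple[int, int, float]:
    """(shared, expected, fraction) coverage of reference interactions.

    *expected*: reference (species B) pairs, self-pairs excluded, whose
    two members both map back to species-A proteins that appear in the
    network (as bait or prey) and where at least one mapped member is in
    the bait set.  *shared*: expected pairs present in the species-A
    network in either direction.
    """
    bait_set_a = bait_set_a if bait_set_a is not None else network_a.baits
    b_to_a = ortholog_map.inverse()
    participants = set(network_a.baits) | network_a.prey
    g = network_a.graph
    expected = shared = 0
    seen: set[frozenset[str]] = set()
    for b1, b2 in reference_edges_b:
        if b1 == b2:
            continue  # self-self interactions excluded
        key = frozenset((b1, b2))
        if key in seen:
            continue
        seen.add(key)
        a1, a2 = b_to_a.get(b1), b_to_a.get(b2)
        if a1 is None or a2 is None or a1 == a2:
            continue
        if a1 not in participants or a2 not in participants:
            continue
        if a1 not in bait_set_a and a2 not in bait_set_a:
            continue
        expected += 1
        if g.has_edge(a1, a2) or g.has_edge(a2, a1):
            shared += 1
    fraction = shared / expected if expected else float("nan")
    return shared, expected, fraction


def write_ortholog_map(omap: OrthologMap, stream) -> None:
    rows = [
        {"protein_a": a, "protein_b": b,
         "evalue_ab": omap.evalues[(a, b)][0], "evalue_ba": omap.evalues[(a, b)][1]}
        for a, b in sorted(omap.pairs.items())
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "evalue_ab", "evalue_ba"]
                 ).to_csv(stream, sep="\t", index=False)
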