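"""Interaction network assembly and validation statistics.

Builds a directed bait -> prey graph from the high-confidence rows of a
confidence table and computes the internal-consistency measures used to
validate such networks: the reciprocal confirmation rate between baits,
functional-role agreement of interacting pairs against a label
permutation null, bait-bait pull-down profile correlations, and degree
summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .confidence_scoring import MedianMaxTable
from .io_formats import RoleAnnotation


@dataclass
class InteractionNetwork:
    """Directed bait -> prey network over a known bait set.

    Node attributes: ``role``, ``is_bait``, ``bait_prominence`` (the
    normalized score of the bait protein in its own pull-down).  Edge
    attributes: ``score``, ``dashed``, ``reciprocal``, ``p_value``.
    Self-edges are excluded; bait nodes are always present.
    """

    graph: nx.DiGraph
    baits: set[str]

    def sorted_edges(self):
        return [(u, v, self.graph.edges[u, v]) for u, v in sorted(self.graph.edges)]

    @property
    def prey(self) -> set[str]:
        """Distinct prey endpoints (baits pulled down by others included)."""
        return {v for _, v in self.graph.edges}

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class AgreementResult:
    observed_agreement: float
    permuted_mean: float
    p_value: float
    n_perm: int


def build_network(confidence_table: pd.DataFrame,
                  roles: RoleAnnotation | None = None,
                  pvals: pd.DataFrame | None = None,
                  bait_proteins: dict[str, str] | None = None) -> InteractionNetwork:
    """Assemble the network from the high-confidence rows.

    Self-edges (a bait pulling down its own protein) are dropped from the
    edge set, but every bait is kept as a node; its own-score becomes the
    node's ``bait_prominence``.  ``pvals`` (bait, prey, p_value) attaches
    bootstrap p-values to matching edges.
    """
    roles = roles or RoleAnnotation({})
    bait_proteins = bait_proteins or {}
    pval_map: dict[tuple[str, str], float] = {}
    if pvals is not None:
        pval_map = {(r.bait, r.prey): float(r.p_value) for r in pvals.itertuples()}

    g = nx.DiGraph()
    baits = set(confidence_table["bait"].unique())

    def add_node(pid: str, is_bait: bool) -> None:
        if pid not in g:
            g.add_node(pid, role=roles.get(pid), is_bait=is_bait, bait_prominence=0.0)
        if is_bait:
            g.nodes[pid]["is_bait"] = True

    for bait in sorted(baits):
        add_node(bait, True)

    hc = confidence_table[confidence_table["high_confidence"]]
    for row in hc.itertuples():
        bait_protein = bait_proteins.get(row.bait, row.bait)
        if row.prey == bait_protein or row.prey == row.bait:
            g.nodes[row.bait]["bait_prominence"] = float(row.score)
            continue
        add_node(row.prey, row.prey in baits)
        g.add_edge(row.bait, row.prey, score=float(row.score), dashed=bool(row.dashed),
                   reciprocal=False, p_value=pval_map.get((row.bait, row.prey)))

    for u, v in g.edges:
        g.edges[u, v]["reciprocal"] = g.has_edge(v, u)
    return InteractionNetwork(g, baits)


def reciprocal_rate(network: InteractionNetwork,
                    bait_set: set[str] | None = None) -> tuple[int, int, float]:
    """Reciprocal confirmation rate among bait-bait interactions.

    Only unordered bait pairs with at least one directed edge count as
    *possible*; pairs with both directions are *observed* reciprocals.
    Returns (observed, possible, rate) with rate NaN when nothing is
    possible.
    """
    baits = bait_set if bait_set is not None else network.baits
    g = network.graph
    observed = possible = 0
    baits_sorted = sorted(baits)
    for i, a in enumerate(baits_sorted):
        for b in baits_sorted[i + 1:]:
            ab = g.has_edge(a, b)
            ba = g.has_edge(b, a)
            if ab or ba:
                possible += 1
                if ab and ba:
                    observed += 1
    rate = observed / possible if possible else float("nan")
    return observed, possible, rate


def functional_agreement(network: InteractionNetwork, roles: RoleAnnotation,
                         drop_unannotated: bool = False) -> float:
    """Fraction of edges whose endpoints share a functional role.

    By default an edge with an unannotated endpoint counts in the
    denominator and never agrees (annotation catalogs are incomplete);
    ``drop_unannotated`` removes such edges from the denominator instead.
    """
    agree = total = 0
    for u, v in network.graph.edges:
        ru, rv = roles.get(u), roles.get(v)
        if drop_unannotated and (ru is None or rv is None):
            continue
        total += 1
        if ru is not None and ru == rv:
            agree += 1
    return agree / total if total else float("nan")


def permutation_test(network: InteractionNetwork, roles: RoleAnnotation,
                     n_perm: int = 100_000,
                     rng: np.random.Generator | int | None = None,
                     drop_unannotated: bool = False) -> AgreementResult:
    """Permutation null for the functional-role agreement.

    Role labels (including "no label") are shuffled across the proteins
    appearing in the network, preserving the label multiset, and the
    agreement is recomputed; p is the fraction of permutations whose
    agreement is at least the observed one (ties count toward the null,
    so a network whose agreement cannot be beaten — e.g. every node one
    role — gets p = 1, never a spuriously small value).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nodes = sorted(network.graph.nodes)
    node_pos = {n: i for i, n in enumerate(nodes)}
    labels = np.array([roles.get(n) if roles.get(n) is not None else "\0unannotated"
                       for n in nodes], dtype=object)
    annotated = labels != "\0unannotated"
    edges = list(network.graph.edges)
    if not edges:
        raise ValueError("permutation test needs at least one edge")
    u_idx = np.array([node_pos[u] for u, _ in edges])
    v_idx = np.array([node_pos[v] for _, v in edges])

    def agreement(lab: np.ndarray, ann: np.ndarray) -> float:
        both_ann = ann[u_idx] & ann[v_idx]
        agree = (lab[u_idx] == lab[v_idx]) & both_ann
        total = both_ann.sum() if drop_unannotated else len(edges)
        return agree.sum() / total if total else float("nan")

    observed = agreement(labels, annotated)
    exceed = 0
    perm_sum = 0.0
    for _ in range(n_perm):
        perm = rng.permutation(len(nodes))
        a = agreement(labels[perm], annotated[perm])
        perm_sum += a
        if a >= observed:
            exceed += 1
    return AgreementResult(observed, perm_sum / n_perm, exceed / n_perm, n_perm)


def profile_correlations(score_profiles: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Pearson correlations between pull-down prey profiles.

    ``score_profiles`` maps each bait (and optionally the control) to a
    protein -> value map: pseudo-confidence scores for baits, median-max
    values for the control.  Vectors are aligned on the union of proteins
    observed in any pull-down, zero-filled, giving a symmetric matrix
    with unit diagonal; correlations against a constant vector are NaN.
    """
    names = sorted(score_profiles)
    if len(names) < 2:
        raise ValueError("need at least two pull-down profiles")
    proteins = sorted({p for prof in score_profiles.values() for p in prof})
    mat = np.array([[score_profiles[n].get(p, 0.0) for p in proteins] for n in names])
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x, y = mat[i], mat[j]
            xc, yc = x - x.mean(), y - y.mean()
            denom = math.sqrt(float((xc ** 2).sum()) * float((yc ** 2).sum()))
            r = float((xc * yc).sum() / denom) if denom else float("nan")
            out.iloc[i, j] = out.iloc[j, i] = r
    return out


def degree_summary(network: InteractionNetwork) -> dict[str, float]:
    """Bait/prey/edge counts and mean degrees (means to one decimal)."""
    n_edges = network.n_edges()
    baits_with_prey = {u for u, _ in network.graph.edges}
    prey = network.prey
    n_baits = len(network.baits)
    n_prey = len(prey)
    mean_prey_per_bait = (
        round(n_edges / len(baits_with_prey), 1) if baits_with_prey else float("nan")
    )
    mean_baits_per_prey = round(n_edges / n_prey, 1) if n_prey else float("nan")
    return {
        "n_baits": n_baits,
        "n_prey": n_prey,
        "n_edges": n_edges,
        "mean_prey_per_bait": mean_prey_per_bait,
        "mean_baits_per_prey": mean_baits_per_prey,
    }
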