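"""Transcriptomic validation of interactions.

Interacting proteins tend to be co-expressed: both subunits must be
present for a complex to form.  This module computes percentile-rank
transcript abundance, centered Pearson co-expression for gene pairs, and
compares the co-expression distributions of interacting versus
non-interacting pairs with a Welch two-sample t-test (unequal variances,
two-tailed) plus a frequency-polygon table for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

Pair = tuple[str, str]


@dataclass
class CoexpressionReport:
    interacting: dict[Pair, float]
    noninteracting: dict[Pair, float]
    interacting_mean: float
    interacting_sd: float
    noninteracting_mean: float
    noninteracting_sd: float
    t_statistic: float
    p_value: float
    df: float
    polygon: pd.DataFrame  # columns: bin_center, interacting, noninteracting

    def summary(self) -> dict[str, float]:
        return {
            "n_interacting": len(self.interacting),
            "n_noninteracting": len(self.noninteracting),
            "interacting_mean": self.interacting_mean,
            "interacting_sd": self.interacting_sd,
            "noninteracting_mean": self.noninteracting_mean,
            "noninteracting_sd": self.noninteracting_sd,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
        }


def percentile_rank(expression: ExpressionMatrix) -> dict[str, float]:
    """Percentile rank of each gene's mean log2 ratio, max -> 100.

    Convention: rank/n * 100 with average ranks for ties.  Genes whose
    expression is entirely missing are excluded with a warning.
    """
    means = expression.values.mean(axis=1, skipna=True)
    dropped = means.index[means.isna()]
    if len(dropped):
        import logging
        logging.getLogger("apmsnet").warning(
            "percentile_rank: excluding all-missing genes %s", list(dropped))
        means = means.dropna()
    if len(means) < 2:
        raise ValueError("need at least two genes with expression values")
    ranks = means.rank(method="average")
    return (ranks / len(means) * 100.0).to_dict()


def pair_coexpression(expression: ExpressionMatrix, pairs: list[Pair],
                      min_overlap: int = 3) -> dict[Pair, float]:
    """Centered Pearson correlation per gene pair over shared conditions.

    Missing values are pairwise-deleted; pairs with fewer than
    ``min_overlap`` shared conditions, or with an absent gene, get NaN.
    """
    values = expression.values
    out: dict[Pair, float] = {}
    for a, b in pairs:
        if a not in values.index or b not in values.index:
            out[(a, b)] = float("nan")
            continue
        x = values.loc[a].to_numpy(dtype=float)
        y = values.loc[b].to_numpy(dtype=float)
        mask = ~(np.isnan(x) | np.isnan(y))
        if mask.sum() < min_overlap:
            out[(a, b)] = float("nan")
            continue
        xm, ym = x[mask], y[mask]
        xc, yc = xm - xm.mean(), ym - ym.mean()
        denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        out[(a, b)] = float((xc * yc).sum() / denom) if denom else float("nan")
    return out


def frequency_polygon(values: np.ndarray, n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Bin centers and per-bin fractions over [-1, 1]; fractions sum to 1."""
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()
    fractions = counts / total if total else counts.astype(float)
    return centers, fractions


def compare_sets(interacting_pairs: list[Pair], noninteracting_pairs: list[Pair],
                 expression: ExpressionMatrix, n_bins: int = 20,
                 min_overlap: int = 3) -> CoexpressionReport:
    """Welch t-test between interacting and non-interacting co-expression.

    Both sets must contribute at least two finite correlations.  The
    returned report carries the per-pair correlations, means +/- SDs,
    the Welch statistic with Welch-Satterthwaite degrees of freedom, the
    two-tailed p-value, and a frequency-polygon table.
    """
    co_int = pair_coexpression(expression, interacting_pairs, min_overlap)
    co_non = pair_coexpression(expression, noninteracting_pairs, min_overlap)
    a = np.array([v for v in co_int.values() if np.isfinite(v)])
    b = np.array([v for v in co_non.values() if np.isfinite(v)])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each set needs at least two finite correlations")
    res = stats.ttest_ind(a, b, equal_var=False)
    centers, frac_a = frequency_polygon(a, n_bins)
    _, frac_b = frequency_polygon(b, n_bins)
    polygon = pd.DataFrame({
        "bin_center": centers, "interacting": frac_a, "noninteracting": frac_b,
    })
    return CoexpressionReport(
        interacting=co_int,
        noninteracting=co_non,
        interacting_mean=float(a.mean()),
        interacting_sd=float(a.std(ddof=1)),
        noninteracting_mean=float(b.mean()),
        noninteracting_sd=float(b.std(ddof=1)),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        polygon=polygon,
    )


def noninteracting_pairs(confidence_table: pd.DataFrame) -> list[Pair]:
    """Bait x observed-protein pairs not in the high-confidence set.

    The contrast universe is every (bait, observed prey) combination from
    the pull-downs minus the high-confidence edges and self pairs.
    """
    hc = {(r.bait, r.prey) for r in
          confidence_table[confidence_table["high_confidence"]].itertuples()}
    out = []
    for row in confidence_table.itertuples():
        if row.bait == row.prey or (row.bait, row.prey) in hc:
            continue
        out.append((row.bait, row.prey))
    return sorted(set(out))
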