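"""Bootstrap significance of bait-prey pairs.

Each (bait, prey) pair is tested by resampling the prey's per-replicate
fraction-maximum emPAI values against a pool of "null" replicates: all
replicates of other baits and of the no-bait control whose full protein
profile correlates with every replicate of the focal bait at Pearson
R below a threshold (0.3 by default).  Each bootstrap iteration samples
three values with replacement from the bait side and three from the
pool side for the same prey, and counts a success when the bait median
strictly exceeds the pool median; the p-value is 1 - n_successes/B with
B = 10,000.  Ties favour the null, making the test conservative; the
smallest attainable non-zero p-value is 1/B.

Randomness is a per-pair numpy Generator seeded from
(seed, bait, prey) via SeedSequence, so results are independent of row
order and byte-identical across runs with the same seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .confidence_scoring import max_over_fractions
from .io_formats import CONTROL_ID, PulldownMatrix


@dataclass
class BootstrapConfig:
    n_boot: int = 10_000
    r_threshold: float = 0.3
    sample_size: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 <= self.r_threshold <= 1.0:
            raise ValueError("r_threshold must be in [0, 1]")


@dataclass
class BootstrapResult:
    """Rows of the significance table plus the null-pool bookkeeping."""

    table: pd.DataFrame  # columns: bait, prey, n_exceed, p_value, pool_size
    pools: dict[str, list[tuple[str, int]]]  # bait -> [(source_bait, replicate)]


RESULT_COLUMNS = ["bait", "prey", "n_exceed", "p_value", "pool_size"]


def replicate_profile(matrix: PulldownMatrix, bait_id: str, replicate_id: int,
                      protein_index: list[str] | None = None) -> np.ndarray:
    """Dense max-over-fractions vector for one replicate.

    Aligned to ``protein_index`` (default: all proteins in the matrix,
    sorted); unobserved proteins are 0.
    """
    index = protein_index if protein_index is not None else matrix.proteins()
    maxima = max_over_fractions(matrix, bait_id, replicate_id)
    return np.array([maxima.get(p, 0.0) for p in index])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return float("nan")  # constant profile: no linear association defined
    return float((xc * yc).sum() / denom)


def build_null_pool(matrix: PulldownMatrix, bait_id: str,
                    config: BootstrapConfig | None = None,
                    protein_index: list[str] | None = None
                    ) -> list[tuple[str, int]]:
    """Replicates usable as null data for one bait.

    A candidate replicate (from any other bait or the control) enters the
    pool iff its profile correlates at R < ``r_threshold`` with EVERY
    replicate profile of the focal bait.  The bait's own replicates are
    never candidates.  NaN correlations (constant profiles) count as
    dissimilar.
    """
    config = config or BootstrapConfig()
    index = protein_index if protein_index is not None else matrix.proteins()
    focal = [replicate_profile(matrix, bait_id, rep, index)
             for rep in matrix.replicates(bait_id)]
    pool: list[tuple[str, int]] = []
    for other in matrix.baits(include_control=True):
        if other == bait_id:
            continue
        for rep in matrix.replicates(other):
            profile = replicate_profile(matrix, other, rep, index)
            rs = [_pearson(profile, f) for f in focal]
            if all(np.isnan(r) or r < config.r_threshold for r in rs):
                pool.append((other, rep))
    if not pool:
        raise ValueError(
            f"empty null pool for bait {bait_id!r}; every candidate replicate "
            f"correlates at R >= {config.r_threshold} — consider raising r_threshold"
        )
    return pool


def pair_rng(seed: int, bait_id: str, prey_id: str) -> np.random.Generator:
    """Deterministic per-(bait, prey) generator, independent of row order."""
    return np.random.default_rng(np.random.SeedSequence(
        [seed, zlib.crc32(bait_id.encode()), zlib.crc32(prey_id.encode())]))


def bootstrap_pvalue(bait_values, pool_values, config: BootstrapConfig,
                     rng: np.random.Generator) -> tuple[int, float]:
    """One pair's bootstrap: (n_exceed, p).

    Samples ``sample_size`` values with replacement from each side
    ``n_boot`` times and counts strict bait-median > pool-median wins.
    """
    bait_values = np.asarray(bait_values, dtype=float)
    pool_values = np.asarray(pool_values, dtype=float)
    if len(bait_values) != config.sample_size:
        raise ValueError(f"expected {config.sample_size} bait values, got {len(bait_values)}")
    if len(pool_values) == 0:
        raise ValueError("empty pool values")
    b = rng.choice(bait_values, size=(config.n_boot, config.sample_size), replace=True)
    c = rng.choice(pool_values, size=(config.n_boot, config.sample_size), replace=True)
    n_exceed = int((np.median(b, axis=1) > np.median(c, axis=1)).sum())
    return n_exceed, 1.0 - n_exceed / config.n_boot


def significance_table(matrix: PulldownMatrix,
                       config: BootstrapConfig | None = None,
                       baits: list[str] | None = None) -> BootstrapResult:
    """Bootstrap p-values for every observed (bait, prey) pair.

    The bait protein itself is tested like any prey, so bait
    self-significance is reported as well.
    """
    config = config or BootstrapConfig()
    baits = baits if baits is not None else matrix.baits()
    index = matrix.proteins()
    pos = {p: i for i, p in enumerate(index)}

    # densify every replicate once
    profiles = {
        (bait, rep): replicate_profile(matrix, bait, rep, index)
        for bait in matrix.baits(include_control=True)
        for rep in matrix.replicates(bait)
    }

    rows = []
    pools: dict[str, list[tuple[str, int]]] = {}
    for bait in baits:
        pool = build_null_pool(matrix, bait, config, index)
        pools[bait] = pool
        reps = matrix.replicates(bait)
        observed = sorted({k[0] for k in matrix.entries if k[1] == bait})
        pool_matrix = np.stack([profiles[m] for m in pool])
        bait_matrix = np.stack([profiles[(bait, rep)] for rep in reps])
        for prey in observed:
            i = pos[prey]
            bait_values = bait_matrix[:, i]
            if len(bait_values) != config.sample_size:
                raise ValueError(
                    f"bait {bait!r} has {len(bait_values)} replicates but the "
                    f"bootstrap samples {config.sample_size}"
                )
            rng = pair_rng(config.rng_seed, bait, prey)
            n_exceed, p = bootstrap_pvalue(bait_values, pool_matrix[:, i], config, rng)
            rows.append({"bait": bait, "prey": prey, "n_exceed": n_exceed,
                         "p_value": p, "pool_size": len(pool)})
    return BootstrapResult(pd.DataFrame(rows, columns=RESULT_COLUMNS), pools)
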