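"""Gene-level one-sided significance by alpha-RRA rank aggregation with a
permutation null.

Each guide statistic (per-gene CS contributions, here guide-level CS
averaged over replicates) is converted to a percentile in (0, 1) by rank;
for a gene whose m guides have sorted percentiles p(1) <= ... <= p(m), the
robust rank aggregation score restricted to the top alpha fraction is

    rho = min_{i <= k} BetaCDF(p(i); i, m - i + 1),  k = #{i : p(i) <= alpha},

with rho = 1 when no percentile clears alpha.  Significance comes from a
permutation null built by reassigning guide percentiles to pseudo-genes of
matching guide count; the one-sided p uses the add-one estimator
p = (1 + #{null rho <= observed rho}) / (n_permutations + 1).
Depletion ranks ascending (most-depleted guides get the smallest
percentiles); enrichment ranks descending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.25
DEFAULT_N_PERMUTATIONS = 10_000


@dataclass
class RRAResult:
    """Per-gene rank-aggregation scores and permutation p-values for one
    direction (depletion or enrichment)."""

    table: pd.DataFrame  # columns: gene, rho, p, fdr, n_guides
    direction: str
    n_permutations: int
    seed: int


def percentile_ranks(statistic: pd.Series, direction: str) -> pd.Series:
    """Percentiles rank/(N+1) in (0,1); ties get the average rank.

    ``direction="depletion"`` ranks ascending (most negative first);
    ``direction="enrichment"`` ranks descending.
    """
    x = statistic.astype(float)
    if direction == "depletion":
        ranks = stats.rankdata(x, method="average")
    elif direction == "enrichment":
        ranks = stats.rankdata(-x, method="average")
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return pd.Series(ranks / (len(x) + 1), index=x.index)


def rra_rho(percentiles: np.ndarray, alpha: float = DEFAULT_ALPHA) -> float:
    """Alpha-restricted rank-aggregation score for one gene's percentiles."""
    p = np.sort(np.asarray(percentiles, dtype=float))
    if p.size == 0:
        raise ValueError("gene has no percentiles")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    k = int((p <= alpha).sum())
    if k == 0:
        return 1.0
    m = p.size
    i = np.arange(1, k + 1)
    return float(stats.beta.cdf(p[:k], i, m - i + 1).min())


def _rra_rho_rows(sorted_rows: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized rho over a (n_rows, m) array of row-sorted percentiles."""
    n, m = sorted_rows.shape
    i = np.arange(1, m + 1)
    beta = stats.beta.cdf(sorted_rows, i, m - i + 1)
    beta = np.where(sorted_rows <= alpha, beta, np.inf)
    rho = beta.min(axis=1)
    return np.where(np.isinf(rho), 1.0, rho)


def permutation_p(
    guide_stats: pd.Series,
    guide_to_gene: pd.Series,
    direction: str,
    alpha: float = DEFAULT_ALPHA,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> RRAResult:
    """Alpha-RRA with a permutation null matched on guide count.

    ``guide_stats`` holds one statistic per guide (non-targeting guides may
    be included; they contribute to the rank pool but not to gene calls).
    The null for guide count m is built by drawing m percentiles from the
    pooled percentile distribution n_permutations times.
    """
    if n_permutations < 100:
        raise ValueError("need >= 100 permutations")
    pct = percentile_ranks(guide_stats, direction)
    targeting = guide_to_gene.loc[guide_to_gene.index.intersection(pct.index)]
    targeting = targeting[targeting != "NON_TARGETING"]

    grouped = pct.loc[targeting.index].groupby(targeting.loc[targeting.index])
    obs = grouped.apply(lambda s: rra_rho(s.to_numpy(), alpha))
    n_guides = grouped.size()

    rng = np.random.default_rng(seed)
    pool = pct.to_numpy()
    p_out = pd.Series(index=obs.index, dtype=float)
    for m in sorted(n_guides.unique()):
        draws = rng.choice(pool, size=(n_permutations, int(m)), replace=True)
        draws.sort(axis=1)
        null = np.sort(_rra_rho_rows(draws, alpha))
        genes_m = n_guides.index[n_guides == m]
        counts = np.searchsorted(null, obs.loc[genes_m].to_numpy(), side="right")
        p_out.loc[genes_m] = (1.0 + counts) / (n_permutations + 1.0)

    table = pd.DataFrame({
        "gene": obs.index,
        "rho": obs.to_numpy(),
        "p": p_out.loc[obs.index].to_numpy(),
        "n_guides": n_guides.loc[obs.index].to_numpy(),
    }).reset_index(drop=True)
    table["fdr"] = benjamini_hochberg(table["p"].to_numpy())
    return RRAResult(table, direction, n_permutations, seed)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported, not used for calls)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adjusted, 0, 1)
    return out


def run_both_directions(
    guide_stats: pd.Series,
    guide_to_gene: pd.Series,
    alpha: float = DEFAULT_ALPHA,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Depletion and enrichment analyses merged into one per-gene table with
    columns (gene, n_guides, rho_depletion, p_depletion, rho_enrichment,
    p_enrichment, ...)."""
    dep = permutation_p(guide_stats, guide_to_gene, "depletion", alpha,
                        n_permutations, seed).table
    enr = permutation_p(guide_stats, guide_to_gene, "enrichment", alpha,
                        n_permutations, seed + 1).table
    merged = dep.rename(columns={
        "rho": "rho_depletion", "p": "p_depletion", "fdr": "fdr_depletion"
    }).merge(
        enr.rename(columns={
            "rho": "rho_enrichment", "p": "p_enrichment",
            "fdr": "fdr_enrichment"})[
            ["gene", "rho_enrichment", "p_enrichment", "fdr_enrichment"]],
        on="gene")
    return merged
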