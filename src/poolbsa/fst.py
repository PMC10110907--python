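"""Pool-aware F_ST: per-SNP scan, global and pairwise estimates.

Differentiation among populations is estimated from the control pools
with a two-level moment ANOVA in the Weir–Cockerham style. Pool
sequencing samples alleles twice — 2N chromosomes into the pool, then R
reads from the pool — so each population's sample size is replaced by an
effective allele count, the harmonic combination

    n_e = 2 N R / (2 N + R).

Per SNP the estimator returns the between-population variance component
``a`` (numerator) and the total ``a + b`` (denominator) separately, so
that multi-SNP estimates can be aggregated as a ratio of sums
(sum a / sum (a + b)) rather than a mean of per-SNP ratios. Standard
errors for pairwise genome-wide values come from a block jackknife over
contiguous SNP blocks, which is robust to local linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import PoolCounts, StudyDesign


def effective_allele_count(n_females, depth):
    """Effective number of alleles sampled by a pool: 2NR / (2N + R)."""
    n_females = np.asarray(n_females, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(n_females < 1) or np.any(depth < 1):
        raise ValueError("n_females and depth must be >= 1")
    two_n = 2.0 * n_females
    return two_n * depth / (two_n + depth)


def _control_freqs_and_sizes(
    counts: PoolCounts, design: StudyDesign, populations: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    p = np.empty((len(counts), len(populations)))
    n_e = np.empty_like(p)
    for j, pop in enumerate(populations):
        pool = design.pool_for(pop, "control")
        depth = counts.depth(pool.pool_id)
        if np.any(depth <= 0):
            raise ValueError(
                f"pool {pool.pool_id!r} has zero depth; filter first"
            )
        p[:, j] = counts.ref(pool.pool_id) / depth
        n_e[:, j] = effective_allele_count(pool.n_females, depth)
    return p, n_e


def _anova_components(p: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Between-population component ``a`` and total ``a + b`` per SNP.

    Two-level ANOVA on allele indicators with per-population (effective)
    sample sizes n_ij: MSP is the between-population mean square, MSI the
    within-population mean square, and a = (MSP - MSI) / n_c with the
    usual unbalanced-design coefficient n_c.
    """
    r = p.shape[1]
    if r < 2:
        raise ValueError("need at least two populations")
    N = n.sum(axis=1)
    n_c = (N - (n**2).sum(axis=1) / N) / (r - 1)
    p_bar = (n * p).sum(axis=1) / N
    msp = (n * (p - p_bar[:, None]) ** 2).sum(axis=1) / (r - 1)
    msi = (n * p * (1.0 - p)).sum(axis=1) / (N - r)
    a = (msp - msi) / n_c
    return a, a + msi


def fst_per_snp(
    counts: PoolCounts,
    design: StudyDesign,
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP F_ST components from the control pools.

    Returns a frame with ``chrom, pos, a, a_plus_b, fst``; ``fst`` is the
    per-SNP ratio a / (a + b), left missing where the denominator is not
    positive (e.g. a site monomorphic in every pool). Negative per-SNP
    estimates are kept so ratio-of-sums aggregation stays unbiased.
    """
    if populations is None:
        populations = design.population_ids
    p, n_e = _control_freqs_and_sizes(counts, design, populations)
    a, total = _anova_components(p, n_e)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(total > 0, a / np.where(total > 0, total, 1.0), np.nan)
    out = counts.sites[["chrom", "pos"]].copy()
    out["a"] = a
    out["a_plus_b"] = total
    out["fst"] = fst
    return out


def fst_global(components: pd.DataFrame) -> float:
    """Genome-wide ratio-of-sums estimate: sum(a) / sum(a + b)."""
    denom = components["a_plus_b"].sum()
    if denom <= 0:
        raise ValueError("total variance is zero: no polymorphic sites")
    return float(components["a"].sum() / denom)


def _block_jackknife(a: np.ndarray, total: np.ndarray, block_size: int) -> float:
    """Delete-one-block jackknife SE of the ratio-of-sums estimate."""
    n = len(a)
    n_blocks = max(1, int(np.ceil(n / block_size)))
    if n_blocks < 2:
        return float("nan")
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    sum_a, sum_t = a.sum(), total.sum()
    loo = np.array(
        [
            (sum_a - a[lo:hi].sum()) / (sum_t - total[lo:hi].sum())
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
    )
    return float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))


def fst_pairwise(
    counts: PoolCounts,
    design: StudyDesign,
    block_size: int = 500,
) -> pd.DataFrame:
    """Pairwise genome-wide F_ST with block-jackknife standard errors.

    Each pair is recomputed on its two-population subset (ratio of sums
    over all SNPs); SNPs are taken in genomic order and the jackknife
    deletes contiguous blocks of ``block_size`` SNPs.
    """
    order = counts.sites.sort_values(["chrom", "pos"]).index.to_numpy()
    rows = []
    for pop_a, pop_b in combinations(design.population_ids, 2):
        p, n_e = _control_freqs_and_sizes(counts, design, [pop_a, pop_b])
        a, total = _anova_components(p[order], n_e[order])
        value = a.sum() / total.sum()
        se = _block_jackknife(a, total, block_size)
        rows.append(
            {"pop_a": pop_a, "pop_b": pop_b, "fst": float(value), "se": se}
        )
    return pd.DataFrame(rows)


def flag_high_fst(fst_values, threshold: float = 0.15) -> np.ndarray:
    """Flag strongly differentiated SNPs: strict fst > threshold.

    Missing values are never flagged.
    """
    fst = np.asarray(fst_values, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(fst, nan=-np.inf) > threshold


@dataclass
class FstScan:
    """Per-SNP scan plus global and pairwise summaries."""

    per_snp: pd.DataFrame
    global_fst: float
    mean_per_snp_fst: float
    pairwise: pd.DataFrame
    threshold: float

    @property
    def n_flagged(self) -> int:
        return int(self.per_snp["high_fst"].sum())


def run_fst_scan(
    counts: PoolCounts,
    design: StudyDesign,
    threshold: float = 0.15,
    block_size: int = 500,
) -> FstScan:
    """Full differentiation scan from control pools.

    Reports both the ratio-of-sums global estimate and the mean of
    per-SNP ratios (they differ on heterogeneous data), the pairwise
    matrix with jackknife SEs, and the per-SNP high-differentiation flag.
    """
    per_snp = fst_per_snp(counts, design)
    per_snp["high_fst"] = flag_high_fst(per_snp["fst"], threshold)
    return FstScan(
        per_snp=per_snp,
        global_fst=fst_global(per_snp),
        mean_per_snp_fst=float(per_snp["fst"].mean()),
        pairwise=fst_pairwise(counts, design, block_size),
        threshold=threshold,
    )
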