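"""Allele-frequency shift statistics and nested likelihood-ratio tests.

For each SNP and population the shift between the selected and control
pool is measured on the variance-stabilized scale::

    dz_j = arcsin(sqrt(p_sel_j)) - arcsin(sqrt(p_ctrl_j))

Positive dz means the reference base is more common in the selected pool.
On this scale the sampling variance of each pool's transformed frequency
is approximately frequency-independent,

    V_pool = 1 / (8 N) + 1 / (4 R),

the two terms reflecting the finite pool of N females (2N chromosomes)
and the finite read depth R; the per-population shift variance is the sum
over the two pools. Shifts are modeled as independent Gaussians,
dz_j ~ Normal(delta_j, V_j), and four nested models are compared:

* Model 0 — delta_j = 0 everywhere (no effect; 0 parameters),
* Model 1 — one shared delta (strictly parallel response; 1 parameter),
* Model 2 — one delta per exposure group (high / low; 2 parameters),
* Model 4 — free per-population deltas (4 parameters with 4 populations).

Likelihood-ratio statistics LRT_k = 2 (LL_k - LL_0) are referred to
chi-square distributions with 1, 2, and 4 degrees of freedom. Genome-wide
significance is declared by Benjamini–Hochberg FDR control on the
free-model p-values (a permissive screen); each significant SNP is then
assigned the model with the smallest raw p-value, ties broken by the
highest log-likelihood, then by parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PoolCounts, StudyDesign

_LOG_2PI = float(np.log(2.0 * np.pi))
#: magnitude below which a negative LRT is treated as floating-point error
LRT_CLIP = 1e-9
#: relative p-value spacing below which competing models are considered tied
TIE_TOL = 1e-12

MODEL_LABELS = ("LRT1", "LRT2", "LRT4")


def asin_sqrt(p):
    """Variance-stabilizing transform z = arcsin(sqrt(p)), in radians."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("frequencies must lie in [0, 1]")
    return np.arcsin(np.sqrt(p))


def sampling_variance(n_females, depth):
    """Variance of one pool's transformed frequency: 1/(8N) + 1/(4R)."""
    n_females = np.asarray(n_females, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(n_females < 1) or np.any(depth < 1):
        raise ValueError("n_females and depth must be >= 1")
    return 1.0 / (8.0 * n_females) + 1.0 / (4.0 * depth)


@dataclass
class ShiftTable:
    """Per-SNP x per-population transformed shifts and their variances.

    Arrays have shape (n_snps, n_pops), with columns ordered as
    ``populations``; ``high_group`` marks the high-exposure populations.
    """

    sites: pd.DataFrame  # chrom, pos, ref, alt
    populations: list[str]
    high_group: np.ndarray  # bool, (n_pops,)
    z_ctrl: np.ndarray
    z_sel: np.ndarray
    dz: np.ndarray
    var: np.ndarray

    def __len__(self) -> int:
        return len(self.sites)


def compute_shifts(counts: PoolCounts, design: StudyDesign) -> ShiftTable:
    """Transformed selected-minus-control shifts for every SNP x population."""
    pops = design.population_ids
    n = len(counts)
    z_ctrl = np.empty((n, len(pops)))
    z_sel = np.empty((n, len(pops)))
    var = np.empty((n, len(pops)))
    for j, pop in enumerate(pops):
        cols = {}
        for cond in ("control", "selected"):
            pool = design.pool_for(pop, cond)
            depth = counts.depth(pool.pool_id)
            if np.any(depth <= 0):
                raise ValueError(
                    f"pool {pool.pool_id!r} has zero depth at some sites; "
                    "filter before computing shifts"
                )
            cols[cond] = (
                asin_sqrt(counts.ref(pool.pool_id) / depth),
                sampling_variance(pool.n_females, depth),
            )
        z_ctrl[:, j] = cols["control"][0]
        z_sel[:, j] = cols["selected"][0]
        var[:, j] = cols["control"][1] + cols["selected"][1]
    high = np.array([design.exposure_group(p) == "high" for p in pops])
    return ShiftTable(
        sites=counts.sites[["chrom", "pos", "ref", "alt"]].copy(),
        populations=list(pops),
        high_group=high,
        z_ctrl=z_ctrl,
        z_sel=z_sel,
        dz=z_sel - z_ctrl,
        var=var,
    )


# ---------------------------------------------------------------------------
# model fits (closed-form Gaussian MLEs). All accept dz/V of shape
# (..., n_pops) and reduce over the last axis, so they work per SNP or
# vectorized over a whole table.


def _normal_loglik(dz, mean, var):
    return -0.5 * (_LOG_2PI + np.log(var) + (dz - mean) ** 2 / var)


def loglik_null(dz, var):
    """Log-likelihood of Model 0: every true shift is zero."""
    dz, var = np.asarray(dz, float), np.asarray(var, float)
    if np.any(var <= 0):
        raise ValueError("shift variances must be positive")
    return _normal_loglik(dz, 0.0, var).sum(axis=-1)


def fit_parallel(dz, var):
    """Model 1 MLE: inverse-variance weighted mean shift.

    Returns ``(delta_hat, LL1)``.
    """
    dz, var = np.asarray(dz, float), np.asarray(var, float)
    w = 1.0 / var
    delta = (dz * w).sum(axis=-1) / w.sum(axis=-1)
    ll = _normal_loglik(dz, delta[..., None], var).sum(axis=-1)
    return delta, ll


def fit_group(dz, var, high_group):
    """Model 2 MLE: one weighted-mean shift per exposure group.

    Returns ``(delta_high, delta_low, LL2)``.
    """
    dz, var = np.asarray(dz, float), np.asarray(var, float)
    high = np.asarray(high_group, bool)
    if not high.any() or high.all():
        raise ValueError("both exposure groups must be non-empty")
    w = 1.0 / var
    d_high = (dz * w)[..., high].sum(axis=-1) / w[..., high].sum(axis=-1)
    d_low = (dz * w)[..., ~high].sum(axis=-1) / w[..., ~high].sum(axis=-1)
    mean = np.where(high, d_high[..., None], d_low[..., None])
    ll = _normal_loglik(dz, mean, var).sum(axis=-1)
    return d_high, d_low, ll


def fit_free(dz, var):
    """Model 4 MLE: each population's shift is its own estimate.

    Returns ``(delta_j, LL4)``; LL4 = -0.5 * sum log(2 pi V_j), and the
    implied statistic LRT4 reduces to sum dz_j^2 / V_j.
    """
    dz, var = np.asarray(dz, float), np.asarray(var, float)
    ll = (-0.5 * (_LOG_2PI + np.log(var))).sum(axis=-1)
    return dz.copy(), ll


def lrt_pvalues(ll0, ll1, ll2, ll4):
    """LRT statistics and chi-square p-values for the three nested tests.

    Returns ``((LRT1, p1), (LRT2, p2), (LRT4, p4))`` with df 1, 2, 4.
    Negative statistics larger than a 1e-9 rounding tolerance raise, as
    they indicate a broken likelihood computation.
    """
    out = []
    for ll, df in ((ll1, 1), (ll2, 2), (ll4, 4)):
        lrt = 2.0 * (np.asarray(ll, float) - np.asarray(ll0, float))
        if np.any(lrt < -LRT_CLIP):
            raise ValueError(
                f"LRT with df={df} is negative beyond rounding tolerance: "
                f"min={np.min(lrt)}"
            )
        lrt = np.clip(lrt, 0.0, None)
        out.append((lrt, stats.chi2.sf(lrt, df)))
    return tuple(out)


def bh_fdr(p_values, q: float = 0.10):
    """Benjamini–Hochberg step-up adjustment and significance flags.

    Returns ``(adjusted, flags)`` with ``flags = adjusted <= q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0.0) | (p > 1.0)):
        # chi-square survival can underflow to exactly 0 for huge statistics
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def assign_best_model(p1, p2, p4, ll1, ll2, ll4) -> str:
    """Best-fitting model for one significant SNP.

    The model with the smallest raw p-value wins; p-values equal within a
    1e-12 relative tolerance — including simultaneous underflow to exactly
    zero — are tie-broken by the highest log-likelihood, and a residual
    tie by the fewest parameters. The tolerance is relative because raw
    p-values at strong loci span many orders of magnitude; an absolute
    band would spuriously tie every small p-value.
    """
    ps = np.array([p1, p2, p4], dtype=float)
    lls = np.array([ll1, ll2, ll4], dtype=float)
    pmin = ps.min()
    tied = (ps == 0.0) if pmin == 0.0 else ps <= pmin * (1.0 + TIE_TOL)
    if tied.sum() == 1:
        return MODEL_LABELS[int(np.argmax(tied))]
    best_ll = lls[tied].max()
    tied &= lls >= best_ll - TIE_TOL
    return MODEL_LABELS[int(np.argmax(tied))]  # first True = fewest params


@dataclass
class BsaResult:
    """Full per-SNP results table plus model summary counts."""

    table: pd.DataFrame
    summary: dict


def run_bsa(
    counts: PoolCounts,
    design: StudyDesign,
    q: float = 0.10,
) -> BsaResult:
    """Run the full shift-testing procedure on filtered counts.

    Fits all four models per SNP, computes LRT1/2/4 p-values, applies BH
    FDR control at rate ``q`` to the free-model p-values, and assigns a
    best model to each flagged SNP. The returned table has one row per
    SNP; ``summary`` holds the flagged counts per best model.
    """
    shifts = compute_shifts(counts, design)
    dz, var = shifts.dz, shifts.var
    ll0 = loglik_null(dz, var)
    delta1, ll1 = fit_parallel(dz, var)
    d_high, d_low, ll2 = fit_group(dz, var, shifts.high_group)
    delta4, ll4 = fit_free(dz, var)
    (lrt1, p1), (lrt2, p2), (lrt4, p4) = lrt_pvalues(ll0, ll1, ll2, ll4)
    q4, significant = bh_fdr(p4, q)

    best = np.full(len(shifts), "none", dtype=object)
    for i in np.flatnonzero(significant):
        best[i] = assign_best_model(
            p1[i], p2[i], p4[i], ll1[i], ll2[i], ll4[i]
        )

    table = shifts.sites.copy()
    for j, pop in enumerate(shifts.populations):
        table[f"dz_{pop}"] = dz[:, j]
        table[f"V_{pop}"] = var[:, j]
    table["LL0"] = ll0
    table["LL1"] = ll1
    table["LL2"] = ll2
    table["LL4"] = ll4
    table["LRT1"] = lrt1
    table["LRT2"] = lrt2
    table["LRT4"] = lrt4
    table["p1"] = p1
    table["p2"] = p2
    table["p4"] = p4
    table["q4"] = q4
    table["significant"] = significant
    table["best_model"] = best
    table["delta_parallel"] = delta1
    table["delta_high"] = d_high
    table["delta_low"] = d_low
    for j, pop in enumerate(shifts.populations):
        table[f"delta_{pop}"] = delta4[:, j]

    n_sig = int(significant.sum())
    summary = {
        "n_snps": int(len(table)),
        "n_significant": n_sig,
        "fdr_q": q,
        "best_model_counts": {
            label: int((best == label).sum()) for label in MODEL_LABELS
        },
    }
    return BsaResult(table=table, summary=summary)
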