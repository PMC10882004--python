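"""Allocation-bias Monte Carlo: SAE, Cohen's-d SAE, and the 95% PES range.

The allocation bias of one randomized trial is the difference in mean true
outcome change between the arms (placebo minus treatment) *before* any
treatment effect — a purely randomization-induced effect size.  Repeating
the sampling + allocation many times gives a bias distribution whose SD is
the standard allocation error (SAE).  Because the bias distribution is
centered at zero, ``[-1.96*SAE, +1.96*SAE]`` is the 95% range of effect
sizes observable under a null treatment (the possible effect size, PES).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, RngLike, as_rng
from .randomize import (
    ARM_T,
    Allocation,
    RandomizationMethod,
    sample_population,
    stratified_on,
)

__all__ = [
    "BiasDistribution",
    "allocation_bias",
    "cohens_d_bias",
    "pooled_sd",
    "estimate_bias_distribution",
    "pes_range",
    "sae_reduction",
    "sae_vs_index_correlation",
]


def allocation_bias(allocation: Allocation, cohort: Cohort) -> float:
    """Mean true change of the placebo arm minus that of the treatment arm."""
    gt = cohort.gt[allocation.ids]
    mask_t = allocation.arm == ARM_T
    n_t = int(mask_t.sum())
    n_p = allocation.n - n_t
    if n_p == 0 or n_t == 0:
        raise ValueError("allocation bias undefined: an arm is empty")
    return float(gt[~mask_t].mean() - gt[mask_t].mean())


def pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    """Two-group pooled SD with n-1 weights (classical Cohen's d denominator)."""
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("pooled SD needs >= 2 values per group")
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    return float(np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)))


def cohens_d_bias(allocation: Allocation, cohort: Cohort) -> float:
    """Allocation bias on the Cohen's d scale (divided by the pooled SD)."""
    gt = cohort.gt[allocation.ids]
    mask_t = allocation.arm == ARM_T
    gp, gt_arm = gt[~mask_t], gt[mask_t]
    sd = pooled_sd(gp, gt_arm)
    if sd == 0:
        raise ValueError("degenerate cohort: zero pooled SD")
    return float((gp.mean() - gt_arm.mean()) / sd)


@dataclass
class BiasDistribution:
    """Replicate allocation biases and derived summaries."""

    biases: np.ndarray
    biases_d: np.ndarray
    method_tag: str = ""

    @property
    def n_reps(self) -> int:
        return len(self.biases)

    @property
    def sae(self) -> float:
        """Standard allocation error: SD (ddof=1) of the replicate biases."""
        return float(np.std(self.biases, ddof=1))

    @property
    def sae_d(self) -> float:
        """SAE on the Cohen's d scale."""
        return float(np.std(self.biases_d, ddof=1))

    @property
    def mean_bias(self) -> float:
        return float(np.mean(self.biases))

    @property
    def pes(self) -> tuple[float, float]:
        return pes_range(self.sae)

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error of the SAE estimate (~SAE/sqrt(2 n_reps))."""
        return self.sae / np.sqrt(2.0 * self.n_reps)

    def summary(self) -> dict:
        lo, hi = self.pes
        return {
            "method": self.method_tag,
            "n_reps": self.n_reps,
            "sae": self.sae,
            "sae_cohens_d": self.sae_d,
            "mean_bias": self.mean_bias,
            "pes_low": lo,
            "pes_high": hi,
            "mc_se": self.mc_se,
        }


def estimate_bias_distribution(
    cohort: Cohort,
    method: RandomizationMethod,
    n: int = 500,
    n_reps: int = 10_000,
    rng: RngLike = None,
) -> BiasDistribution:
    """Monte-Carlo bias distribution of one randomization method.

    Each replicate independently re-extracts ``n`` participants, regenerates
    the randomization table(s), allocates, and records the bias both in
    outcome units and on the Cohen's d scale.  Replicates run on spawned RNG
    substreams, so replicate r is reproducible regardless of batching.
    """
    if n_reps < 2:
        raise ValueError(f"n_reps must be >= 2, got {n_reps}")
    rng = as_rng(rng)
    gt = cohort.gt
    biases = np.empty(n_reps)
    biases_d = np.empty(n_reps)
    for r, child in enumerate(rng.spawn(n_reps)):
        ids = sample_population(cohort, n, child)
        alloc = method.allocate(cohort, ids, child)
        g = gt[ids]
        mask_t = alloc.arm == ARM_T
        gp, gtr = g[~mask_t], g[mask_t]
        diff = gp.mean() - gtr.mean()
        biases[r] = diff
        sd = pooled_sd(gp, gtr)
        # degenerate (constant-outcome) cohort: d-scale bias undefined
        biases_d[r] = diff / sd if sd > 0 else np.nan
    return BiasDistribution(biases=biases, biases_d=biases_d, method_tag=method.tag)


def pes_range(sae: float) -> tuple[float, float]:
    """95% possible-effect-size range [-1.96*SAE, +1.96*SAE]."""
    if sae < 0:
        raise ValueError(f"SAE must be >= 0, got {sae}")
    return (-1.96 * sae, 1.96 * sae)


def sae_reduction(sae_reference: float, sae_method: float) -> float:
    """Percent SAE reduction of a method relative to a reference method."""
    if sae_reference <= 0:
        raise ValueError(f"reference SAE must be > 0, got {sae_reference}")
    return 100.0 * (1.0 - sae_method / sae_reference)


def sae_vs_index_correlation(
    cohort: Cohort,
    index_names: list[str],
    n: int = 500,
    n_reps: int = 2_000,
    rng: RngLike = None,
    interval: float = 0.5,
) -> pd.DataFrame:
    """SAE of stratifying on each index, paired with that index's Pearson
    correlation to the true change (inverse relationship: better-correlated
    indices remove more between-strata outcome variance)."""
    rng = as_rng(rng)
    rows = []
    for name in index_names:
        v = cohort.index_values(name)
        corr = float(np.corrcoef(v, cohort.gt)[0, 1]) if np.std(v) > 0 else float("nan")
        method = stratified_on(cohort, name, interval=interval)
        dist = estimate_bias_distribution(cohort, method, n=n, n_reps=n_reps, rng=rng)
        rows.append({"index": name, "correlation": corr,
                     "sae": dist.sae, "mc_se": dist.mc_se})
    return pd.DataFrame(rows)
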