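"""SAE as a function of sample size, and the minimum-sample-size solver.

For a given randomization method the SAE shrinks roughly as ``c / sqrt(s)``
with sample size s (CLT scaling; for non-stratified allocation of s
participants into equal arms, c = 2*sigma with sigma the outcome SD).  The
minimum sample size needed to confine the 95% possible-effect-size range
within a target half-width r is

    s_hat = min over s of { s : 1.96 * SAE(s) < r }.

Evaluating this literally on a Monte-Carlo SAE curve returns the first
noise-induced crossing, so by default the solver first fits c/sqrt(s) by
least squares and inverts the fit; the literal grid scan is available with
``smooth=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, RngLike, as_rng
from .randomize import ARM_T, RandomizationMethod, oversampling_sequence

__all__ = [
    "SAECurve",
    "default_grid",
    "build_sae_curve",
    "fit_inverse_sqrt",
    "min_sample_size",
    "sample_size_reduction",
    "NOT_ACHIEVABLE",
]

#: Sentinel returned when no sample size in/under the curve's reach satisfies r.
NOT_ACHIEVABLE: None = None


def default_grid(
    s_min: int = 50, s_max: int = 3000, fine_until: int = 600, coarse_step: int = 10
) -> np.ndarray:
    """Sample-size grid: step 1 up to ``fine_until`` (resolution near typical
    phase II sizes), ``coarse_step`` beyond, inclusive of ``s_max``."""
    fine = np.arange(s_min, min(fine_until, s_max) + 1)
    if s_max <= fine_until:
        return fine
    coarse = np.arange(fine_until + coarse_step, s_max + 1, coarse_step)
    return np.concatenate([fine, coarse])


@dataclass
class SAECurve:
    """SAE evaluated on a grid of sample sizes for one method."""

    grid: np.ndarray
    sae_at: np.ndarray
    n_reps: int
    method_tag: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("sample-size grid must be strictly increasing")
        if np.any(self.sae_at < 0):
            raise ValueError("SAE values must be >= 0")

    def sae(self, s: int) -> float:
        i = int(np.searchsorted(self.grid, s))
        if i == len(self.grid) or self.grid[i] != s:
            raise KeyError(f"sample size {s} not on curve grid")
        return float(self.sae_at[i])


def build_sae_curve(
    cohort: Cohort,
    method: RandomizationMethod,
    grid: np.ndarray | None = None,
    n_reps: int = 1_000,
    rng: RngLike = None,
    sequential: bool = True,
) -> SAECurve:
    """Monte-Carlo SAE curve over a sample-size grid.

    With ``sequential=True`` (default, and how the curve is meant to be
    read) each replicate allocates one long extraction sequence participant
    by participant and records the running bias at every grid point, so
    biases at nearby sample sizes within a replicate are correlated but the
    per-size SD across replicates is unbiased.  The extraction sequence is a
    cohort permutation continued by with-replacement draws, so each prefix
    up to the cohort size is an ordinary without-replacement sample and
    larger sizes engage oversampling.

    ``sequential=False`` instead runs an independent bias distribution per
    grid point (slower; used for validating the sequential shortcut).
    """
    from .bias import estimate_bias_distribution  # local: avoid cycle

    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=int)
    rng = as_rng(rng)

    if not sequential:
        sae = np.array([
            estimate_bias_distribution(cohort, method, n=int(s), n_reps=n_reps, rng=rng).sae
            for s in grid
        ])
        return SAECurve(grid=grid, sae_at=sae, n_reps=n_reps, method_tag=method.tag)

    gt = cohort.gt
    s_max = int(grid[-1])
    biases = np.empty((n_reps, len(grid)))
    for r, child in enumerate(rng.spawn(n_reps)):
        seq = oversampling_sequence(cohort, s_max, child)
        alloc = method.allocate(cohort, seq, child)
        g = gt[seq]
        is_t = alloc.arm == ARM_T
        cum_t_sum = np.cumsum(np.where(is_t, g, 0.0))
        cum_sum = np.cumsum(g)
        cum_t_n = np.cumsum(is_t)
        at = grid - 1
        n_t = cum_t_n[at]
        n_p = grid - n_t
        sum_t = cum_t_sum[at]
        sum_p = cum_sum[at] - sum_t
        biases[r] = sum_p / n_p - sum_t / n_t
    sae = np.std(biases, axis=0, ddof=1)
    return SAECurve(grid=grid, sae_at=sae, n_reps=n_reps, method_tag=method.tag)


def fit_inverse_sqrt(curve: SAECurve) -> float:
    """Least-squares constant c of the model SAE(s) = c / sqrt(s)."""
    w = 1.0 / np.sqrt(curve.grid.astype(float))
    return float((curve.sae_at @ w) / (w @ w))


def min_sample_size(curve: SAECurve, r: float, smooth: bool = True) -> int | None:
    """Minimum sample size with 95% PES range inside ``[-r, r]``.

    Smoothed (default): invert the fitted ``c/sqrt(s)`` model,
    ``ceil((1.96*c/r)**2)``, floored at the curve's smallest grid size.
    Literal: first grid size with ``1.96*SAE(s) < r``.  Returns
    ``NOT_ACHIEVABLE`` (None) when no size up to the top of the grid
    qualifies.
    """
    if r <= 0:
        raise ValueError(f"target PES half-width r must be > 0, got {r}")
    if smooth:
        c = fit_inverse_sqrt(curve)
        if c == 0:
            return int(curve.grid[0])
        s_hat = max(int(curve.grid[0]), math.ceil((1.96 * c / r) ** 2))
        return s_hat if s_hat <= int(curve.grid[-1]) else NOT_ACHIEVABLE
    ok = 1.96 * curve.sae_at < r
    idx = np.flatnonzero(ok)
    return int(curve.grid[idx[0]]) if idx.size else NOT_ACHIEVABLE


def sample_size_reduction(s_reference: int, s_method: int) -> float:
    """Percent reduction in required sample size relative to a reference."""
    if s_reference <= 0:
        raise ValueError(f"reference sample size must be > 0, got {s_reference}")
    return 100.0 * (1.0 - s_method / s_reference)
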