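"""Two-phase trial simulation: proof-of-concept gate, sample-size
re-estimation from the observed effect, and an effect-confirming phase.

The proof-of-concept (PoC) phase is a small one-tailed trial (default
n = 500, alpha = 0.1).  When it passes, the confirmatory phase's size is
estimated from the PoC's observed effect size (OES) and arm SDs so that the
*expected* test statistic reaches the one-sided p = 0.01 normal quantile —
deliberately stricter than the 0.05 decision threshold, building in a
margin against an over-estimated OES.  The confirmatory phase draws a fresh
sample, allocates with the same method, and succeeds at one-tailed
alpha = 0.05.  A trial succeeds only if both phases do.

Over-estimated PoC effects (allocation bias in the placebo-worse direction)
under-size the confirmatory phase and sink it; this is why suppressing
allocation bias raises the end-to-end success rate even though it lowers
the PoC pass rate for small true effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, RngLike, as_rng
from .randomize import ARM_T, RandomizationMethod, sample_population
from .trial import apply_effect, t_test

__all__ = [
    "PhaseConfig",
    "MultiPhaseResult",
    "estimate_confirm_n",
    "run_multiphase",
    "success_rate",
]


@dataclass(frozen=True)
class PhaseConfig:
    """Gates and sizes of the two-phase design."""

    n: int = 500
    alpha_poc: float = 0.1
    alpha_confirm: float = 0.05
    design_p: float = 0.01
    tails: int = 1
    n_cap: int = 20_000

    def __post_init__(self) -> None:
        if not 0.0 < self.design_p < self.alpha_confirm < self.alpha_poc < 1.0:
            raise ValueError(
                "need 0 < design_p < alpha_confirm < alpha_poc < 1, got "
                f"{self.design_p}, {self.alpha_confirm}, {self.alpha_poc}"
            )
        if self.n < 4:
            raise ValueError(f"PoC sample size must be >= 4, got {self.n}")
        if self.n_cap < 4:
            raise ValueError(f"n_cap must be >= 4, got {self.n_cap}")
        if self.tails not in (1, 2):
            raise ValueError(f"tails must be 1 or 2, got {self.tails}")


@dataclass
class MultiPhaseResult:
    """Outcome of one simulated two-phase trial.

    ``confirm_n``/``confirm_p`` are None when the PoC gate failed; ``capped``
    flags a confirmatory size clamped at the safety cap.
    """

    poc_p: float
    poc_oes: float
    gated: bool
    confirm_n: int | None
    confirm_p: float | None
    success: bool
    capped: bool = False

    def __post_init__(self) -> None:
        if self.success and not (self.gated and self.confirm_p is not None):
            raise ValueError("success implies a passed gate and a confirm p value")


def estimate_confirm_n(
    oes: float,
    sd_p: float,
    sd_t: float,
    design_p: float = 0.01,
    n_cap: int = 20_000,
) -> tuple[int, bool]:
    """Total confirmatory sample size targeting the design p value.

    Per-arm size at which the expected two-sample statistic
    oes / sqrt((sd_p^2 + sd_t^2)/m) equals the upper ``design_p`` normal
    quantile z:  m = ceil(z^2 (sd_p^2 + sd_t^2) / oes^2).  Returns
    (total = 2m clamped into [4, n_cap], capped_flag).
    """
    if oes <= 0:
        raise ValueError(f"observed effect size must be > 0, got {oes}")
    z = stats.norm.isf(design_p)
    m = math.ceil(z * z * (sd_p**2 + sd_t**2) / (oes * oes))
    total = 2 * m
    if total > n_cap:
        return n_cap, True
    return max(total, 4), False


def run_multiphase(
    cohort: Cohort,
    method: RandomizationMethod,
    x: float,
    config: PhaseConfig = PhaseConfig(),
    rng: RngLike = None,
) -> MultiPhaseResult:
    """One PoC + (conditionally) one confirmatory trial.

    The confirmatory sample is drawn fresh from the cohort, independent of
    the PoC sample, with oversampling when the estimated size exceeds the
    cohort.  Identical rng state gives an identical result.
    """
    rng = as_rng(rng)
    poc_p, poc_oes, sd_p, sd_t = _phase(cohort, method, config.n, x, rng, config.tails)
    if not (poc_p < config.alpha_poc and poc_oes > 0):
        return MultiPhaseResult(
            poc_p=poc_p, poc_oes=poc_oes, gated=False,
            confirm_n=None, confirm_p=None, success=False,
        )
    confirm_n, capped = estimate_confirm_n(
        poc_oes, sd_p, sd_t, design_p=config.design_p, n_cap=config.n_cap
    )
    confirm_n += confirm_n % 2  # even, for exact 1:1 arms
    confirm_p, _, _, _ = _phase(cohort, method, confirm_n, x, rng, config.tails)
    return MultiPhaseResult(
        poc_p=poc_p,
        poc_oes=poc_oes,
        gated=True,
        confirm_n=confirm_n,
        confirm_p=confirm_p,
        success=bool(confirm_p < config.alpha_confirm),
        capped=capped,
    )


def _phase(cohort, method, n, x, rng, tails):
    """One phase: sample, allocate, apply effect, test.  Returns
    (p, oes, sd_placebo, sd_treated)."""
    ids = sample_population(cohort, n, rng)
    alloc = method.allocate(cohort, ids, rng)
    g = cohort.gt[ids]
    mask_t = alloc.arm == ARM_T
    gp = g[~mask_t]
    gt_treated = apply_effect(g[mask_t], x)
    p = t_test(gp, gt_treated, tails=tails)
    oes = float(gp.mean() - gt_treated.mean())
    return p, oes, float(np.std(gp, ddof=1)), float(np.std(gt_treated, ddof=1))


def success_rate(
    cohort: Cohort,
    method: RandomizationMethod,
    x_grid: np.ndarray,
    n_reps: int = 2_000,
    config: PhaseConfig = PhaseConfig(),
    rng: RngLike = None,
) -> pd.DataFrame:
    """End-to-end success fraction (and gate pass fraction) per effect size."""
    if n_reps < 100:
        raise ValueError(f"n_reps must be >= 100, got {n_reps}")
    rng = as_rng(rng)
    rows = []
    for x in np.asarray(x_grid, dtype=float):
        gated = 0
        succ = 0
        capped = 0
        for child in rng.spawn(n_reps):
            res = run_multiphase(cohort, method, x, config, child)
            gated += res.gated
            succ += res.success
            capped += res.capped
        rows.append({
            "x": float(x),
            "success_rate": succ / n_reps,
            "gated_rate": gated / n_reps,
            "capped_rate": capped / n_reps,
        })
    return pd.DataFrame(rows)
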