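"""Single-trial simulation with an injected multiplicative treatment effect.

A simulated trial extracts participants, allocates them by a randomization
method, then suppresses the treatment arm's true CDR-SB changes by x%
(each value scaled by 1 - x/100 — the effect acts on the decline itself, so
the arm's variance shrinks by the squared factor).  A pooled-variance
two-sample t test on the arms yields the trial p value; the observed effect
size (OES) is the placebo-minus-treatment difference of post-effect means.

Because allocation bias adds to (or subtracts from) the injected effect,
p values scatter around the deterministic p value of a *perfect*
allocation, in which both arms carry exactly the population's mean and
variance.  Detection rates are therefore reported conditionally on the
pre-effect bias direction: replicates where the placebo arm was already
declining faster over-detect, the reverse under-detect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, RngLike, as_rng
from .randomize import ARM_T, RandomizationMethod, sample_population

__all__ = [
    "PLACEBO_WORSE",
    "TREATMENT_WORSE",
    "TrialResult",
    "DetectionRates",
    "apply_effect",
    "t_test",
    "perfect_allocation_p",
    "run_trial",
    "pvalue_summary",
    "detection_rates",
]

# Bias directions: "worse" = larger CDR-SB increase = faster decline.
PLACEBO_WORSE = "placebo_worse"
TREATMENT_WORSE = "treatment_worse"


def apply_effect(values: np.ndarray, x: float) -> np.ndarray:
    """Suppress true changes by x percent: each value times (1 - x/100)."""
    if not 0.0 <= x <= 100.0:
        raise ValueError(f"treatment effect x must be in [0, 100], got {x}")
    return np.asarray(values, dtype=float) * (1.0 - x / 100.0)


def t_test(
    group_p: np.ndarray,
    group_t: np.ndarray,
    tails: int = 2,
    welch: bool = False,
) -> float:
    """Two-sample t-test p value in the placebo-minus-treatment direction.

    Pooled-variance (Student) by default; ``welch=True`` for a sensitivity
    analysis with unequal variances.  ``tails=1`` tests the one-sided
    alternative "placebo declines more than treatment".  Degenerate zero
    variance: p = 1 with equal means, 0 (or 1 against the alternative's
    direction, one-tailed) otherwise.
    """
    a = np.asarray(group_p, dtype=float)
    b = np.asarray(group_t, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each arm needs >= 2 observations")
    if tails not in (1, 2):
        raise ValueError(f"tails must be 1 or 2, got {tails}")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        diff = a.mean() - b.mean()
        if diff == 0:
            return 1.0
        if tails == 2:
            return 0.0
        return 0.0 if diff > 0 else 1.0
    alternative = "greater" if tails == 1 else "two-sided"
    res = stats.ttest_ind(a, b, equal_var=not welch, alternative=alternative)
    return float(res.pvalue)


def perfect_allocation_p(
    mu: float, sigma: float, x: float, n: int, tails: int = 2
) -> float:
    """Deterministic p value of a perfectly allocated trial.

    Both arms (size n/2) carry the population moments; the treatment arm's
    are scaled by (1 - x/100).  t = x/100*mu / sqrt((sigma^2 +
    (1-x/100)^2*sigma^2) / (n/2)), df = n - 2.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if n < 4 or n % 2:
        raise ValueError(f"n must be even and >= 4, got {n}")
    if not 0.0 <= x <= 100.0:
        raise ValueError(f"treatment effect x must be in [0, 100], got {x}")
    f = 1.0 - x / 100.0
    se = np.sqrt((sigma**2 + (f * sigma) ** 2) / (n / 2))
    t = (mu - f * mu) / se
    df = n - 2
    if tails == 2:
        return float(2.0 * stats.t.sf(abs(t), df))
    return float(stats.t.sf(t, df))


@dataclass
class TrialResult:
    """Outcome of one simulated trial."""

    p_value: float
    mean_p: float
    mean_t: float
    pre_effect_bias: float
    bias_direction: str
    oes: float
    n_p: int
    n_t: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p value out of [0, 1]: {self.p_value}")


def run_trial(
    cohort: Cohort,
    method: RandomizationMethod,
    n: int,
    x: float,
    rng: RngLike = None,
    tails: int = 2,
    welch: bool = False,
) -> TrialResult:
    """Sample, allocate, inject the effect into the treatment arm, test.

    The pre-effect bias (and its direction) is recorded before the effect is
    applied; ties in the pre-effect means count as ``placebo_worse`` so the
    direction is deterministic on grid-valued outcomes.
    """
    rng = as_rng(rng)
    ids = sample_population(cohort, n, rng)
    alloc = method.allocate(cohort, ids, rng)
    g = cohort.gt[ids]
    mask_t = alloc.arm == ARM_T
    gp, gt_arm = g[~mask_t], g[mask_t]
    pre_bias = float(gp.mean() - gt_arm.mean())
    direction = PLACEBO_WORSE if pre_bias >= 0 else TREATMENT_WORSE
    gt_treated = apply_effect(gt_arm, x)
    p = t_test(gp, gt_treated, tails=tails, welch=welch)
    return TrialResult(
        p_value=p,
        mean_p=float(gp.mean()),
        mean_t=float(gt_treated.mean()),
        pre_effect_bias=pre_bias,
        bias_direction=direction,
        oes=float(gp.mean() - gt_treated.mean()),
        n_p=len(gp),
        n_t=len(gt_treated),
    )


def pvalue_summary(
    cohort: Cohort,
    method: RandomizationMethod,
    n: int,
    x_grid: np.ndarray,
    n_reps: int = 2_000,
    rng: RngLike = None,
    tails: int = 2,
) -> pd.DataFrame:
    """Median and quartiles of the trial p value per treatment effect."""
    if n_reps < 100:
        raise ValueError(f"n_reps must be >= 100, got {n_reps}")
    rng = as_rng(rng)
    rows = []
    for x in np.asarray(x_grid, dtype=float):
        ps = replicate_pvalues(cohort, method, n, x, n_reps, rng, tails=tails)[0]
        q25, med, q75 = np.quantile(ps, [0.25, 0.5, 0.75])
        rows.append({"x": float(x), "median": med, "q25": q25, "q75": q75})
    return pd.DataFrame(rows)


def replicate_pvalues(
    cohort: Cohort,
    method: RandomizationMethod,
    n: int,
    x: float,
    n_reps: int,
    rng: RngLike = None,
    tails: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate p values and pre-effect biases (the simulation kernel
    behind ``pvalue_summary`` and ``detection_rates``)."""
    rng = as_rng(rng)
    ps = np.empty(n_reps)
    pre = np.empty(n_reps)
    for r, child in enumerate(rng.spawn(n_reps)):
        res = run_trial(cohort, method, n, x, child, tails=tails)
        ps[r] = res.p_value
        pre[r] = res.pre_effect_bias
    return ps, pre


@dataclass
class DetectionRates:
    """Fraction of replicates with p < threshold, pooled and by direction.

    A direction with no replicates reports ``nan``.
    """

    pooled: float
    placebo_worse: float
    treatment_worse: float
    n_placebo_worse: int
    n_treatment_worse: int
    threshold: float
    x: float


def detection_rates(
    cohort: Cohort,
    method: RandomizationMethod,
    n: int,
    x: float,
    n_reps: int = 2_000,
    threshold: float = 0.05,
    rng: RngLike = None,
    tails: int = 2,
) -> DetectionRates:
    """Detection rates conditional on the pre-effect bias direction."""
    if n_reps < 100:
        raise ValueError(f"n_reps must be >= 100, got {n_reps}")
    ps, pre = replicate_pvalues(cohort, method, n, x, n_reps, rng, tails=tails)
    detected = ps < threshold
    worse = pre >= 0  # ties -> placebo_worse
    n_pw = int(worse.sum())
    n_tw = n_reps - n_pw
    return DetectionRates(
        pooled=float(detected.mean()),
        placebo_worse=float(detected[worse].mean()) if n_pw else float("nan"),
        treatment_worse=float(detected[~worse].mean()) if n_tw else float("nan"),
        n_placebo_worse=n_pw,
        n_treatment_worse=n_tw,
        threshold=threshold,
        x=x,
    )
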