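"""Synthetic trial cohorts with a grid-valued outcome and correlated indices.

The simulated population mirrors a prodromal-Alzheimer's trial cohort whose
end point is the 2-year change in CDR-SB (Clinical Dementia Rating — Sum of
Boxes).  Each participant carries

* ``gt_change`` — the actual ("ground truth") CDR-SB change, discrete on a
  0.5-point grid because CDR-SB itself moves in half-point steps;
* ``pred_change`` — a continuous prognostic index emulating a fitted
  regression model's prediction of that change, with a configurable
  population correlation to the truth;
* any number of auxiliary indices (age, biomarker levels, cognitive scores)
  each with its own marginal mean/SD and correlation to the truth.

All variables share a single latent Gaussian factor (the pre-rounding true
change), so an index's correlation with the truth is the only property that
matters for single-index stratification downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "IndexSpec",
    "CohortParams",
    "Participant",
    "Cohort",
    "generate_cohort",
    "filter_cohort",
    "round_to_grid",
    "as_rng",
]

RngLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


def as_rng(rng: RngLike) -> np.random.Generator:
    """Normalize a seed / SeedSequence / Generator into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def round_to_grid(values: np.ndarray, grid: float) -> np.ndarray:
    """Round to the nearest grid multiple, halves away from zero.

    ``np.round`` rounds halves to even, which would bias the discretized
    outcome at exact half-grid points; CDR-SB changes are symmetric about
    zero so halves are pushed outward instead.
    """
    if grid <= 0:
        raise ValueError(f"grid must be positive, got {grid}")
    scaled = np.asarray(values, dtype=float) / grid
    return np.copysign(np.floor(np.abs(scaled) + 0.5), scaled) * grid


@dataclass(frozen=True)
class IndexSpec:
    """Marginal description of one auxiliary index.

    ``correlation`` is the population Pearson correlation between the index
    and the latent (pre-rounding) true outcome change.
    """

    name: str
    correlation: float
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError(
                f"index {self.name!r}: correlation must be in [-1, 1], "
                f"got {self.correlation}"
            )
        if self.sd < 0:
            raise ValueError(f"index {self.name!r}: sd must be >= 0, got {self.sd}")
        if not self.name or self.name in ("id", "gt_change", "pred_change"):
            raise ValueError(f"illegal index name {self.name!r}")


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters of a synthetic cohort.

    Defaults reproduce the simulation sample used throughout this package:
    506 participants, true CDR-SB changes with mean 0.978 and SD 1.899 on a
    0.5 grid, and a prediction index correlated 0.601 with the truth.

    ``exact_moments`` matches the realized sample moments of the latent
    truth (and its correlation with each index) to the requested values
    exactly, in the style of ``MASS::mvrnorm(empirical=TRUE)``.  The cohort
    then *is* a population with the stated statistics rather than one random
    draw from it; see docs/methods.md for why this is the default.
    """

    n_participants: int = 506
    gt_mean: float = 0.978
    gt_sd: float = 1.899
    gt_grid: float = 0.5
    pred_correlation: float = 0.601
    index_specs: tuple[IndexSpec, ...] = ()
    seed: int = 0
    exact_moments: bool = True

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError(f"n_participants must be >= 2, got {self.n_participants}")
        if self.gt_sd < 0:
            raise ValueError(f"gt_sd must be >= 0, got {self.gt_sd}")
        if self.gt_grid <= 0:
            raise ValueError(f"gt_grid must be > 0, got {self.gt_grid}")
        if not -1.0 <= self.pred_correlation <= 1.0:
            raise ValueError(
                f"pred_correlation must be in [-1, 1], got {self.pred_correlation}"
            )
        specs = tuple(
            s if isinstance(s, IndexSpec) else IndexSpec(*s) for s in self.index_specs
        )
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate index names in {names}")
        object.__setattr__(self, "index_specs", specs)


@dataclass(frozen=True)
class Participant:
    id: int
    gt_change: float
    pred_change: float
    indices: Mapping[str, float]


@dataclass
class Cohort:
    """A participant table plus (optionally) the parameters that made it.

    ``table`` columns: ``id``, ``gt_change``, ``pred_change``, then one
    column per auxiliary index.  Ids are unique and contiguous from 0.
    """

    table: pd.DataFrame
    params: CohortParams | None = None

    RESERVED = ("id", "gt_change", "pred_change")

    def __post_init__(self) -> None:
        missing = [c for c in self.RESERVED if c not in self.table.columns]
        if missing:
            raise ValueError(f"cohort table missing columns {missing}")
        ids = self.table["id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("cohort ids must be contiguous from 0")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def gt(self) -> np.ndarray:
        return self.table["gt_change"].to_numpy()

    @property
    def pred(self) -> np.ndarray:
        return self.table["pred_change"].to_numpy()

    @property
    def index_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.RESERVED]

    def index_values(self, name: str) -> np.ndarray:
        """Values of a stratification index; ``pred_change``/``gt_change`` count."""
        if name not in self.table.columns or name == "id":
            raise KeyError(
                f"unknown index {name!r}; available: "
                f"{['gt_change', 'pred_change'] + self.index_names}"
            )
        return self.table[name].to_numpy()

    def participants(self) -> Iterator[Participant]:
        idx_names = self.index_names
        for row in self.table.itertuples(index=False):
            d = row._asdict()
            yield Participant(
                id=int(d["id"]),
                gt_change=float(d["gt_change"]),
                pred_change=float(d["pred_change"]),
                indices={k: float(d[k]) for k in idx_names},
            )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path_or_buf) -> None:
        """Write as UTF-8 CSV with '.' decimal separator (spec wire format)."""
        self.table.to_csv(path_or_buf, index=False)

    def to_csv_bytes(self) -> bytes:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue().encode("utf-8")

    @classmethod
    def from_csv(cls, path_or_buf) -> "Cohort":
        table = pd.read_csv(path_or_buf)
        table["id"] = table["id"].astype(int)
        return cls(table=table, params=None)


def _standardize(x: np.ndarray) -> np.ndarray:
    """Center and scale to sample mean 0, sample SD (ddof=1) exactly 1."""
    x = x - x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate draw: zero sample variance")
    return x / sd


def _orthogonal_noise(rng: np.random.Generator, z: np.ndarray, exact: bool) -> np.ndarray:
    """Unit-SD noise; if ``exact``, made exactly sample-orthogonal to z."""
    e = rng.standard_normal(z.size)
    if exact:
        e = e - z * (e @ z) / (z @ z)
        e = _standardize(e)
    return e


def generate_cohort(params: CohortParams) -> Cohort:
    """Draw a cohort from the single-latent-factor model.

    Construction (per participant i, latent z_i ~ N(0,1)):

    * latent truth  L = gt_mean + gt_sd * z
    * observed truth  gt_change = L rounded to gt_grid (halves away from 0)
    * prediction  pred = gt_mean + rho*|rho|*gt_sd*z + |rho|*gt_sd*sqrt(1-rho^2)*e,
      the calibrated-regression form: Var(pred) = rho^2 * gt_sd^2 and the
      regression of truth on prediction has unit slope, as a well-calibrated
      fitted predictor does.
    * each auxiliary index  v = mean + c*sd*z + sd*sqrt(1-c^2)*e_k, keeping
      its own marginal SD.

    Identical params (including seed) give a byte-identical cohort table.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    z = rng.standard_normal(p.n_participants)
    if p.exact_moments:
        z = _standardize(z)

    latent = p.gt_mean + p.gt_sd * z
    gt = round_to_grid(latent, p.gt_grid)

    rho = p.pred_correlation
    e = _orthogonal_noise(rng, z, p.exact_moments)
    pred = (
        p.gt_mean
        + rho * abs(rho) * p.gt_sd * z
        + abs(rho) * p.gt_sd * np.sqrt(1.0 - rho * rho) * e
    )

    data = {"id": np.arange(p.n_participants), "gt_change": gt, "pred_change": pred}
    for spec in p.index_specs:
        c = spec.correlation
        ek = _orthogonal_noise(rng, z, p.exact_moments)
        data[spec.name] = spec.mean + c * spec.sd * z + spec.sd * np.sqrt(1.0 - c * c) * ek

    return Cohort(table=pd.DataFrame(data), params=p)


Predicate = Union[str, Callable[[pd.DataFrame], Sequence[bool]]]


def filter_cohort(cohort: Cohort, predicate: Predicate) -> Cohort:
    """Sub-cohort of rows satisfying ``predicate``; ids renumbered from 0.

    ``predicate`` is either a pandas query string over the cohort's columns
    (e.g. ``"age >= 72"``) or a callable mapping the table to a boolean
    mask.  Referencing an unknown index raises ``KeyError``.  An empty
    result is allowed.
    """
    if isinstance(predicate, str):
        try:
            sub = cohort.table.query(predicate)
        except pd.errors.UndefinedVariableError as exc:
            raise KeyError(f"unknown index in predicate {predicate!r}: {exc}") from exc
    else:
        mask = np.asarray(predicate(cohort.table), dtype=bool)
        if mask.shape != (len(cohort),):
            raise ValueError(
                f"predicate mask has shape {mask.shape}, expected ({len(cohort)},)"
            )
        sub = cohort.table[mask]

    sub = sub.reset_index(drop=True).copy()
    sub["id"] = np.arange(len(sub))
    return Cohort(table=sub, params=None)
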