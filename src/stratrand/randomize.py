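"""Permuted-block randomization, with and without single-index stratification.

Allocation follows the classical permuted-block scheme with the smallest
block: a randomization table is a random sequence of two-label blocks, each
independently ``[P, T]`` or ``[T, P]`` with probability 1/2, consumed in
participant order.  Stratified randomization bins participants on one index
and runs an independent table per stratum, so each stratum's arm counts
differ by at most one and the index's distribution is balanced across arms.

Arms are encoded 0 = placebo ("P"), 1 = treatment ("T") throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cohort import Cohort, RngLike, as_rng

__all__ = [
    "ARM_P",
    "ARM_T",
    "ARM_LABELS",
    "RandomizationTable",
    "StrataSpec",
    "Allocation",
    "RandomizationMethod",
    "nonstratified",
    "stratified_on",
    "build_table",
    "sample_population",
    "assign_strata",
    "allocate_nonstratified",
    "allocate_stratified",
]

ARM_P: int = 0
ARM_T: int = 1
ARM_LABELS = np.array(["P", "T"])


@dataclass
class RandomizationTable:
    """A sequence of two-label permuted blocks with a consumption cursor.

    ``flips[k] == 0`` means block k is ``[P, T]``; 1 means ``[T, P]``.  The
    label at position i (0-based) is therefore ``flips[i // 2] XOR (i % 2)``:
    consuming an odd number of labels leaves the arms imbalanced by exactly
    one, an even number by zero.
    """

    flips: np.ndarray
    cursor: int = 0

    @property
    def n_blocks(self) -> int:
        return len(self.flips)

    @property
    def capacity(self) -> int:
        return 2 * self.n_blocks

    @property
    def remaining(self) -> int:
        return self.capacity - self.cursor

    def labels(self) -> np.ndarray:
        """The full label sequence (0=P, 1=T) of the table."""
        pos = np.arange(self.capacity)
        return (self.flips[pos // 2] ^ (pos & 1)).astype(np.uint8)

    def take(self, k: int) -> np.ndarray:
        """Consume and return the next ``k`` labels."""
        if k > self.remaining:
            raise ValueError(
                f"randomization table exhausted: need {k} labels, "
                f"{self.remaining} remain of {self.capacity}"
            )
        pos = np.arange(self.cursor, self.cursor + k)
        self.cursor += k
        return (self.flips[pos // 2] ^ (pos & 1)).astype(np.uint8)


def build_table(n_blocks: int, rng: RngLike = None) -> RandomizationTable:
    """A table of ``n_blocks`` independent uniform permuted blocks."""
    if n_blocks < 1:
        raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
    rng = as_rng(rng)
    return RandomizationTable(flips=rng.integers(0, 2, size=n_blocks, dtype=np.uint8))


def sample_population(cohort: Cohort, n: int, rng: RngLike = None) -> np.ndarray:
    """Randomly extract ``n`` participant ids in randomized order.

    Without replacement while the cohort suffices; with replacement
    (oversampling) when ``n`` exceeds the cohort size.
    """
    if n < 2:
        raise ValueError(f"trial sample size must be >= 2, got {n}")
    rng = as_rng(rng)
    if n <= cohort.n:
        return rng.permutation(cohort.n)[:n]
    return rng.integers(0, cohort.n, size=n)


def oversampling_sequence(cohort: Cohort, n: int, rng: RngLike = None) -> np.ndarray:
    """Extraction sequence whose every prefix of length <= cohort size is a
    without-replacement sample: a full permutation continued by
    with-replacement draws.  Used by the sequential SAE-curve simulation,
    where one running trial must pass through all sample sizes."""
    rng = as_rng(rng)
    if n <= cohort.n:
        return rng.permutation(cohort.n)[:n]
    extra = rng.integers(0, cohort.n, size=n - cohort.n)
    return np.concatenate([rng.permutation(cohort.n), extra])


@dataclass(frozen=True)
class StrataSpec:
    """Stratification subgroups for one index.

    Core strata are the half-open intervals
    ``[minimum + shift + k*interval, minimum + shift + (k+1)*interval)``;
    two boundary strata catch values below the (shifted) minimum and above
    the top core interval, so every finite value is allocable.  ``shift``
    offsets the stratum edges by half the outcome grid when the index is
    continuous, so grid-valued and continuous indices bin comparably.
    """

    index_name: str
    minimum: float
    maximum: float
    interval: float
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError(f"interval must be > 0, got {self.interval}")
        if not self.maximum > self.minimum:
            raise ValueError(
                f"maximum ({self.maximum}) must exceed minimum ({self.minimum})"
            )

    @property
    def n_core(self) -> int:
        return math.ceil((self.maximum - self.minimum) / self.interval)

    @property
    def n_strata(self) -> int:
        """Core strata plus the two boundary strata."""
        return self.n_core + 2

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        index_name: str,
        interval: float = 0.5,
        shift: float | None = None,
        grid: float = 0.5,
    ) -> "StrataSpec":
        """Default spec for an index: 1st/99th percentile bounds rounded
        outward to the grid; shift = grid/2 for continuous indices, 0 for
        indices already on the grid."""
        v = cohort.index_values(index_name)
        if shift is None:
            on_grid = np.allclose(np.round(v / grid) * grid, v, atol=1e-9)
            shift = 0.0 if on_grid else grid / 2.0
        lo = math.floor(np.quantile(v, 0.01) / grid) * grid
        hi = math.ceil(np.quantile(v, 0.99) / grid) * grid
        if hi <= lo:
            hi = lo + interval
        return cls(index_name=index_name, minimum=lo, maximum=hi,
                   interval=interval, shift=shift)


def assign_strata(values: np.ndarray, spec: StrataSpec) -> np.ndarray:
    """Map index values to integer stratum ids.

    Value v falls in stratum ``floor((v - (minimum + shift)) / interval)``,
    clipped into the boundary strata: -1 below the shifted minimum,
    ``spec.n_core`` above the top.  Half-open intervals make grid values
    unambiguous; ids are non-decreasing in v.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite stratification index value")
    raw = np.floor((v - (spec.minimum + spec.shift)) / spec.interval)
    return np.clip(raw, -1, spec.n_core).astype(np.int64)


@dataclass
class Allocation:
    """Arm assignment for one sampled trial population.

    ``ids[i]`` is the cohort id of the i-th sampled participant (ids may
    repeat under oversampling), ``arm[i]`` its arm (0=P, 1=T), ``stratum``
    its stratum id for stratified methods (None otherwise).
    """

    ids: np.ndarray
    arm: np.ndarray
    stratum: np.ndarray | None = None
    method_tag: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.arm):
            raise ValueError("ids and arm must have equal length")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def placebo_ids(self) -> np.ndarray:
        return self.ids[self.arm == ARM_P]

    @property
    def treatment_ids(self) -> np.ndarray:
        return self.ids[self.arm == ARM_T]

    @property
    def arm_labels(self) -> np.ndarray:
        return ARM_LABELS[self.arm]

    def counts(self) -> tuple[int, int]:
        n_t = int(self.arm.sum())
        return self.n - n_t, n_t


def allocate_nonstratified(
    ids: np.ndarray, table: RandomizationTable, method_tag: str = "nonstratified"
) -> Allocation:
    """Consume table labels in sample order; even n gives exact 1:1 arms."""
    ids = np.asarray(ids)
    return Allocation(ids=ids, arm=table.take(len(ids)), method_tag=method_tag)


def allocate_stratified(
    ids: np.ndarray,
    strata: np.ndarray,
    tables: Mapping[int, RandomizationTable],
    method_tag: str = "stratified",
) -> Allocation:
    """Block-randomize within each stratum from that stratum's own table.

    Participants are fed to their stratum's table in sample order, so an
    odd-sized stratum leaves its last participant on the first label of the
    next unused block.  Per-stratum arm counts therefore differ by at most
    one; the trial arms are the unions over strata.
    """
    ids = np.asarray(ids)
    strata = np.asarray(strata)
    if len(ids) != len(strata):
        raise ValueError("ids and strata must have equal length")
    arm = np.empty(len(ids), dtype=np.uint8)
    for sid in np.unique(strata):
        member_pos = np.flatnonzero(strata == sid)
        try:
            table = tables[int(sid)]
        except KeyError:
            raise KeyError(
                f"no randomization table for occupied stratum {int(sid)}"
            ) from None
        arm[member_pos] = table.take(len(member_pos))
    return Allocation(ids=ids, arm=arm, stratum=strata, method_tag=method_tag)


@dataclass(frozen=True)
class RandomizationMethod:
    """A named allocation procedure: non-stratified, or stratified on one index."""

    tag: str
    strata_spec: StrataSpec | None = None

    @property
    def stratified(self) -> bool:
        return self.strata_spec is not None

    def allocate(self, cohort: Cohort, ids: np.ndarray, rng: RngLike = None) -> Allocation:
        """Generate fresh randomization table(s) and allocate ``ids``.

        Tables are sized to the sample (ceil(n/2) blocks per table — e.g.
        250 blocks for a 500-participant non-stratified trial), regenerated
        per call as each simulated trial regenerates its tables.
        """
        rng = as_rng(rng)
        ids = np.asarray(ids)
        if not self.stratified:
            table = build_table(max(1, -(-len(ids) // 2)), rng)
            return allocate_nonstratified(ids, table, method_tag=self.tag)
        spec = self.strata_spec
        values = cohort.index_values(spec.index_name)[ids]
        strata = assign_strata(values, spec)
        tables = {}
        for sid, count in zip(*np.unique(strata, return_counts=True)):
            tables[int(sid)] = build_table(max(1, -(-int(count) // 2)), rng)
        return allocate_stratified(ids, strata, tables, method_tag=self.tag)


def nonstratified(tag: str = "nonstratified") -> RandomizationMethod:
    return RandomizationMethod(tag=tag)


def stratified_on(
    cohort: Cohort,
    index_name: str,
    interval: float = 0.5,
    shift: float | None = None,
    tag: str | None = None,
) -> RandomizationMethod:
    """Stratified method with the default cohort-derived stratum ranges."""
    spec = StrataSpec.from_cohort(cohort, index_name, interval=interval, shift=shift)
    return RandomizationMethod(tag=tag or f"stratified_{index_name}", strata_spec=spec)
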