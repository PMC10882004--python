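"""Permuted-block tables, sampling, stratum assignment, allocation balance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stratrand as sr
from stratrand.randomize import ARM_P, ARM_T


class TestRandomizationTable:
    def test_full_table_is_exactly_balanced(self):
        table = sr.build_table(250, rng=0)
        labels = table.labels()
        assert len(labels) == 500
        assert (labels == ARM_P).sum() == 250
        assert (labels == ARM_T).sum() == 250

    def test_single_block_is_a_permutation_of_both_arms(self):
        table = sr.build_table(1, rng=1)
        assert sorted(table.labels().tolist()) == [ARM_P, ARM_T]

    def test_prefix_imbalance_at_most_one(self):
        table = sr.build_table(50, rng=2)
        labels = table.labels()
        running = np.cumsum(np.where(labels == ARM_P, 1, -1))
        assert np.all(np.abs(running[1::2]) == 0)
        assert np.all(np.abs(running[0::2]) == 1)

    def test_first_label_frequency_is_fair(self):
        """Over 10,000 seeded tables the first label is P about half the
        time (exact binomial 3-sigma bound)."""
        root = np.random.default_rng(3)
        firsts = [sr.build_table(10, rng=r).labels()[0] for r in root.spawn(10_000)]
        freq = np.mean(np.array(firsts) == ARM_P)
        assert abs(freq - 0.5) < 3 * 0.5 / np.sqrt(10_000)

    def test_exhaustion_raises(self):
        table = sr.build_table(2, rng=4)
        table.take(3)
        with pytest.raises(ValueError, match="exhausted"):
            table.take(2)

    def test_zero_blocks_rejected(self):
        with pytest.raises(ValueError):
            sr.build_table(0)


class TestSamplePopulation:
    def test_full_extraction_is_a_permutation(self, default_cohort):
        ids = sr.sample_population(default_cohort, 506, rng=5)
        assert np.array_equal(np.sort(ids), np.arange(506))

    def test_subsample_is_without_replacement(self, default_cohort):
        ids = sr.sample_population(default_cohort, 500, rng=6)
        assert len(ids) == 500
        assert len(np.unique(ids)) == 500

    def test_oversampling_draws_with_replacement_uniformly(self, default_cohort):
        """n > cohort: duplicates appear and aggregate multiplicities are
        uniform (chi-square over 200 seeded draws of 1000)."""
        root = np.random.default_rng(7)
        counts = np.zeros(506)
        for child in root.spawn(200):
            ids = sr.sample_population(default_cohort, 1000, rng=child)
            assert len(ids) == 1000
            counts += np.bincount(ids, minlength=506)
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats_chi2_sf(chi2, 505) > 1e-4

    def test_too_small_sample_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            sr.sample_population(default_cohort, 1)


def stats_chi2_sf(x, df):
    from scipy import stats

    return stats.chi2.sf(x, df)


class TestAssignStrata:
    SPEC = sr.StrataSpec(
        index_name="pred_change", minimum=-2.0, maximum=6.0, interval=0.5, shift=0.25
    )

    def test_value_falls_in_stated_interval(self):
        # stratum edges at -1.75 + 0.5k; 0.30 lies in [0.25, 0.75)
        sid = sr.assign_strata(np.array([0.30]), self.SPEC)[0]
        low = self.SPEC.minimum + self.SPEC.shift + sid * self.SPEC.interval
        assert low == pytest.approx(0.25)
        assert low <= 0.30 < low + self.SPEC.interval

    def test_half_open_edges(self):
        ids = sr.assign_strata(np.array([0.2499, 0.25, 0.7499, 0.75]), self.SPEC)
        assert ids[0] == ids[1] - 1
        assert ids[1] == ids[2]
        assert ids[3] == ids[2] + 1

    def test_out_of_range_clamped_to_boundary_strata(self):
        ids = sr.assign_strata(np.array([-5.0, 1e6]), self.SPEC)
        assert ids[0] == -1
        assert ids[1] == self.SPEC.n_core

    def test_monotone_in_value(self):
        v = np.arange(-2.0, 6.0, 0.1)
        ids = sr.assign_strata(v, self.SPEC)
        assert np.all(np.diff(ids) >= 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            sr.assign_strata(np.array([np.nan]), self.SPEC)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"minimum": 0.0, "maximum": 0.0, "interval": 0.5},
            {"minimum": 1.0, "maximum": 0.0, "interval": 0.5},
            {"minimum": 0.0, "maximum": 1.0, "interval": 0.0},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sr.StrataSpec(index_name="x", **kwargs)

    def test_from_cohort_shift_defaults(self, default_cohort):
        cont = sr.StrataSpec.from_cohort(default_cohort, "pred_change")
        grid = sr.StrataSpec.from_cohort(default_cohort, "gt_change")
        assert cont.shift == 0.25  # continuous index: offset by half the grid
        assert grid.shift == 0.0  # grid-valued index: no offset needed


class TestAllocateNonstratified:
    def test_exact_one_to_one_ratio(self, default_cohort):
        ids = sr.sample_population(default_cohort, 500, rng=8)
        alloc = sr.allocate_nonstratified(ids, sr.build_table(250, rng=9))
        assert alloc.counts() == (250, 250)

    def test_two_participants_split(self):
        alloc = sr.allocate_nonstratified(
            np.array([3, 7]), sr.RandomizationTable(flips=np.array([0], dtype=np.uint8))
        )
        assert alloc.counts() == (1, 1)

    def test_marginal_assignment_probability_is_half(self, default_cohort):
        """Every sample position is placebo with probability 1/2 (1,000
        seeded allocations, 3-sigma binomial band)."""
        root = np.random.default_rng(10)
        n_p_first = 0
        for child in root.spawn(1000):
            ids = sr.sample_population(default_cohort, 50, rng=child)
            alloc = sr.allocate_nonstratified(ids, sr.build_table(25, rng=child))
            n_p_first += alloc.arm[0] == ARM_P
        assert abs(n_p_first / 1000 - 0.5) < 3 * 0.5 / np.sqrt(1000)


class TestAllocateStratified:
    def test_every_stratum_balanced_within_one(self, default_cohort):
        method = sr.stratified_on(default_cohort, "pred_change")
        ids = sr.sample_population(default_cohort, 500, rng=11)
        alloc = method.allocate(default_cohort, ids, rng=12)
        imbalance_sum = 0
        for sid in np.unique(alloc.stratum):
            arms = alloc.arm[alloc.stratum == sid]
            diff = abs(int((arms == ARM_P).sum()) - int((arms == ARM_T).sum()))
            assert diff <= 1
            imbalance_sum += diff
        n_p, n_t = alloc.counts()
        assert abs(n_p - n_t) <= imbalance_sum  # total bounded by occupied strata

    def test_single_stratum_degenerates_to_exact_split(self, default_cohort):
        wide = sr.RandomizationMethod(
            tag="one_stratum",
            strata_spec=sr.StrataSpec(
                index_name="pred_change", minimum=-100, maximum=100, interval=200
            ),
        )
        ids = sr.sample_population(default_cohort, 500, rng=13)
        alloc = wide.allocate(default_cohort, ids, rng=14)
        assert alloc.counts() == (250, 250)

    def test_stratum_of_two_splits(self):
        tables = {0: sr.build_table(1, rng=15)}
        alloc = sr.allocate_stratified(np.array([0, 1]), np.array([0, 0]), tables)
        assert alloc.counts() == (1, 1)

    def test_missing_table_raises(self):
        with pytest.raises(KeyError, match="stratum"):
            sr.allocate_stratified(np.array([0, 1]), np.array([0, 1]),
                                   {0: sr.build_table(1, rng=16)})

    def test_pipeline_determinism(self, default_cohort):
        method = sr.stratified_on(default_cohort, "pred_change")
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(17)
            ids = sr.sample_population(default_cohort, 500, rng)
            runs.append(method.allocate(default_cohort, ids, rng).arm)
        assert np.array_equal(runs[0], runs[1])


@given(n=st.integers(2, 60))
@settings(max_examples=40, derandomize=True)
def test_allocation_imbalance_bounded_for_any_size(default_cohort, n):
    """|#P - #T| <= 1 for non-stratified allocation of any sample size."""
    rng = np.random.default_rng(n)
    ids = sr.sample_population(default_cohort, n, rng)
    alloc = sr.nonstratified().allocate(default_cohort, ids, rng)
    n_p, n_t = alloc.counts()
    assert abs(n_p - n_t) == n % 2
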