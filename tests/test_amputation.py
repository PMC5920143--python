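"""Deletion plans: segmentation, integer allocation, amputation bookkeeping."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import amputebias as ab
from amputebias.amputation import MechanismSpec, school_mechanisms
from amputebias.errors import (
    DegenerateSegmentationError,
    InfeasiblePlanError,
    ParameterError,
)


class TestSegmentation:
    def test_1_to_100_under_linear_quantiles(self):
        # numpy linear-interpolation quantiles: P25 = 25.75, P75 = 75.25
        labels = ab.segment_by_percentiles(np.arange(1, 101))
        low = {v for v, l in zip(range(1, 101), labels) if l == "low"}
        mid = {v for v, l in zip(range(1, 101), labels) if l == "mid"}
        high = {v for v, l in zip(range(1, 101), labels) if l == "high"}
        assert low == set(range(1, 26))
        assert mid == set(range(26, 76))
        assert high == set(range(76, 101))

    def test_n4_has_one_low_one_high(self):
        labels = list(ab.segment_by_percentiles(np.array([1.0, 2.0, 3.0, 4.0])))
        assert labels == ["low", "mid", "mid", "high"]

    def test_constant_column_is_degenerate(self):
        with pytest.raises(DegenerateSegmentationError):
            ab.segment_by_percentiles(np.full(10, 7.0))

    def test_tie_at_cutpoint_goes_to_mid(self):
        # with values [0,1,1,2,3]: P25 = 1 exactly, P75 = 2 exactly
        vals = np.array([0.0, 1.0, 1.0, 2.0, 3.0])
        assert np.quantile(vals, 0.25) == 1.0 and np.quantile(vals, 0.75) == 2.0
        labels = list(ab.segment_by_percentiles(vals))
        assert labels == ["low", "mid", "mid", "mid", "high"]

    def test_too_few_values(self):
        with pytest.raises(ParameterError):
            ab.segment_by_percentiles(np.array([1.0, 2.0, 3.0]))


class TestAllocateCounts:
    @pytest.mark.parametrize(
        "total,weights,caps,expected",
        [
            (40, (0.8, 0.2), (100, 100), [32, 8]),
            (40, (0.75, 0.23, 0.02), (100, 100, 100), [30, 9, 1]),
            (5, (19 / 50, 18 / 50, 13 / 50), (19, 18, 13), [2, 2, 1]),
            (92, (0.75, 0.23, 0.02), (228, 458, 229), [69, 21, 2]),
            # capacity overflow: excess reassigned by the remaining weights
            (366, (0.75, 0.23, 0.02), (228, 458, 229), [228, 127, 11]),
        ],
    )
    def test_examples(self, total, weights, caps, expected):
        assert ab.allocate_counts(total, weights, caps).tolist() == expected

    def test_infeasible_total(self):
        with pytest.raises(InfeasiblePlanError):
            ab.allocate_counts(10, (0.5, 0.5), (4, 4))

    @given(
        total=st.integers(0, 60),
        weights=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=4),
    )
    def test_sums_and_bounds(self, total, weights):
        w = np.array(weights) / np.sum(weights)
        caps = [100] * len(w)
        counts = ab.allocate_counts(total, w, caps)
        assert counts.sum() == total
        assert np.all(counts >= 0)
        # largest-remainder allocations are within one of the exact shares
        assert np.all(np.abs(counts - total * w) < 1.0)

    def test_l1_optimality_against_brute_force(self):
        """Largest-remainder rounding minimizes the L1 distance to the exact
        shares among integer allocations (uncapped case), checked exhaustively."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = int(rng.integers(2, 4))
            w = rng.dirichlet(np.ones(k))
            total = int(rng.integers(1, 12))
            counts = ab.allocate_counts(total, w, [total] * k)
            best = min(
                sum(abs(c - total * wi) for c, wi in zip(combo, w))
                for combo in itertools.product(range(total + 1), repeat=k)
                if sum(combo) == total
            )
            got = sum(abs(c - total * wi) for c, wi in zip(counts, w))
            assert got == pytest.approx(best, abs=1e-9)


class TestInvertWeights:
    def test_reversal_examples(self):
        m = school_mechanisms(0.1)
        assert ab.invert_weights(m["MAR1a"]).stratum_weights == (0.20, 0.80)
        assert ab.invert_weights(m["MAR1b"]).stratum_weights == (0.02, 0.23, 0.75)

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5))
    def test_involution(self, raw):
        w = tuple(np.array(raw) / np.sum(raw))
        spec = MechanismSpec(
            "MAR_STRATA",
            0.2,
            stratum_variable="x",
            stratum_levels=tuple(f"s{i}" for i in range(len(w))),
            stratum_weights=w,
        )
        assert ab.invert_weights(ab.invert_weights(spec)).stratum_weights == w

    def test_mcar_cannot_invert(self):
        with pytest.raises(ParameterError):
            ab.invert_weights(MechanismSpec("MCAR", 0.2))


class TestAmpute:
    def test_mcar_counts_forced(self, school_cohort):
        mask = ab.ampute(school_cohort, MechanismSpec("MCAR", 0.10), seed=1)
        assert len(mask) == round(0.10 * 915) == 92
        small = school_cohort.copy()
        small.data = small.data.iloc[:100].copy()
        mask = ab.ampute(small, MechanismSpec("MCAR", 0.10), seed=1)
        assert len(mask) == 10

    def test_deterministic_and_nonmutating(self, school_cohort):
        before = school_cohort.data.copy()
        m1 = ab.ampute(school_cohort, school_mechanisms(0.2)["MAR1b"], seed=42)
        m2 = ab.ampute(school_cohort, school_mechanisms(0.2)["MAR1b"], seed=42)
        assert m1.deleted_subject_ids == m2.deleted_subject_ids
        assert school_cohort.data.equals(before)
        masked = ab.apply_mask(school_cohort, m1)
        assert school_cohort.data.equals(before)  # view is derived, source intact
        assert masked.data["post"].isna().sum() == len(m1)
        assert masked.data["pre"].isna().sum() == 0  # pre retained for deleted subjects

    def test_mar1b_composition_is_exact(self, school_cohort):
        mask = ab.ampute(school_cohort, school_mechanisms(0.1)["MAR1b"], seed=7)
        assert len(mask) == 92
        assert mask.realized_counts_per_stratum == {"low": 69, "mid": 21, "high": 2}

    def test_mar1a_composition_is_exact(self, school_cohort):
        mask = ab.ampute(school_cohort, school_mechanisms(0.1)["MAR1a"], seed=7)
        counts = mask.realized_counts_per_stratum
        n_boy = int((school_cohort.data.sex == "boy").sum())
        n_girl = 915 - n_boy
        expected = ab.allocate_counts(92, (0.8, 0.2), (n_boy, n_girl))
        assert [counts["boy"], counts["girl"]] == expected.tolist()

    def test_mar1b_40_percent_overflows_gracefully(self, school_cohort):
        mask = ab.ampute(school_cohort, school_mechanisms(0.4)["MAR1b"], seed=7)
        assert len(mask) == round(0.4 * 915)
        labels = ab.segment_by_percentiles(school_cohort.data["pre"].to_numpy())
        n_low = int((labels == "low").sum())
        assert mask.realized_counts_per_stratum["low"] == n_low  # stratum exhausted

    def test_infeasible_stratum_raises(self, prison_cohort):
        table, _ = prison_cohort
        spec = MechanismSpec(
            "MAR_STRATA",
            0.8,
            stratum_variable="group",
            stratum_levels=("CBT", "ACT", "CG"),
            stratum_weights=(1.0, 0.0, 0.0),
        )
        with pytest.raises(InfeasiblePlanError):
            ab.ampute(table, spec, seed=0)

    def test_mcar_deletion_frequencies_uniform(self):
        """Per-subject deletion frequency over 1000 seeds passes a chi-square
        goodness-of-fit test for uniformity at alpha = 0.01."""
        t = ab.generate_school_cohort(ab.SchoolCohortSpec(seed=5))
        small = t.copy()
        small.data = small.data.iloc[:50].copy()
        counts = np.zeros(50)
        spec = MechanismSpec("MCAR", 0.2)
        ids = small.data["subject_id"].to_numpy()
        pos = {i: k for k, i in enumerate(ids)}
        for s in range(1000):
            for i in ab.ampute(small, spec, seed=s).deleted_subject_ids:
                counts[pos[i]] += 1
        stat, p = stats.chisquare(counts)
        assert p > 0.01


class TestStudy2Mar:
    def test_10_percent_only_above_p75(self, prison_cohort):
        table, _ = prison_cohort
        mask = ab.ampute_study2_mar(table, 0.10, seed=3)
        assert len(mask) == 5
        years = table.data.set_index("subject_id")["years_dependence"]
        p75 = np.quantile(table.data["years_dependence"], 0.75)
        assert all(years[i] > p75 for i in mask.deleted_subject_ids)
        groups = table.data.set_index("subject_id")["group"]
        split = {g: sum(groups[i] == g for i in mask.deleted_subject_ids) for g in ("CBT", "ACT", "CG")}
        assert split == {"CBT": 2, "ACT": 2, "CG": 1}

    def test_30_percent_skews_to_long_dependence(self, prison_cohort):
        table, _ = prison_cohort
        mask = ab.ampute_study2_mar(table, 0.30, seed=3)
        assert len(mask) == 15
        counts = mask.realized_counts_per_stratum
        assert counts["high"] > counts["low"]

    def test_other_rates_rejected(self, prison_cohort):
        with pytest.raises(ParameterError):
            ab.ampute_study2_mar(prison_cohort[0], 0.20, seed=0)

    def test_non_monotone_weights_rejected(self, prison_cohort):
        with pytest.raises(ParameterError):
            ab.ampute_study2_mar(prison_cohort[0], 0.30, seed=0, weights_30=(0.6, 0.3, 0.1))
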