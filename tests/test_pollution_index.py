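"""Pollution index, grading, exceedance and category binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grainrisk.errors import EmptyGroupError, ParameterError
from grainrisk.pollution_index import (
    bin_cd_categories,
    bin_f_categories,
    compute_pi,
    exceedance_ratio,
    grade_pi,
    quintile_slices,
)

from conftest import make_record


class TestComputePi:
    @pytest.mark.parametrize("mean_c, si, expected", [
        (0.135, 0.1, 1.35),   # wheat mean over wheat limit
        (0.2, 0.2, 1.0),      # mean exactly at the limit
        (0.0, 0.5, 0.0),
    ])
    def test_values(self, mean_c, si, expected):
        assert compute_pi(mean_c, si) == pytest.approx(expected)

    def test_nonpositive_limit_rejected(self):
        with pytest.raises(ParameterError):
            compute_pi(0.1, 0.0)

    @given(c=st.floats(0, 10), scale=st.floats(0.1, 10))
    @settings(max_examples=50, derandomize=True)
    def test_linear_in_concentration(self, c, scale):
        assert compute_pi(scale * c, 0.2) == pytest.approx(scale * compute_pi(c, 0.2))


class TestGradePi:
    @pytest.mark.parametrize("pi, grade", [
        (0.408, "excellent"),
        (0.434, "excellent"),
        (0.7, "excellent"),          # band closed on its upper cut
        (0.7000001, "safe"),
        (1.0, "safe"),
        (1.352, "slight_pollution"),
        (2.0, "slight_pollution"),
        (2.0001, "pollution"),
    ])
    def test_grades(self, pi, grade):
        assert grade_pi(pi) == grade

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            grade_pi(-0.1)

    @given(a=st.floats(0, 5), b=st.floats(0, 5))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_and_total(self, a, b):
        order = ["excellent", "safe", "slight_pollution", "pollution"]
        ga, gb = grade_pi(a), grade_pi(b)
        if a <= b:
            assert order.index(ga) <= order.index(gb)


class TestExceedance:
    def test_by_count(self):
        recs = [make_record(sample_id=str(i), cd_mgkg=v)
                for i, v in enumerate([0.05, 0.15, 0.25])]
        assert exceedance_ratio(recs, "rice", 0.1) == pytest.approx(200 / 3)

    def test_all_below_is_zero(self):
        recs = [make_record(sample_id=str(i), cd_mgkg=v)
                for i, v in enumerate([0.01, 0.02])]
        assert exceedance_ratio(recs, "rice", 0.1) == 0.0

    def test_value_at_limit_is_compliant(self):
        recs = [make_record(cd_mgkg=0.1)]
        assert exceedance_ratio(recs, "rice", 0.1) == 0.0

    def test_empty_group_raises(self):
        with pytest.raises(EmptyGroupError):
            exceedance_ratio([], "rice", 0.1)

    def test_bounded_and_permutation_invariant(self, rng):
        vals = rng.uniform(0, 0.5, 200)
        recs = [make_record(sample_id=str(i), cd_mgkg=v)
                for i, v in enumerate(vals)]
        e = exceedance_ratio(recs, "rice", 0.2)
        assert 0 <= e <= 100
        perm = [recs[i] for i in rng.permutation(len(recs))]
        assert exceedance_ratio(perm, "rice", 0.2) == e

    def test_calibrated_binomial_rate(self, rng):
        # 1000 draws with P(exceed) = 0.45: observed rate within 3 sd of 45%
        vals = np.where(rng.random(1000) < 0.45, 0.3, 0.05)
        recs = [make_record(sample_id=str(i), cd_mgkg=v)
                for i, v in enumerate(vals)]
        assert exceedance_ratio(recs, "rice", 0.1) == pytest.approx(45, abs=5)


class TestCdBinning:
    def test_wheat_boundaries_and_assignment(self):
        recs = [make_record(sample_id=str(i), crop="wheat", cd_mgkg=v)
                for i, v in enumerate([0.02, 0.05, 0.08, 0.193, 0.4])]
        b = bin_cd_categories(recs, "wheat", si=0.1)
        assert b.boundaries == pytest.approx((0.035, 0.07, 0.1, 0.2))
        assert [c.n for c in b.per_category] == [1, 1, 1, 1, 1]
        assert b.per_category[3].obs_max == 0.193  # 0.193 falls in category 4

    def test_corn_cut_is_right_closed(self):
        # a value exactly at a cut stays in the lower category
        recs = [make_record(sample_id=str(i), crop="corn", cd_mgkg=v)
                for i, v in enumerate([0.069, 0.070, 0.0701])]
        b = bin_cd_categories(recs, "corn", si=0.1)
        assert [c.n for c in b.per_category] == [0, 2, 1, 0, 0]

    def test_degenerate_single_bin(self):
        recs = [make_record(sample_id=str(i), cd_mgkg=0.05)
                for i in range(7)]  # all at 0.5 * si
        b = bin_cd_categories(recs, "rice", si=0.1)
        assert [c.n for c in b.per_category] == [0, 7, 0, 0, 0]
        assert b.per_category[0].obs_min is None  # empty bin: no range

    def test_bins_partition_sample(self, rng):
        vals = rng.uniform(0, 0.6, 113)
        recs = [make_record(sample_id=str(i), cd_mgkg=v)
                for i, v in enumerate(vals)]
        b = bin_cd_categories(recs, "rice", si=0.2)
        assert sum(c.n for c in b.per_category) == 113


class TestFBinning:
    def test_even_split(self):
        recs = [make_record(sample_id=str(i), f_mgkg=float(v))
                for i, v in enumerate(range(1, 11))]
        b = bin_f_categories(recs, "rice")
        assert [c.n for c in b.per_category] == [2, 2, 2, 2, 2]
        assert b.per_category[0].obs_max == 2.0

    def test_sizes_differ_by_at_most_one(self, rng):
        recs = [make_record(sample_id=str(i), f_mgkg=v)
                for i, v in enumerate(rng.uniform(0.8, 5.2, 113))]
        sizes = [c.n for c in bin_f_categories(recs, "rice").per_category]
        assert sum(sizes) == 113
        assert max(sizes) - min(sizes) <= 1

    def test_edges_match_sort_and_slice_oracle(self, rng):
        vals = rng.uniform(0, 10, 20)
        recs = [make_record(sample_id=str(i), f_mgkg=v)
                for i, v in enumerate(vals)]
        b = bin_f_categories(recs, "rice")
        srt = np.sort(vals)
        # oracle: five consecutive slices of four sorted values each
        assert b.boundaries == pytest.approx((srt[3], srt[7], srt[11], srt[15]))
        for k, c in enumerate(b.per_category):
            chunk = srt[4 * k: 4 * (k + 1)]
            assert c.n == 4
            assert (c.obs_min, c.obs_max) == (chunk[0], chunk[-1])
            assert c.mean == pytest.approx(chunk.mean())
            assert c.median == pytest.approx(np.median(chunk))

    def test_too_few_records_raises(self):
        recs = [make_record(sample_id=str(i), f_mgkg=float(i)) for i in range(4)]
        with pytest.raises(EmptyGroupError):
            bin_f_categories(recs, "rice")

    def test_quintile_slices_partition(self):
        for n in (5, 20, 102, 113, 119):
            slices = quintile_slices(n)
            assert slices[0][0] == 0 and slices[-1][1] == n
            assert all(a2 == b1 for (_, b1), (a2, _) in zip(slices, slices[1:]))
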