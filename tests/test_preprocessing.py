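"""Outlier screening, exclusions, averaging, transforms, selectivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcsm.data import LongitudinalTable
from lcsm.preprocessing import (
    ExclusionSpec,
    OutlierPolicy,
    apply_exclusions,
    hemispheric_average,
    mad_flags,
    prepare_model_inputs,
    selectivity_index,
)


class TestMadFlags:
    def test_hand_enumerated_upper_flag(self):
        # median 3, MAD 1 -> threshold 3 + 3 * 1.4826 = 7.4478
        flags = mad_flags(
            [1, 2, 3, 4, 100], OutlierPolicy(k_mads=3, side="upper")
        )
        assert flags.tolist() == [False, False, False, False, True]

    def test_all_equal_values_not_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            flags = mad_flags([5.0, 5.0, 5.0, 5.0])
        assert not flags.any()

    def test_missing_never_flagged(self):
        flags = mad_flags([1, 2, np.nan, 3, 1000])
        assert not flags[2]
        assert flags[4]

    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=5, max_size=30,
        ),
        st.floats(min_value=0.5, max_value=5.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_two_sided_flags_invariant_under_reflection(self, values, k):
        values = np.asarray(values)
        if np.median(np.abs(values - np.median(values))) == 0:
            return  # degenerate-scale branch warns; covered above
        policy = OutlierPolicy(k_mads=k)
        med = np.median(values)
        assert np.array_equal(
            mad_flags(values, policy), mad_flags(2 * med - values, policy)
        )

    def test_scale_equivariance_of_two_sided_flags(self):
        # the x100 and sign-flip transforms commute with MAD screening
        rng = np.random.default_rng(0)
        x = rng.normal(0.4, 0.05, 60)
        x[0] = 0.9
        policy = OutlierPolicy()
        base = mad_flags(x, policy)
        assert np.array_equal(base, mad_flags(100 * x, policy))
        assert np.array_equal(base, mad_flags(-x, policy))


@pytest.fixture
def three_row_table() -> LongitudinalTable:
    return LongitudinalTable(
        pd.DataFrame(
            {
                "speed_a_t0": [10.0, 11.0, 12.0],
                "speed_a_t1": [10.5, 11.5, 12.5],
                "fa_x_t0": [0.40, 0.41, 0.42],
                "fa_x_t1": [0.39, 0.40, 0.41],
                "fa_y_t0": [0.30, 0.31, 0.32],
                "fa_y_t1": [0.29, 0.30, 0.31],
                "hm_t0": [0.2, 0.21, 0.19],
                "hm_t1": [0.2, 5.0, 0.22],
            }
        )
    )


class TestApplyExclusions:
    def test_no_flags_leaves_table_unchanged(self, three_row_table):
        spec = ExclusionSpec(per_variable={"speed_a": OutlierPolicy()})
        out, log = apply_exclusions(three_row_table, spec)
        pd.testing.assert_frame_equal(out.df, three_row_table.df)
        assert log.removed == {"speed_a": 0}

    def test_head_motion_flag_blanks_fa_cells_same_occasion(self, three_row_table):
        spec = ExclusionSpec(head_motion=("hm", ("fa_x", "fa_y")))
        out, log = apply_exclusions(three_row_table, spec)
        # participant 1 at occasion 1 loses both tract values, nothing else
        assert np.isnan(out.df.loc[1, "fa_x_t1"])
        assert np.isnan(out.df.loc[1, "fa_y_t1"])
        assert out.df.loc[1, "fa_x_t0"] == 0.41
        assert out.df.loc[1, "speed_a_t1"] == 11.5
        assert log.removed["hm->dependents"] == 2

    def test_removal_counts_match_planted_extremes(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "v_t0": rng.uniform(-1, 1, size=200),
                "v_t1": rng.uniform(-1, 1, size=200),
            }
        )
        df.loc[[3, 10, 55], "v_t0"] = 40.0  # planted outliers
        spec = ExclusionSpec(per_variable={"v": OutlierPolicy()})
        out, log = apply_exclusions(df, spec)
        assert log.removed["v"] == 3
        assert log.total == 3
        assert out.df["v_t0"].isna().sum() == 3

    def test_unknown_variable_rejected(self, three_row_table):
        spec = ExclusionSpec(per_variable={"nope": OutlierPolicy()})
        with pytest.raises(KeyError):
            apply_exclusions(three_row_table, spec)


class TestHemisphericAverage:
    def test_equal_voxels_is_arithmetic_mean(self):
        assert hemispheric_average(0.4, 0.5, 200, 200) == pytest.approx(0.45)

    def test_voxel_weighted_example(self):
        assert hemispheric_average(0.40, 0.50, 300, 100) == pytest.approx(0.425)

    def test_one_side_missing_returns_other(self):
        assert hemispheric_average(np.nan, 0.5, 0, 100) == pytest.approx(0.5)
        assert np.isnan(hemispheric_average(np.nan, np.nan, 0, 0))

    @given(
        st.floats(min_value=0.1, max_value=0.9),
        st.floats(min_value=0.1, max_value=0.9),
        st.integers(min_value=1, max_value=2000),
        st.integers(min_value=1, max_value=2000),
    )
    @settings(max_examples=50, deadline=None)
    def test_result_between_sides(self, L, R, vL, vR):
        out = float(hemispheric_average(L, R, vL, vR))
        assert min(L, R) - 1e-12 <= out <= max(L, R) + 1e-12

    def test_nonpositive_voxels_rejected(self):
        with pytest.raises(ValueError):
            hemispheric_average(0.4, 0.5, 0, 100)


class TestPrepareModelInputs:
    def test_all_transforms(self):
        df = pd.DataFrame(
            {
                "fa_slf_t0": [0.35796],
                "speed_tmta_t0": [40.0],
                "age_base": [70.0],
                "education": [2.0],
                "gender": [1.0],
                "hm_t0": [0.24],
            }
        )
        out = prepare_model_inputs(
            df, fa_variables=("fa_slf",), reverse_variables=("speed_tmta",)
        ).df
        assert out.loc[0, "fa_slf_t0"] == pytest.approx(35.796)
        assert out.loc[0, "speed_tmta_t0"] == pytest.approx(-40.0)
        assert out.loc[0, "age_base"] == 0.0
        assert out.loc[0, "education"] == 0.0
        # gender and head motion untouched
        assert out.loc[0, "gender"] == 1.0
        assert out.loc[0, "hm_t0"] == 0.24

    def test_screening_commutes_with_scaling(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"fa_q_t0": rng.normal(0.4, 0.02, 100)})
        df.loc[7, "fa_q_t0"] = 0.9
        spec = ExclusionSpec(per_variable={"fa_q": OutlierPolicy()})
        first_screen, log1 = apply_exclusions(df, spec)
        a = prepare_model_inputs(first_screen, fa_variables=("fa_q",)).df
        scaled = prepare_model_inputs(df, fa_variables=("fa_q",))
        b, log2 = apply_exclusions(scaled, spec)
        assert log1.removed == log2.removed
        pd.testing.assert_frame_equal(a, b.df)


class TestSelectivityIndex:
    @pytest.mark.parametrize(
        "base_mean, base_sd, follow_mean, expected",
        [
            (70.84, 5.08, 70.15, -0.14),  # baseline age
            (2.23, 0.86, 2.29, 0.07),  # education
            (0.24, 0.15, 0.26, 0.13),  # head motion
        ],
    )
    def test_cohort_table_values(self, base_mean, base_sd, follow_mean, expected):
        assert round(selectivity_index(base_mean, base_sd, follow_mean), 2) == expected

    def test_equal_means_give_zero(self):
        assert selectivity_index(10.0, 2.0, 10.0) == 0.0

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            selectivity_index(10.0, 0.0, 11.0)

    @given(
        st.floats(min_value=-100, max_value=100),
        st.floats(min_value=0.1, max_value=50),
        st.floats(min_value=-100, max_value=100),
    )
    @settings(max_examples=40, deadline=None)
    def test_sign_tracks_direction_of_difference(self, m0, sd, m1):
        s = selectivity_index(m0, sd, m1)
        assert np.sign(s) == np.sign(m1 - m0)
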