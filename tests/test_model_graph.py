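"""Model-builder structure: df accounting, edits, serialization."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcsm.builders import (
    BuilderConfig,
    CouplingSpec,
    build_bivariate_lcs,
    build_univariate_lcs,
)
from lcsm.model import PathModel, edit_parameters, fix, free

from conftest import SPEED_INDICATORS, symbolic_df_count


@pytest.fixture(scope="module")
def speed_model(speed_config):
    return build_univariate_lcs(speed_config)


@pytest.fixture(scope="module")
def tract_model(tract_config):
    return build_univariate_lcs(tract_config)


class TestPrintedDegreesOfFreedom:
    """The builders reproduce the published model sizes exactly."""

    def test_speed_strong_invariance(self, speed_model):
        free_k, moments, df = speed_model.count_df()
        assert speed_model.n_observed == 19
        assert moments == 209
        assert df == 143

    def test_speed_with_retest_mean(self, speed_config):
        model = build_univariate_lcs(
            dataclasses.replace(speed_config, retest="free_mean")
        )
        assert model.count_df()[2] == 142

    def test_single_tract_with_head_motion(self, tract_model):
        assert tract_model.n_observed == 11
        assert tract_model.count_df()[2] == 26

    @pytest.mark.parametrize(
        "coupling, df_expected",
        [
            (None, 292),
            (CouplingSpec(lag_years=2, direction="a_to_b"), 291),
            (CouplingSpec(lag_years=2, direction="b_to_a"), 291),
            (CouplingSpec(lag_years=2, direction="bidirectional"), 290),
            (CouplingSpec(lag_years=1, direction="bidirectional"), 290),
        ],
    )
    def test_bivariate_series(self, speed_config, tract_config, coupling, df_expected):
        speed_retest = dataclasses.replace(speed_config, retest="free_mean")
        model = build_bivariate_lcs(tract_config, speed_retest, coupling)
        assert model.n_observed == 27
        assert model.count_df()[2] == df_expected

    def test_coupling_label_count_drives_df(self, speed_config, tract_config):
        # adding k equal-over-time coupling labels costs exactly k df
        speed_retest = dataclasses.replace(speed_config, retest="free_mean")
        base = build_bivariate_lcs(tract_config, speed_retest, None)
        uni = build_bivariate_lcs(
            tract_config, speed_retest, CouplingSpec(2, "a_to_b")
        )
        full = build_bivariate_lcs(
            tract_config, speed_retest, CouplingSpec(2, "bidirectional")
        )
        assert base.count_df()[0] + 1 == uni.count_df()[0]
        assert base.count_df()[0] + 2 == full.count_df()[0]


class TestSymbolicCounterOracle:
    """count_df agrees with independent enumeration of the JSON export."""

    def test_builder_models(self, speed_config, tract_config, small_lcs_config):
        speed_retest = dataclasses.replace(speed_config, retest="free_mean")
        models = [
            build_univariate_lcs(speed_config),
            build_univariate_lcs(tract_config),
            build_univariate_lcs(small_lcs_config),
            build_bivariate_lcs(tract_config, speed_retest, CouplingSpec(2)),
        ]
        for m in models:
            assert m.count_df() == symbolic_df_count(m)

    def test_minimal_two_occasion_model(self):
        cfg = BuilderConfig(
            domain="m", indicators=("y",), occasions=(0, 1), phantom=(),
            covariates=(),
        )
        model = build_univariate_lcs(cfg)
        assert model.count_df() == symbolic_df_count(model)
        # 2 observed: 3 covariances + 2 means = 5 moments
        assert model.count_df()[1] == 5

    @given(
        n_ind=st.integers(min_value=3, max_value=5),
        level=st.sampled_from(["configural", "weak", "strong"]),
        retest=st.sampled_from(["none", "free_mean"]),
    )
    @settings(max_examples=12, deadline=None)
    def test_randomized_configs(self, n_ind, level, retest):
        cfg = BuilderConfig(
            domain="x",
            indicators=tuple(f"v{i}" for i in range(n_ind)),
            invariance_level=level,
            retest=retest,
            covariates=("age_base",),
        )
        model = build_univariate_lcs(cfg)
        assert model.count_df() == symbolic_df_count(model)


class TestPhantomOccasion:
    def test_contributes_no_observed_moments(self):
        with_phantom = build_univariate_lcs(
            BuilderConfig(
                domain="g", indicators=("y",), occasions=(0, 1, 2, 3, 4),
                phantom=(3,), covariates=(),
            )
        )
        without = build_univariate_lcs(
            BuilderConfig(
                domain="g", indicators=("y",), occasions=(0, 1, 2, 4),
                phantom=(), covariates=(),
            )
        )
        assert with_phantom.count_df()[1] == without.count_df()[1]
        assert with_phantom.n_observed == without.n_observed
        # the phantom adds latent structure only
        assert with_phantom.n_variables == without.n_variables + 2

    def test_phantom_must_be_on_grid(self):
        with pytest.raises(ValueError):
            BuilderConfig(
                domain="g", indicators=("y",), occasions=(0, 1, 2), phantom=(3,)
            )


class TestEdits:
    def test_fix_slope_variance_gains_one_df(self, tract_model):
        free0, _, df0 = tract_model.count_df()
        edited = edit_parameters(tract_model, [("var_S:slf", fix(0.0))])
        free1, _, df1 = edited.count_df()
        assert (free1, df1) == (free0 - 1, df0 + 1)

    def test_free_constrained_intercept_at_three_occasions(self, speed_model):
        free0 = speed_model.count_df()[0]
        cells = [
            speed_model.by_name("M", f"speed_lps14_t{t}") for t in (1, 2, 4)
        ]
        edited = edit_parameters(speed_model, [(c, free()) for c in cells])
        assert edited.count_df()[0] == free0 + 3

    def test_free_then_fix_roundtrip(self, speed_model):
        df0 = speed_model.count_df()[2]
        cell = speed_model.by_name("M", "d_ps_t1")
        freed = edit_parameters(speed_model, [(cell, free())])
        assert freed.count_df()[2] == df0 - 1
        back = edit_parameters(freed, [(cell, fix(0.0))])
        assert back.count_df()[2] == df0

    def test_fix_conflicting_fixed_cell_rejected(self, speed_model):
        cell = speed_model.by_name("A", "eta_ps_t1", "eta_ps_t0")  # fixed to 1
        with pytest.raises(ValueError, match="already fixed"):
            edit_parameters(speed_model, [(cell, fix(0.5))])

    def test_unknown_label_rejected(self, speed_model):
        with pytest.raises(KeyError):
            edit_parameters(speed_model, [("no_such_label", fix(0.0))])


class TestStructure:
    def test_undirected_matrix_symmetric(self, speed_model):
        n = speed_model.n_variables
        for i in range(n):
            for j in range(n):
                assert speed_model.S[i, j] == speed_model.S[j, i]

    def test_latent_change_structure_acyclic(self, speed_model):
        speed_model.validate()

    def test_cycle_detected(self):
        A = np.array([[0.0, "a"], ["b", 0.0]], dtype=object)
        S = np.array([[1.0, 0.0], [0.0, 1.0]], dtype=object)
        M = np.array([0.0, 0.0], dtype=object)
        model = PathModel(["x", "y"], 2, A, S, M)
        with pytest.raises(ValueError, match="cycle"):
            model.validate()

    def test_json_roundtrip(self, speed_model):
        clone = PathModel.from_json(speed_model.to_json())
        assert clone.variable_names == speed_model.variable_names
        assert clone.count_df() == speed_model.count_df()
        assert clone.constraint_map() == speed_model.constraint_map()

    def test_summary_reports_df(self, tract_model):
        text = tract_model.summary()
        assert "df: 26" in text
        assert "I_slf" in text


class TestBuilderErrors:
    def test_two_indicators_above_configural_rejected(self):
        with pytest.raises(ValueError, match="3 indicators"):
            BuilderConfig(domain="x", indicators=("a", "b"))

    def test_two_indicators_configural_allowed(self):
        cfg = BuilderConfig(
            domain="x", indicators=("a", "b"), invariance_level="configural"
        )
        assert build_univariate_lcs(cfg).count_df() == symbolic_df_count(
            build_univariate_lcs(cfg)
        )

    def test_retest_on_first_order_warns(self):
        with pytest.warns(UserWarning, match="retest"):
            BuilderConfig(
                domain="x", indicators=("y",), retest="free_mean", covariates=()
            )

    def test_mismatched_grids_rejected(self, speed_config):
        other = BuilderConfig(
            domain="fa", indicators=("fa_x",), occasions=(0, 1, 2), phantom=(),
        )
        with pytest.raises(ValueError, match="occasion grid"):
            build_bivariate_lcs(other, speed_config)

    def test_lag_longer_than_grid_rejected(self, speed_config, tract_config):
        speed_retest = dataclasses.replace(speed_config, retest="free_mean")
        with pytest.raises(ValueError, match="no coupling path"):
            build_bivariate_lcs(
                tract_config, speed_retest, CouplingSpec(lag_years=4)
            )


class TestCouplingPaths:
    @pytest.mark.parametrize("lag, n_paths", [(1, 3), (2, 2), (3, 1)])
    def test_paths_per_direction(self, speed_config, tract_config, lag, n_paths):
        speed_retest = dataclasses.replace(speed_config, retest="free_mean")
        model = build_bivariate_lcs(
            tract_config, speed_retest, CouplingSpec(lag, "a_to_b")
        )
        label = "gamma:slf->ps"
        assert len(model.constraint_map()[label]) == n_paths
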