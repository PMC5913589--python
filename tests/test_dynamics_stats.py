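"""Time-series derivatives, rolling-onset detection and group statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from droughtfeat.dynamics_stats import (
    FeatureSeries,
    anova_oneway,
    detect_rolling_onset,
    feature_change,
    first_derivative,
    pearson_r,
)
from droughtfeat.features_pipeline import DroughtFeatures


def _series(par, tbr=None, tcr=None, gpar=None, timepoints=None):
    n = len(par)
    return FeatureSeries(
        plant_id="p",
        timepoints=np.arange(1, n + 1) if timepoints is None else np.asarray(timepoints),
        values={
            "par": np.asarray(par, dtype=float),
            "tbr": np.asarray(tbr if tbr is not None else [0.5] * n, dtype=float),
            "tcr": np.asarray(tcr if tcr is not None else [0.6] * n, dtype=float),
            "gpar": np.asarray(gpar if gpar is not None else [0.9] * n, dtype=float),
        },
    )


def _features(gpar=0.9, tbr=0.5, par=0.3, tcr=0.6):
    return DroughtFeatures(gpar=gpar, tbr=tbr, par=par, tcr=tcr)


class TestFeatureChange:
    def test_after_minus_before(self):
        delta = feature_change(_features(par=0.30), _features(par=0.45))
        assert delta["par"] == pytest.approx(0.15)
        assert delta["gpar"] == 0.0

    def test_identical_features_give_zero_deltas(self):
        assert all(v == 0.0 for v in feature_change(_features(), _features()).values())

    def test_senescence_delta_sign(self):
        delta = feature_change(_features(gpar=0.95), _features(gpar=0.60))
        assert delta["gpar"] == pytest.approx(-0.35)

    def test_missing_side_gives_nan(self):
        assert all(math.isnan(v) for v in feature_change(None, _features()).values())


class TestFirstDerivative:
    def test_pairwise_differences(self):
        s = _series([1.0, 1.0, 2.0, 4.0])
        assert first_derivative(s, "par").tolist() == [0.0, 1.0, 2.0]

    def test_constant_series_is_all_zero(self):
        assert np.all(first_derivative(_series([0.4] * 6), "par") == 0.0)

    def test_matches_loop_oracle_on_random_series(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        d = first_derivative(_series(x), "par")
        expected = [x[i] - x[i - 1] for i in range(1, len(x))]
        assert np.allclose(d, expected)

    def test_gap_in_timepoints_yields_missing(self):
        s = _series([1.0, 2.0, 5.0], timepoints=[1, 2, 5])
        d = first_derivative(s, "par")
        assert d[0] == 1.0 and math.isnan(d[1])

    def test_missing_value_propagates(self):
        d = first_derivative(_series([1.0, math.nan, 3.0]), "par")
        assert math.isnan(d[0]) and math.isnan(d[1])

    def test_single_point_gives_empty(self):
        assert first_derivative(_series([1.0]), "par").size == 0

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=20))
    def test_derivative_of_cumsum_recovers_increments(self, increments):
        cum = np.concatenate([[0.0], np.cumsum(increments)])
        d = first_derivative(_series(cum), "par")
        assert np.allclose(d, increments, atol=1e-9)


class TestOnsetDetection:
    def test_constructed_par_jump_at_day_six(self):
        par = [0.30, 0.30, 0.31, 0.30, 0.31, 0.45, 0.50]
        tbr = [0.50, 0.50, 0.49, 0.50, 0.49, 0.35, 0.30]
        tcr = [0.60, 0.60, 0.59, 0.60, 0.59, 0.45, 0.40]
        report = detect_rolling_onset(_series(par, tbr, tcr))
        assert report.onset_index == 6
        assert report.per_descriptor_votes == {"par": 6, "tbr": 6, "tcr": 6}
        assert report.magnitude == pytest.approx(0.14)

    def test_flat_series_yields_no_onset(self):
        report = detect_rolling_onset(_series([0.3] * 5, [0.5] * 5, [0.6] * 5))
        assert report.onset_index is None

    def test_three_way_tie_falls_to_par_candidate(self):
        par = [0.30, 0.50, 0.31, 0.30, 0.30]  # PAR peak at day 2
        tbr = [0.50, 0.50, 0.30, 0.50, 0.50]  # TBR valley at day 3
        tcr = [0.60, 0.60, 0.60, 0.40, 0.60]  # TCR valley at day 4
        report = detect_rolling_onset(_series(par, tbr, tcr))
        assert report.per_descriptor_votes == {"par": 2, "tbr": 3, "tcr": 4}
        assert report.onset_index == 2

    def test_majority_beats_par(self):
        par = [0.30, 0.50, 0.31, 0.30, 0.30]
        tbr = [0.50, 0.50, 0.50, 0.30, 0.50]
        tcr = [0.60, 0.60, 0.60, 0.40, 0.60]
        assert detect_rolling_onset(_series(par, tbr, tcr)).onset_index == 4

    def test_invariant_to_constant_offset(self):
        par = [0.30, 0.30, 0.31, 0.30, 0.31, 0.45, 0.50]
        base = detect_rolling_onset(_series(par))
        shifted = detect_rolling_onset(_series([v + 5.0 for v in par]))
        assert base.onset_index == shifted.onset_index

    def test_gpar_is_excluded_from_voting(self):
        par = [0.30, 0.30, 0.45, 0.46, 0.46]
        gpar = [0.9, 0.9, 0.9, 0.9, 0.1]  # huge senescence drop at day 5
        assert detect_rolling_onset(_series(par, gpar=gpar)).onset_index == 3

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_rolling_onset(_series([0.3, 0.4]))


class TestAnova:
    def test_hand_computed_two_group_case(self):
        res = anova_oneway([[1, 2, 3], [4, 5, 6]])
        assert res.F == pytest.approx(13.5, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p == pytest.approx(sps.f.sf(13.5, 1, 4))

    def test_identical_groups_give_f_zero_p_one(self):
        res = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert res.F == 0.0 and res.p == 1.0

    def test_matches_scipy_f_oneway_on_random_groups(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(loc=m, size=9) for m in (0.0, 0.4, 1.1)]
        res = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    @given(
        st.floats(-50, 50),
        st.floats(0.1, 20),
    )
    def test_f_invariant_to_shift_and_scale(self, shift, scale):
        groups = [[1.0, 2.0, 4.0], [3.0, 5.0, 6.0], [2.0, 2.5, 7.0]]
        base = anova_oneway(groups).F
        transformed = [[scale * v + shift for v in g] for g in groups]
        assert anova_oneway(transformed).F == pytest.approx(base, rel=1e-6)

    def test_zero_within_variance_flagged_infinite(self):
        res = anova_oneway([[1, 1, 1], [2, 2, 2]])
        assert math.isinf(res.F) and res.p == 0.0 and res.degenerate_within

    @pytest.mark.parametrize(
        "groups",
        [
            [[1, 2, 3]],  # one group
            [[1], [2, 3]],  # singleton group
            [[2, 2], [2, 2]],  # no information at all
        ],
    )
    def test_degenerate_inputs_rejected(self, groups):
        with pytest.raises(ValueError):
            anova_oneway(groups)


class TestPearson:
    def test_perfect_linear_relation(self):
        assert pearson_r([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_hand_computed_case(self):
        assert pearson_r([1, 2, 3], [6, 5, 1]) == pytest.approx(-5 / math.sqrt(28), abs=1e-12)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert pearson_r(x, -y) == pytest.approx(-pearson_r(x, y), abs=1e-12)

    def test_pairwise_missing_dropped(self):
        x = [1.0, 2.0, math.nan, 3.0, 4.0]
        y = [2.0, 4.0, 100.0, 6.0, math.nan]
        assert pearson_r(x, y) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])


def test_series_validation():
    with pytest.raises(ValueError):
        FeatureSeries("p", [1, 1, 2], {"par": np.zeros(3)})
    with pytest.raises(ValueError):
        FeatureSeries("p", [1, 2], {"par": np.zeros(3)})
    with pytest.raises(KeyError):
        first_derivative(_series([1.0, 2.0]), "biomass")
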