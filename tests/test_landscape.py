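"""Landscape normalization, scoring, selection, error propagation and
rescue analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spinachscan import landscape
from spinachscan.landscape import (
    DegenerateRangeError,
    InsufficientDataError,
    correlate_landscapes,
    intersect_candidates,
    normalize_parameter,
    partner_score_correlation,
    position_score,
    propagate_error,
    rescue_analysis,
    rescue_index,
    score_spms,
    select_quantiles,
)


class TestNormalizeParameter:
    def test_extremes_and_midpoint(self):
        x = normalize_parameter([0.0, 5.0, 10.0], [True, True, True])
        assert x == pytest.approx([0.0, 0.5, 1.0])

    def test_non_fluorogenic_maps_to_minus_one(self):
        x = normalize_parameter([0.0, 5.0, 99.0], [True, True, False])
        assert x[2] == -1.0
        assert x[:2] == pytest.approx([0.0, 1.0])

    def test_orientation_flips_which_end_is_beneficial(self):
        # favorable_negative ddG: the most negative value should score 1
        x = normalize_parameter([-1.0, 0.0, 2.0], [True] * 3, orientation=-1.0)
        assert x[0] == 1.0 and x[2] == 0.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(DegenerateRangeError):
            normalize_parameter([3.0, 3.0, 3.0], [True] * 3)

    @given(
        shift=st.floats(min_value=-100, max_value=100),
        scale=st.floats(min_value=0.01, max_value=100),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_positive_affine_transform(self, shift, scale):
        vals = np.array([0.1, 0.7, 0.3, 0.9, 0.5])
        fl = [True] * 5
        a = normalize_parameter(vals, fl)
        b = normalize_parameter(vals * scale + shift, fl)
        assert a == pytest.approx(b, abs=1e-9)


def _frame(rows):
    return pd.DataFrame(rows)


class TestScoreSpms:
    def _base_frame(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        return _frame(
            [
                {
                    "mutant_id": f"m{i}", "positions": str(i // 3 + 1),
                    "s_m": rng.uniform(0, 1), "ddg": rng.normal(0, 0.3),
                    "ddh": rng.normal(0, 2), "dtm": rng.normal(0, 2),
                    "fluorogenic": True,
                }
                for i in range(n)
            ]
        )

    def test_all_best_gives_four_all_nonfluorogenic_minus_four(self):
        df = self._base_frame()
        df.loc[0, ["s_m", "dtm"]] = df[["s_m", "dtm"]].max()
        df.loc[0, ["ddg", "ddh"]] = df[["ddg", "ddh"]].min()
        df.loc[1, "fluorogenic"] = False
        scored = score_spms(df)
        assert scored.loc[0, "score"] == pytest.approx(4.0)
        assert scored.loc[1, "score"] == pytest.approx(-4.0)

    def test_sum_of_components(self):
        df = self._base_frame()
        scored = score_spms(df)
        expected = scored[["X_s_m", "X_ddg", "X_ddh", "X_dtm"]].sum(axis=1)
        assert scored["score"].to_numpy() == pytest.approx(expected.to_numpy())

    def test_score_bounds_hold_on_random_landscapes(self):
        for seed in range(5):
            scored = score_spms(self._base_frame(n=30, seed=seed))
            assert scored["score"].between(-4.0, 4.0).all()

    def test_missing_parameter_on_fluorogenic_spm_rejected(self):
        df = self._base_frame()
        df.loc[2, "ddh"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            score_spms(df)


class TestPositionScore:
    def test_constant_scores_stay_constant(self):
        df = _frame(
            [{"mutant_id": f"m{i}", "positions": str(i + 1), "score": 2.5}
             for i in range(6)]
        )
        track = position_score(df, 6)
        assert track["score"].to_numpy() == pytest.approx(np.full(6, 2.5))

    def test_truncated_window_hand_example(self):
        # per-position scores (0, 3, 0) -> windowed (1.5, 1.0, 1.5)
        df = _frame(
            [
                {"mutant_id": "a", "positions": "1", "score": 0.0},
                {"mutant_id": "b", "positions": "2", "score": 3.0},
                {"mutant_id": "c", "positions": "3", "score": 0.0},
            ]
        )
        track = position_score(df, 3)
        assert track["score"].to_numpy() == pytest.approx([1.5, 1.0, 1.5])

    def test_single_position_track_is_its_own_score(self):
        df = _frame([{"mutant_id": "a", "positions": "1", "score": 1.7}])
        track = position_score(df, 1)
        assert track["score"].iloc[0] == pytest.approx(1.7)

    def test_three_spms_per_position_average_before_windowing(self):
        df = _frame(
            [{"mutant_id": f"m{k}", "positions": "1", "score": s}
             for k, s in enumerate([0.0, 1.0, 2.0])]
        )
        track = position_score(df, 1)
        assert track["s_position"].iloc[0] == pytest.approx(1.0)

    def test_moving_average_never_leaves_input_range(self, rng):
        scores = rng.normal(0, 2, 30)
        df = _frame(
            [{"mutant_id": f"m{i}", "positions": str(i + 1), "score": s}
             for i, s in enumerate(scores)]
        )
        track = position_score(df, 30)
        assert track["score"].max() <= scores.max() + 1e-12
        assert track["score"].min() >= scores.min() - 1e-12


class TestPropagateError:
    def test_no_scatter_no_fit_error_gives_zero(self):
        assert propagate_error([2.0, 2.0, 2.0], [0.0, 0.0, 0.0]) == 0.0

    def test_two_replicates_unit_spread(self):
        # X = {0, 2}: sum sq dev = 2, /((N-1)N) = 1, squared then sqrt -> 1
        assert propagate_error([0.0, 2.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_as_printed_mode_squares_the_variance_terms(self):
        s = 0.3
        out = propagate_error([1.0, 1.0, 1.0], [s, s, s], mode="as_printed")
        assert out == pytest.approx(s**2)

    def test_quadrature_mode_is_conventional(self):
        s = 0.3
        out = propagate_error([1.0, 1.0, 1.0], [s, s, s], mode="quadrature")
        assert out == pytest.approx(s)

    def test_single_replicate_rejected(self):
        with pytest.raises(InsufficientDataError):
            propagate_error([1.0], [0.1])


def _landscape_frame(n=20, seed=1):
    rng = np.random.default_rng(seed)
    return _frame(
        [
            {
                "mutant_id": f"m{i:02d}", "positions": str(i + 1),
                "s_m": float(i), "ddg": rng.normal(0, 0.3),
                "ddh": rng.normal(0, 2), "dtm": rng.normal(0, 2),
                "fluorogenic": True,
            }
            for i in range(n)
        ]
    )


class TestSelectQuantiles:
    def test_ten_distinct_records_top_decile_selects_one(self):
        df = _landscape_frame(10)
        sel = select_quantiles(df, "s_m", q=0.10)
        assert len(sel) == 1
        assert sel["mutant_id"].iloc[0] == "m09"  # highest s_m

    def test_zero_quantile_selects_nothing(self):
        assert len(select_quantiles(_landscape_frame(), "s_m", q=0.0)) == 0

    def test_beneficial_direction_respects_orientation(self):
        df = _landscape_frame(10)
        sel = select_quantiles(df, "ddg", q=0.10)
        assert sel["ddg"].iloc[0] == df["ddg"].min()  # favorable_negative

    def test_intersection_of_disjoint_top_sets_is_empty(self):
        df = _landscape_frame(20)
        # make s_m and dtm anti-correlated so deciles cannot overlap
        df["dtm"] = -df["s_m"]
        assert len(intersect_candidates(df, ["s_m", "dtm"], q=0.10)) == 0

    def test_non_fluorogenic_records_never_selected(self):
        df = _landscape_frame(20)
        df.loc[19, "fluorogenic"] = False  # would otherwise top s_m
        sel = select_quantiles(df, "s_m", q=0.10)
        assert "m19" not in set(sel["mutant_id"])

    def test_too_few_records_rejected(self):
        with pytest.raises(InsufficientDataError):
            select_quantiles(_landscape_frame(5), "s_m")


class TestRescue:
    def test_full_rescue_none_and_halfway(self):
        assert rescue_index(0.2, 1.0, 1.0) == pytest.approx(1.0)
        assert rescue_index(0.2, 0.2, 1.0) == pytest.approx(0.0)
        assert rescue_index(0.2, 0.6, 1.0) == pytest.approx(0.5)

    def test_undefined_when_spm_matches_wildtype(self):
        assert np.isnan(rescue_index(1.0, 0.5, 1.0))

    def test_analysis_anchors_on_more_deleterious_spm(self):
        spm = {"A1G": 0.8, "U9C": 0.2}
        dpms = _frame(
            [{"mutant_id": "A1G+U9C", "spm_a": "A1G", "spm_b": "U9C", "s_m": 0.6}]
        )
        out = rescue_analysis(spm, dpms, wt_signal=1.0)
        assert out["anchor_spm"].iloc[0] == "U9C"
        assert out["rescue"].iloc[0] == pytest.approx(0.5)

    def test_reported_rescue_is_clipped(self):
        spm = {"a": 0.5, "b": 0.6}
        dpms = _frame([{"mutant_id": "d", "spm_a": "a", "spm_b": "b", "s_m": 5.0}])
        out = rescue_analysis(spm, dpms, wt_signal=1.0)
        assert out["rescue"].iloc[0] == 2.0
        assert out["rescue_raw"].iloc[0] == pytest.approx(9.0)


class TestCorrelateLandscapes:
    def test_exact_line_recovered(self):
        df = _frame(
            [{"mutant_id": f"m{i}", "s_m": 2.0 * i, "ddg": float(i),
              "fluorogenic": True} for i in range(5)]
        )
        slope, intercept, r = correlate_landscapes(df, "ddg", "s_m")
        assert (slope, intercept, r) == pytest.approx((2.0, 0.0, 1.0))

    def test_constant_response_gives_zero_slope(self):
        df = _frame(
            [{"mutant_id": f"m{i}", "s_m": 3.0, "ddg": float(i),
              "fluorogenic": True} for i in range(5)]
        )
        slope, _, _ = correlate_landscapes(df, "ddg", "s_m")
        assert slope == pytest.approx(0.0)

    def test_planted_linear_relation_recovered_under_noise(self, rng):
        ddg = rng.normal(0, 0.5, 200)
        s_m = 1.0 + 0.67 * ddg + rng.normal(0, 0.05, 200)
        df = _frame(
            [{"mutant_id": f"m{i}", "s_m": s, "ddg": g, "fluorogenic": True}
             for i, (s, g) in enumerate(zip(s_m, ddg))]
        )
        slope, _, r = correlate_landscapes(df, "ddg", "s_m")
        assert slope == pytest.approx(0.67, abs=0.05)
        assert abs(r) > 0.9

    def test_degenerate_x_rejected(self):
        df = _frame(
            [{"mutant_id": f"m{i}", "s_m": float(i), "ddg": 1.0,
              "fluorogenic": True} for i in range(5)]
        )
        with pytest.raises(ValueError):
            correlate_landscapes(df, "ddg", "s_m")


def test_partner_positions_share_scores_on_symmetric_track():
    track = pd.DataFrame(
        {"position": range(1, 11),
         "score": [1.0, 2.0, 3.0, 0.1, 0.2, 0.3, 0.4, 3.0, 2.0, 1.0]}
    )
    r = partner_score_correlation(track, [(1, 10), (2, 9), (3, 8)])
    assert r == pytest.approx(1.0)
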