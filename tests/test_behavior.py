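"""Behavioral scoring: front-back collapse, chance floors, slopes, z-scores."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plugadapt.behavior import (
    AdaptationModel,
    STIMULUS_CLASSES,
    collapse_front_back,
    circular_distance,
    error_magnitude,
    fit_adaptation_slope,
    percent_correct,
    response_bias,
    session_scores,
    standardize_measures,
)
from plugadapt.synthdata import SPEAKER_AZIMUTHS_DEG


def make_trials(targets, responses, session=1, kind="flat", trial_class="standard"):
    n = len(targets)
    return pd.DataFrame(
        {
            "session": session,
            "trial_index": np.arange(1, n + 1),
            "trial_class": trial_class,
            "kind": kind,
            "tone_freq_hz": np.nan if kind != "tone" else 2000.0,
            "level_db_spl": 63.0,
            "target_deg": targets,
            "response_deg": responses,
            "feedback": kind == "flat",
            "profile_id": "",
        }
    )


class TestCollapse:
    def test_mirror_examples(self):
        assert collapse_front_back(150.0) == 30.0
        assert collapse_front_back(180.0) == 0.0
        assert collapse_front_back(-120.0) == -60.0
        assert collapse_front_back(45.0) == 45.0

    def test_twelve_speakers_collapse_to_seven_positions(self):
        collapsed = set(collapse_front_back(SPEAKER_AZIMUTHS_DEG))
        assert collapsed == {0.0, 30.0, -30.0, 60.0, -60.0, 90.0, -90.0}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            collapse_front_back(190.0)
        with pytest.raises(ValueError):
            collapse_front_back(-180.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(az=st.floats(-179.99, 180.0))
    def test_collapse_is_idempotent_and_bounded(self, az):
        c = collapse_front_back(az)
        assert abs(c) <= 90.0
        assert collapse_front_back(c) == pytest.approx(c)


class TestPercentCorrect:
    def test_perfect_responder_scores_100(self):
        t = make_trials(SPEAKER_AZIMUTHS_DEG, SPEAKER_AZIMUTHS_DEG)
        assert percent_correct(t) == 100.0

    def test_exhaustive_uniform_responder_hits_chance(self):
        # all 144 target x response pairs exactly once -> exactly 100/12
        pairs = list(itertools.product(SPEAKER_AZIMUTHS_DEG, repeat=2))
        t = make_trials([p[0] for p in pairs], [p[1] for p in pairs])
        assert percent_correct(t) == pytest.approx(100.0 / 12.0)

    def test_correction_trials_excluded_by_default(self):
        std = make_trials([0.0, 30.0], [0.0, 30.0])
        corr = make_trials([60.0], [90.0], trial_class="correction")
        t = pd.concat([std, corr], ignore_index=True)
        assert percent_correct(t) == 100.0
        assert percent_correct(t, include_correction=True) == pytest.approx(200 / 3)

    def test_empty_selection_rejected(self):
        t = make_trials([0.0], [0.0], trial_class="correction")
        with pytest.raises(ValueError):
            percent_correct(t)


class TestErrorMagnitude:
    def test_perfect_and_mirror_responders_have_zero_collapsed_error(self):
        t = make_trials(SPEAKER_AZIMUTHS_DEG, SPEAKER_AZIMUTHS_DEG)
        assert error_magnitude(t) == 0.0
        mirrors = [collapse_front_back(a) if abs(a) < 90
                   else a for a in SPEAKER_AZIMUTHS_DEG]
        # respond with the front-hemifield image of every rear target
        resp = [np.sign(a) * (180 - abs(a)) if abs(a) > 90 else (180.0 if a == 0 else a)
                for a in SPEAKER_AZIMUTHS_DEG]
        t2 = make_trials(SPEAKER_AZIMUTHS_DEG, resp)
        assert error_magnitude(t2, collapsed=True) == 0.0
        assert error_magnitude(t2, collapsed=False) > 0.0

    def test_exhaustive_uniform_responder_matches_brute_force(self):
        pairs = list(itertools.product(SPEAKER_AZIMUTHS_DEG, repeat=2))
        t = make_trials([p[0] for p in pairs], [p[1] for p in pairs])
        expected = np.mean(
            [
                abs(collapse_front_back(r) - collapse_front_back(tg))
                for tg, r in pairs
            ]
        )
        assert error_magnitude(t) == pytest.approx(expected)

    def test_collapsed_error_never_exceeds_circular(self):
        for tg, r in itertools.product(SPEAKER_AZIMUTHS_DEG, repeat=2):
            c = abs(collapse_front_back(r) - collapse_front_back(tg))
            assert c <= circular_distance(r, tg) + 1e-12


class TestResponseBias:
    def test_symmetric_responder_has_zero_bias(self):
        pairs = list(itertools.product(SPEAKER_AZIMUTHS_DEG, repeat=2))
        t = make_trials([p[0] for p in pairs], [p[1] for p in pairs])
        assert response_bias(t, "left") == pytest.approx(0.0)

    def test_one_speaker_rightward_shift_gives_plus_thirty(self):
        # responses one collapsed step (30 deg) toward the right/open ear
        targets = [-60.0, -30.0, 0.0, 30.0, 60.0]
        responses = [-30.0, 0.0, 30.0, 60.0, 90.0]
        t = make_trials(targets, responses)
        assert response_bias(t, "left") == pytest.approx(30.0)
        # plugged on the right: same displacement now points away from open ear
        assert response_bias(t, "right") == pytest.approx(-30.0)

    def test_mirrored_tables_give_equal_bias(self):
        targets = np.array([-60.0, 0.0, 30.0])
        responses = np.array([-30.0, 30.0, 60.0])
        left = make_trials(targets, responses)
        right = make_trials(-targets, -responses)
        assert response_bias(left, "left") == pytest.approx(
            response_bias(right, "right")
        )


class TestSessionScores:
    def test_hand_computed_two_session_table(self):
        s1 = make_trials([0.0, 30.0, 60.0, 90.0], [0.0, 30.0, 90.0, 60.0], session=1)
        s2 = make_trials([0.0, 30.0], [0.0, 0.0], session=2)
        scores = session_scores(
            pd.concat([s1, s2], ignore_index=True), "left", classes=("flat",)
        )
        r1 = scores[scores.session == 1].iloc[0]
        assert r1.pct_correct == 50.0
        assert r1.err_mag_deg == pytest.approx((0 + 0 + 30 + 30) / 4)
        assert r1.bias_deg == pytest.approx((0 + 0 + 30 - 30) / 4)
        r2 = scores[scores.session == 2].iloc[0]
        assert r2.pct_correct == 50.0
        assert r2.bias_deg == pytest.approx(-15.0)

    def test_tone_high_pools_2_4_8_khz(self, small_experiment):
        scores = session_scores(small_experiment.trials, "left")
        for s in scores.session.unique():
            sub = scores[scores.session == s].set_index("stimulus_class")
            per_freq = sub.loc[["tone_2k", "tone_4k", "tone_8k"]]
            n = per_freq.n_trials.sum()
            pooled = (per_freq.pct_correct * per_freq.n_trials).sum() / n
            assert sub.loc["tone_high"].pct_correct == pytest.approx(pooled)
            assert sub.loc["tone_high"].n_trials == n

    def test_full_experiment_yields_rows_per_class_and_session(self, small_experiment):
        scores = session_scores(small_experiment.trials, "left")
        n_sessions = small_experiment.params.n_sessions
        counts = scores.groupby("stimulus_class").size()
        for cls in STIMULUS_CLASSES:
            assert counts[cls] == n_sessions

    def test_single_session_rejected(self):
        t = make_trials([0.0], [0.0])
        with pytest.raises(ValueError):
            session_scores(t, "left")


class TestSlopes:
    def test_exact_line_recovered(self):
        scores = [60, 62, 64, 66, 68, 70, 72]
        fit = fit_adaptation_slope(np.arange(1, 8), scores)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(58.0, abs=1e-12)

    def test_constant_scores_give_zero_slope(self):
        fit = fit_adaptation_slope([1, 2, 3], [5.0, 5.0, 5.0])
        assert fit.slope == 0.0

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(3)
        x = np.arange(1, 8, dtype=float)
        y = 3.0 - 1.2 * x + rng.standard_normal(7)
        fit = fit_adaptation_slope(x, y)
        xc = x - x.mean()
        slope = xc @ (y - y.mean()) / (xc @ xc)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(y.mean() - slope * x.mean(), abs=1e-10)

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValueError):
            fit_adaptation_slope([1], [5.0])


class TestStandardize:
    def test_three_values_population_sd(self):
        z = standardize_measures([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.22474487, 0.0, 1.22474487])

    def test_output_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z = standardize_measures(rng.normal(5, 3, size=40))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardize_measures([2.0, 2.0, 2.0])


class TestAdaptationModel:
    def test_fit_produces_slopes_with_cis_containing_point(self, small_experiment):
        res = AdaptationModel(small_experiment.trials, "left").fit(n_boot=200, seed=0)
        assert not res.slopes.empty
        for _, row in res.slopes.iterrows():
            assert row.ci_low <= row.ci_high
        # point slope typically inside its own bootstrap CI
        sl = res.slope("flat", "adaptation_rate")
        lo, hi = res.slope_ci("flat", "adaptation_rate")
        assert lo <= sl.slope <= hi

    def test_wider_level_widens_ci(self, small_experiment):
        res = AdaptationModel(small_experiment.trials, "left").fit(n_boot=400, seed=0)
        lo95, hi95 = res.slope_ci("flat", "adaptation_rate", level=0.95)
        lo99, hi99 = res.slope_ci("flat", "adaptation_rate", level=0.99)
        assert lo99 <= lo95 and hi99 >= hi95

    def test_summary_mentions_classes(self, small_experiment):
        res = AdaptationModel(small_experiment.trials, "left").fit(n_boot=100, seed=0)
        text = res.summary()
        assert "flat" in text and "adaptation_rate" in text
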