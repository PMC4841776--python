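"""Reverse correlation: triggered means, thresholded maps, reweighting."""

import numpy as np
import pandas as pd
import pytest

from plugadapt.revcorr import (
    FeatureStrengthProfile,
    SpectralReweightingModel,
    build_rcmap,
    cue_reweighting,
    feature_strength,
    response_triggered_mean,
    reweighting_null,
    _threshold_rows,
)
from plugadapt.spectra import default_grid, generate_random_vector
from plugadapt.synthdata import SPEAKER_AZIMUTHS_DEG


def make_random_trials(grid, n, responses, session=1, seed=0, profiles=None):
    """Random-spectrum trial table with given responses and fresh profiles."""
    rng = np.random.default_rng(seed)
    ids = [f"s{session}_p{seed}_{i}" for i in range(n)]
    if profiles is None:
        mat = np.stack([generate_random_vector(grid, seed=rng).amp_db for _ in range(n)])
    else:
        mat = profiles
    prof = pd.DataFrame(mat, index=ids)
    prof.index.name = "profile_id"
    trials = pd.DataFrame(
        {
            "session": session,
            "trial_index": np.arange(1, n + 1),
            "trial_class": "standard",
            "kind": "random",
            "tone_freq_hz": np.nan,
            "level_db_spl": 63.0,
            "target_deg": rng.choice(SPEAKER_AZIMUTHS_DEG, size=n),
            "response_deg": responses,
            "feedback": False,
            "profile_id": ids,
        }
    )
    return trials, prof


class TestTriggeredMean:
    def test_single_qualifying_trial_returns_its_own_vector(self):
        grid = default_grid()
        trials, prof = make_random_trials(grid, 3, [0.0, 30.0, 60.0], seed=1)
        tm = response_triggered_mean(trials, prof, grid, 30.0)
        np.testing.assert_allclose(tm.amp_db, prof.iloc[1].to_numpy())

    def test_spectrum_independent_responses_average_to_zero(self):
        grid = default_grid()
        rng = np.random.default_rng(2)
        n = 10_000
        responses = rng.choice(SPEAKER_AZIMUTHS_DEG, size=n)
        trials, prof = make_random_trials(grid, n, responses, seed=2)
        # grand average over all trials: CLT bound on the max over the
        # ~128 (correlated) bins needs a multiplicity margin -> 4 SE
        grand = prof.to_numpy().mean(axis=0)
        assert np.abs(grand).max() < 4 * 10 / np.sqrt(n)
        # per-location triggered means: ~n/12 qualifying trials each
        for loc in (0.0, 90.0):
            tm = response_triggered_mean(trials, prof, grid, loc)
            n_loc = int((responses == loc).sum())
            assert np.abs(tm.amp_db).max() < 4 * 10 / np.sqrt(n_loc)

    def test_missing_location_rejected(self):
        grid = default_grid()
        trials, prof = make_random_trials(grid, 3, [0.0, 0.0, 0.0], seed=3)
        with pytest.raises(ValueError):
            response_triggered_mean(trials, prof, grid, 90.0)


class TestRCMap:
    def test_constant_triggered_profile_thresholds_to_zero_row(self):
        grid = default_grid()
        mat = np.full((12, grid.n), 2.0)
        trials, prof = make_random_trials(
            grid, 12, np.zeros(12), seed=4, profiles=mat
        )
        rc = build_rcmap(trials, prof, grid, min_trials=10)
        assert not rc.missing[np.where(SPEAKER_AZIMUTHS_DEG == 0.0)[0][0]]
        assert np.all(rc.values_db == 0.0)

    def test_lone_spike_survives_thresholding(self):
        grid = default_grid()
        profile = np.zeros(grid.n)
        profile[40] = 6.0
        m, s = profile.mean(), profile.std()
        out = _threshold_rows(profile[None, :], 1.5)[0]
        assert 6.0 > m + 1.5 * s  # the spike is outside the band
        assert out[40] == 6.0
        assert np.all(out[np.arange(grid.n) != 40] == 0.0)

    def test_zero_threshold_returns_unthresholded_means(self):
        grid = default_grid()
        rng = np.random.default_rng(5)
        responses = np.repeat(SPEAKER_AZIMUTHS_DEG, 12)
        trials, prof = make_random_trials(grid, responses.size, responses, seed=5)
        rc0 = build_rcmap(trials, prof, grid, threshold_k=0.0, min_trials=10)
        for i, loc in enumerate(rc0.response_locations):
            tm = response_triggered_mean(trials, prof, grid, loc)
            keep = rc0.values_db[i] != 0.0
            np.testing.assert_allclose(rc0.values_db[i][keep], tm.amp_db[keep])

    def test_sparse_locations_flagged_missing(self):
        grid = default_grid()
        responses = np.array([0.0] * 15 + [30.0] * 3)
        trials, prof = make_random_trials(grid, 18, responses, seed=6)
        rc = build_rcmap(trials, prof, grid, min_trials=10)
        idx0 = np.where(rc.response_locations == 0.0)[0][0]
        idx30 = np.where(rc.response_locations == 30.0)[0][0]
        assert not rc.missing[idx0]
        assert rc.missing[idx30]
        assert np.all(rc.values_db[idx30] == 0.0)

    def test_thresholding_never_increases_magnitude(self):
        rng = np.random.default_rng(7)
        rows = rng.standard_normal((20, 50)) * 3
        out = _threshold_rows(rows, 1.5)
        assert np.all(np.abs(out) <= np.abs(rows) + 1e-12)


class TestFeatureStrength:
    def _map_with(self, grid, values):
        from plugadapt.revcorr import RCMap

        return RCMap(
            response_locations=SPEAKER_AZIMUTHS_DEG,
            grid=grid,
            values_db=values,
            missing=np.zeros(12, dtype=bool),
            n_trials_per_location=np.full(12, 20),
            threshold_k=1.5,
        )

    def test_zero_map_gives_zero_strength(self):
        grid = default_grid()
        fs = feature_strength(self._map_with(grid, np.zeros((12, grid.n))))
        assert np.all(fs.strength_db == 0.0)

    def test_single_entry_divided_by_locations(self):
        grid = default_grid()
        values = np.zeros((12, grid.n))
        values[3, 17] = 6.0
        fs = feature_strength(self._map_with(grid, values))
        assert fs.strength_db[17] == pytest.approx(0.5)

    def test_invariant_to_sign_flips(self):
        grid = default_grid()
        rng = np.random.default_rng(8)
        values = rng.standard_normal((12, grid.n))
        flipped = values * rng.choice([-1.0, 1.0], size=values.shape)
        a = feature_strength(self._map_with(grid, values))
        b = feature_strength(self._map_with(grid, flipped))
        np.testing.assert_allclose(a.strength_db, b.strength_db)


class TestCueReweighting:
    def test_identical_sessions_give_zero_delta(self):
        grid = default_grid()
        s = FeatureStrengthProfile(grid=grid, strength_db=np.abs(
            generate_random_vector(grid, seed=9).amp_db), session=1)
        est = cue_reweighting([s] * 7)
        assert np.all(est.delta_strength_db == 0.0)
        assert est.band_low == est.band_high == 0.0

    def test_unit_step_at_one_bin(self):
        grid = default_grid()
        zero = FeatureStrengthProfile(grid=grid, strength_db=np.zeros(grid.n), session=1)
        bump = np.zeros(grid.n)
        bump[100] = 1.0
        later = [
            FeatureStrengthProfile(grid=grid, strength_db=bump, session=s)
            for s in range(2, 8)
        ]
        est = cue_reweighting([zero] + later)
        assert est.delta_strength_db[100] == pytest.approx(1.0)
        assert est.delta_strength_db[np.arange(grid.n) != 100].max() == 0.0

    def test_needs_two_sessions(self):
        grid = default_grid()
        s = FeatureStrengthProfile(grid=grid, strength_db=np.zeros(grid.n), session=1)
        with pytest.raises(ValueError):
            cue_reweighting([s])


class TestNull:
    def test_small_n_perm_rejected(self, small_experiment):
        with pytest.raises(ValueError):
            reweighting_null(
                small_experiment.trials, small_experiment.profiles,
                small_experiment.grid, n_perm=50, seed=0, min_trials=5,
            )

    def test_bound_positive_and_deterministic(self, small_experiment):
        args = (small_experiment.trials, small_experiment.profiles, small_experiment.grid)
        bound_a, bands_a = reweighting_null(*args, n_perm=120, seed=4, min_trials=5)
        bound_b, bands_b = reweighting_null(*args, n_perm=120, seed=4, min_trials=5)
        np.testing.assert_array_equal(bound_a, bound_b)
        assert bands_a == bands_b
        assert np.all(bound_a > 0.0)

    def test_more_trials_shrink_the_bound(self):
        grid = default_grid()
        rng = np.random.default_rng(10)
        frames = []
        for n, seed in ((120, 1), (480, 2)):
            parts = []
            for session in (1, 2):
                resp = rng.choice(SPEAKER_AZIMUTHS_DEG, size=n)
                t, p = make_random_trials(grid, n, resp, session=session, seed=seed + session)
                parts.append((t, p))
            trials = pd.concat([x[0] for x in parts], ignore_index=True)
            prof = pd.concat([x[1] for x in parts])
            bound, _ = reweighting_null(trials, prof, grid, n_perm=150, seed=0)
            frames.append(bound.mean())
        assert frames[1] < frames[0]


class TestModel:
    def test_recovery_on_adapting_listener(self, adapting_experiment):
        model = SpectralReweightingModel(
            adapting_experiment.trials,
            adapting_experiment.profiles,
            adapting_experiment.grid,
        )
        res = model.fit(n_perm=200, seed=0)
        e = res.estimate
        assert e.band_high > e.band_high_null95  # reweighting detected >= 4 kHz
        assert e.band_low < e.band_low_null95  # none below
        freqs = e.grid.frequencies
        high_rate = e.significant[freqs >= 4000].mean()
        low_rate = e.significant[freqs < 4000].mean()
        assert high_rate > low_rate

    def test_summary_and_frame(self, adapting_experiment):
        res = SpectralReweightingModel(
            adapting_experiment.trials,
            adapting_experiment.profiles,
            adapting_experiment.grid,
        ).fit(n_perm=100, seed=1)
        assert "reweighting" in res.summary()
        df = res.to_frame()
        assert {"freq_hz", "delta_strength_db", "null_upper95_db", "significant"} <= set(
            df.columns
        )
        assert len(df) == adapting_experiment.grid.n
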