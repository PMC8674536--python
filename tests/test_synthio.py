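"""Task-sequence, Weibull, and recording-synthesis generator tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gammarep import synthio as sio


def scan_lags(trials: pd.DataFrame) -> float:
    """Independent lag oracle: exhaustive scan of the emitted sequence."""
    seq = trials["stimulus_id"].tolist()
    last = {}
    worst = 0
    for i, s in enumerate(seq):
        if s in last:
            worst = max(worst, i - last[s] - 1)
        last[s] = i
    return worst


class TestNaturalSequence:
    def test_full_block_is_500_trials(self):
        t = sio.generate_natural_sequence(25, 20, 3, 4, seed=1)
        assert len(t) == 500
        assert (t["stimulus_id"].value_counts() == 20).all()

    def test_single_stimulus_trivial(self):
        t = sio.generate_natural_sequence(1, 5, 1, 0, seed=0)
        assert len(t) == 5
        assert (t["lag"].dropna() == 0).all()
        assert list(t["repetition_number"]) == [1, 2, 3, 4, 5]

    def test_counts_and_lag_by_exhaustive_scan(self):
        t = sio.generate_natural_sequence(10, 8, 3, 4, seed=7)
        assert (t["stimulus_id"].value_counts() == 8).all()
        assert scan_lags(t) <= 4

    @pytest.mark.parametrize("seed", range(0, 1000, 1))
    def test_lag_constraint_never_violated(self, seed):
        t = sio.generate_natural_sequence(8, 5, 3, 4, seed=seed)
        assert scan_lags(t) <= 4
        assert (t["stimulus_id"].value_counts() == 5).all()

    def test_lag_column_matches_scan(self):
        t = sio.generate_natural_sequence(12, 6, 3, 4, seed=11)
        assert t["lag"].dropna().max() <= 4
        # recompute lag independently and compare
        seq = t["stimulus_id"].tolist()
        last = {}
        for i, s in enumerate(seq):
            if s in last:
                assert t["lag"].iloc[i] == i - last[s] - 1
            else:
                assert np.isnan(t["lag"].iloc[i])
            last[s] = i

    def test_infeasible_subset_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            sio.generate_natural_sequence(25, 20, subset_size=8, max_lag=4)

    def test_repetition_number_contiguous(self):
        t = sio.generate_natural_sequence(6, 7, 3, 4, seed=2)
        for _, grp in t.groupby("stimulus_id"):
            assert list(grp["repetition_number"]) == list(range(1, 8))

    def test_dummy_prefix_dummies_drop_out_early(self):
        t = sio.generate_natural_sequence(10, 10, 3, 4, seed=5,
                                          dummy_prefix=True)
        dummies = t[t["stimulus_id"].str.startswith("dummy")]
        assert set(dummies["stimulus_id"]) == {"dummy1", "dummy2"}
        # reduced repetition counts, confined to the session start
        assert dummies["stimulus_id"].value_counts().max() < 10
        assert dummies["trial_index"].max() <= 30
        regular = t[~t["stimulus_id"].str.startswith("dummy")]
        assert (regular["stimulus_id"].value_counts() == 10).all()


class TestChangeTime:
    def test_positive_draws(self, rng):
        x = sio.sample_change_time(0.27, 2.0, rng, size=1000)
        assert np.all(x > 0)

    def test_invalid_parameters(self, rng):
        with pytest.raises(ValueError):
            sio.sample_change_time(-1.0, 2.0, rng)
        with pytest.raises(ValueError):
            sio.sample_change_time(0.3, 0.0, rng)

    def test_cdf_matches_closed_form(self, rng):
        # scale a=1, shape b=2: F(t) = 1 - exp(-t^2)
        x = sio.sample_change_time(1.0, 2.0, rng, size=100_000)
        ks = sps.kstest(x, lambda t: 1.0 - np.exp(-t ** 2)).statistic
        assert ks < 0.01

    def test_moments_match_closed_form(self, rng):
        from math import gamma as G
        a, b, n = 0.27, 2.0, 100_000
        x = sio.sample_change_time(a, b, rng, size=n)
        mean = a * G(1 + 1 / b)
        var = a ** 2 * (G(1 + 2 / b) - G(1 + 1 / b) ** 2)
        se_mean = np.sqrt(var / n)
        assert abs(x.mean() - mean) < 3 * se_mean
        # variance of the sample variance ~ (m4 - var^2)/n; bound loosely
        assert abs(x.var() - var) < 0.05 * var


class TestBlockSequence:
    def test_aba_blocks(self):
        t = sio.generate_block_sequence("ABA", 100, stimuli=("g1", "g2"))
        assert len(t) == 300
        assert t["stimulus_id"].iloc[0] == "g1"
        assert t["stimulus_id"].iloc[100] == "g2"
        assert t["stimulus_id"].iloc[200] == "g1"
        # stimulus changes only at trials 101 and 201
        changes = np.flatnonzero(t["stimulus_id"].to_numpy()[1:]
                                 != t["stimulus_id"].to_numpy()[:-1])
        assert list(changes + 2) == [101, 201]
        assert list(t["block_type"].unique()) == ["[A]BA", "A[B]A", "AB[A]"]

    def test_all_a_design(self):
        t = sio.generate_block_sequence("AAAA", 50)
        assert len(t) == 200
        assert t["stimulus_id"].nunique() == 1
        # no switches: consecutive repetition count runs 1..200
        assert list(t["repetition_number"]) == list(range(1, 201))

    def test_location_blocks_by_scan(self):
        t = sio.generate_block_sequence("InOutIn", 50)
        loc = t["location"].to_numpy()
        assert (loc[:50] == "In").all()
        assert (loc[50:100] == "Out").all()
        assert (loc[100:] == "In").all()
        assert t["block_type"].iloc[0] == "[In]OutIn"

    def test_unknown_token_raises(self):
        with pytest.raises(ValueError, match="unknown design token"):
            sio.generate_block_sequence("InXOut", 10)

    def test_counterbalancing_swap(self):
        t = sio.generate_block_sequence("AB", 10, stimuli=("g1", "g2"),
                                        swap_stimuli=True)
        assert t["stimulus_id"].iloc[0] == "g2"


class TestCorrectness:
    def test_repetition_recount_over_correct_trials(self):
        t = sio.generate_natural_sequence(5, 10, 3, 4, seed=4)
        t2 = sio.simulate_correctness(t, p_error_early=0.4, p_error=0.2,
                                      seed=0)
        assert t2["correct"].sum() < len(t2)
        for _, grp in t2.groupby("stimulus_id"):
            reps = grp.loc[grp["correct"], "repetition_number"]
            assert list(reps) == list(range(1, len(reps) + 1))
            assert grp.loc[~grp["correct"], "repetition_number"].isna().all()


class TestRecordingSynthesis:
    def test_deterministic_under_seed(self, small_truth):
        trials = sio.generate_natural_sequence(4, 6, 3, 4, seed=9)
        a = sio.synthesize_recording(trials, small_truth, seed=42)
        b = sio.synthesize_recording(trials, small_truth, seed=42)
        assert np.array_equal(a.lfp, b.lfp)
        assert np.array_equal(a.mua, b.mua)

    def test_mua_nonnegative_and_time_axis(self, small_session):
        assert small_session.mua.min() >= 0
        assert small_session.time[0] <= -1.0
        assert small_session.time[-1] >= 1.5 - 1.0 / small_session.fs

    def test_no_gamma_when_base_power_zero(self):
        from gammarep import gamma_peaks as gp
        from gammarep.preprocess import baseline_normalize, epoch
        from gammarep.spectral import DPSS_250MS, taper_power

        trials = sio.generate_natural_sequence(3, 8, 3, 4, seed=2)
        truth = sio.GroundTruth.random(["s01", "s02", "s03"],
                                       np.random.default_rng(1),
                                       gamma_base_power=0.0)
        ses = sio.synthesize_recording(trials, truth, seed=5)
        se = epoch(ses.lfp, ses.time, ses.fs, (0.5, 1.5), 0.25)
        be = epoch(ses.lfp, ses.time, ses.fs, (-1.0, 0.0), 0.25)
        rel = baseline_normalize(
            taper_power(se, DPSS_250MS).power.transpose(1, 0, 2),
            taper_power(be, DPSS_250MS).power.transpose(1, 0, 2)).values
        spec = rel.mean(axis=(0, 1))
        freqs = np.fft.rfftfreq(int(0.25 * ses.fs), 1 / ses.fs)
        found = gp.find_peaks(spec, freqs)
        # any residual local maxima of the flat ratio spectrum are tiny
        assert all(pk.height < 1.3 for pk in found)

    def test_fs_too_low_raises(self, small_truth):
        trials = sio.generate_natural_sequence(4, 5, 3, 4, seed=0)
        with pytest.raises(ValueError, match="fs too low"):
            sio.synthesize_recording(trials, small_truth, fs=100.0)

    def test_rf_gating_suppresses_out_blocks(self):
        trials = sio.generate_block_sequence("InOut", 30)
        truth = sio.GroundTruth.random(["g1"], np.random.default_rng(3),
                                       x_transform="log10_trial_in_block")
        ses = sio.synthesize_recording(trials, truth, seed=8)
        stim = ses.time > 0.1
        mua_in = ses.mua[:, :30, :][:, :, stim].mean()
        mua_out = ses.mua[:, 30:, :][:, :, stim].mean()
        assert mua_in > 1.5 * mua_out


class TestEyeTraces:
    def test_flat_without_events_or_jitter(self):
        trials = sio.generate_natural_sequence(2, 3, 2, 4, seed=0)
        eye = sio.synthesize_eye_traces(trials, events_per_trial=0,
                                        jitter_sd=0.0, seed=0)
        assert np.allclose(eye.gaze_x, 0) and np.allclose(eye.gaze_y, 0)
        assert eye.injected_events == []

    def test_events_recorded(self):
        trials = sio.generate_natural_sequence(2, 4, 2, 4, seed=1)
        eye = sio.synthesize_eye_traces(trials, events_per_trial=2, seed=1)
        assert len(eye.injected_events) == 2 * len(trials)


class TestIO:
    def test_trials_csv_roundtrip(self, tmp_path):
        t = sio.generate_natural_sequence(5, 4, 3, 4, seed=6)
        path = tmp_path / "trials.csv"
        sio.write_trials_csv(t, path)
        t2 = sio.read_trials_csv(path)
        pd.testing.assert_frame_equal(
            t.reset_index(drop=True), t2, check_dtype=False)

    def test_session_hdf5_roundtrip(self, tmp_path, small_session):
        path = tmp_path / "session.h5"
        sio.save_session(small_session, path)
        ses = sio.load_session(path)
        assert np.array_equal(ses.lfp, small_session.lfp)
        assert np.array_equal(ses.mua, small_session.mua)
        assert ses.fs == small_session.fs
        assert ses.sites == small_session.sites
        assert list(ses.trials["stimulus_id"]) == \
            list(small_session.trials["stimulus_id"])
        assert ses.truth is not None
        assert np.allclose(ses.truth.gamma_peak_hz,
                           small_session.truth.gamma_peak_hz)

    def test_truth_json_roundtrip(self, tmp_path, small_truth):
        path = tmp_path / "truth.json"
        small_truth.to_json(path)
        t2 = sio.GroundTruth.from_json(path)
        assert t2.stimuli == small_truth.stimuli
        assert np.allclose(t2.mua_base, small_truth.mua_base)
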