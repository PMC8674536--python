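"""Permutation tests, bootstrap SEM, FDR, regression, behavior ops."""

import numpy as np
import pandas as pd
import pytest

from gammarep import stats as st
from gammarep import synthio as sio


class TestSignFlip:
    def test_all_zero_gives_p_one(self, rng):
        res = st.signflip_test(np.zeros(10), rng=rng)
        assert res.p == 1.0

    def test_consistent_effect_hits_floor(self, rng):
        res = st.signflip_test(np.full(20, 0.7), rng=rng)
        assert res.p == pytest.approx(0.002)
        assert res.p >= 2 / res.n_perm

    def test_too_few_sessions(self, rng):
        with pytest.raises(ValueError):
            st.signflip_test(np.array([1.0]), rng=rng)

    def test_type_i_calibration(self):
        rng = np.random.default_rng(21)
        rej = 0
        n_runs = 500
        for _ in range(n_runs):
            res = st.signflip_test(rng.standard_normal(15), n_perm=500,
                                   rng=rng)
            rej += res.p < 0.05
        lo = 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / n_runs)
        hi = 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_runs)
        assert lo <= rej / n_runs <= hi


class TestExchange:
    def test_identical_conditions_give_p_one(self, rng):
        x = np.arange(10.0)
        res = st.exchange_test(x, x.copy(), rng=rng)
        assert res.p == 1.0

    def test_symmetry_under_swap(self):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        a = np.array([1.0, 2.0, 1.5, 2.5, 1.8, 2.2])
        b = a + 0.4
        r1 = st.exchange_test(a, b, rng=rng1)
        r2 = st.exchange_test(b, a, rng=rng2)
        assert r1.observed == -r2.observed
        assert r1.p == r2.p

    def test_power_on_planted_difference(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(200):
            a = rng.standard_normal(20)
            b = a + 1.0 + rng.standard_normal(20) * 0.5
            hits += st.exchange_test(a, b, n_perm=500, rng=rng).p < 0.05
        assert hits / 200 > 0.9

    def test_unpaired_rejected(self, rng):
        with pytest.raises(ValueError, match="paired"):
            st.exchange_test(np.zeros(4), np.zeros(5), rng=rng)


class TestBootstrapSEM:
    def test_constant_data_zero_sem(self, rng):
        assert st.bootstrap_sem(np.full((8, 3), 2.0), rng=rng) == 0.0

    def test_matches_analytic_rate(self):
        rng = np.random.default_rng(3)
        rel_err = []
        for _ in range(100):
            n = 25
            x = rng.standard_normal((n, 1))
            sem = st.bootstrap_sem(x, n_boot=400, rng=rng)
            rel_err.append(sem * np.sqrt(n))
        assert np.mean(rel_err) == pytest.approx(1.0, abs=0.15)

    def test_scale_equivariance(self):
        x = np.random.default_rng(0).standard_normal((10, 2))
        s1 = st.bootstrap_sem(x, n_boot=500, rng=np.random.default_rng(1))
        s2 = st.bootstrap_sem(2 * x, n_boot=500, rng=np.random.default_rng(1))
        assert s2 == pytest.approx(2 * s1)


class TestFDR:
    def test_all_small_p_all_significant(self):
        assert st.fdr_correct(np.full(20, 0.001)).all()

    def test_single_p_plain_alpha(self):
        assert st.fdr_correct(np.array([0.04]))[0]
        assert not st.fdr_correct(np.array([0.06]))[0]

    def test_global_null_fdp_controlled(self):
        rng = np.random.default_rng(17)
        fdps = []
        for _ in range(500):
            p = rng.uniform(size=100)
            mask = st.fdr_correct(p)
            # under the global null every rejection is false: FDP is 1 or 0
            fdps.append(1.0 if mask.any() else 0.0)
        assert np.mean(fdps) <= 0.05 + 1.96 * np.sqrt(0.05 / 500)


class TestBlockRegression:
    def test_planted_persistence_intercept_recovered(self):
        rng = np.random.default_rng(8)
        errs = []
        for _ in range(50):
            trials = sio.generate_block_sequence("ABA", 60, seed=int(
                rng.integers(2 ** 31 - 1)))
            tib = trials["trial_in_block"].to_numpy(dtype=float)
            delayed = (trials["block_type"] == "AB[A]").to_numpy().astype(int)
            log_resp = (0.1 * np.log10(trials["repetition_number"])
                        + 0.1 * delayed
                        + 0.05 * rng.standard_normal(len(trials)))
            df = pd.DataFrame(dict(
                resp=10 ** log_resp, rep=trials["repetition_number"],
                delayed=delayed, session_id="s01"))
            spec = st.RegressionSpec(response="resp", log_terms=["rep"],
                                     block_indicators=["delayed"],
                                     interactions=False)
            table, _ = st.fit_block_regression(df, spec)
            errs.append(table.loc["delayed", "coef"] - 0.1)
        se = np.std(errs) / np.sqrt(len(errs))
        assert abs(np.mean(errs)) < 2 * se + 1e-3

    def test_no_effect_block_term_level(self):
        rng = np.random.default_rng(13)
        rej = 0
        n_runs = 200
        for _ in range(n_runs):
            n = 150
            df = pd.DataFrame(dict(
                resp=10 ** (0.05 * rng.standard_normal(n)),
                rep=np.tile(np.arange(1, 51), 3)[:n],
                delayed=np.r_[np.zeros(100), np.ones(50)].astype(int)))
            spec = st.RegressionSpec(response="resp", log_terms=["rep"],
                                     block_indicators=["delayed"],
                                     interactions=False)
            table, _ = st.fit_block_regression(df, spec)
            rej += table.loc["delayed", "p"] < 0.05
        assert rej / n_runs < 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_runs)

    def test_response_scaling_shifts_only_intercept(self):
        rng = np.random.default_rng(2)
        n = 200
        df = pd.DataFrame(dict(resp=rng.uniform(1, 3, n),
                               rep=np.tile(np.arange(1, 51), 4),
                               delayed=rng.integers(0, 2, n)))
        spec = st.RegressionSpec(response="resp", log_terms=["rep"],
                                 block_indicators=["delayed"],
                                 interactions=False)
        t1, _ = st.fit_block_regression(df, spec)
        df2 = df.assign(resp=df["resp"] * 100.0)
        t2, _ = st.fit_block_regression(df2, spec)
        assert t2.loc["Intercept", "coef"] - t1.loc["Intercept", "coef"] == \
            pytest.approx(2.0, abs=1e-9)
        for term in ("np.log10(rep)", "delayed"):
            assert t2.loc[term, "coef"] == pytest.approx(t1.loc[term, "coef"],
                                                         abs=1e-9)

    def test_duplicate_terms_rejected(self):
        spec = st.RegressionSpec(response="r", log_terms=["a", "a"])
        with pytest.raises(ValueError, match="duplicated"):
            spec.formula()


class TestMicrosaccades:
    def test_constant_gaze_no_events(self):
        gx = np.zeros((3, 1000))
        out = st.detect_microsaccades(gx, gx, fs=500.0)
        assert len(out) == 0

    def test_injected_step_detected_once(self):
        rng = np.random.default_rng(0)
        fs = 500.0
        gx = 0.005 * rng.standard_normal((1, 1000))
        gy = 0.005 * rng.standard_normal((1, 1000))
        gx[0, 400:] += 1.0  # 1 dva step at sample 400
        out = st.detect_microsaccades(gx, gy, fs=fs)
        assert len(out) == 1
        assert abs(out["onset_index"].iloc[0] - 400) <= 0.010 * fs

    @pytest.mark.parametrize("lam", [5.0, 6.0, 7.0])
    def test_threshold_robustness(self, lam):
        # recall of injected 1-dva events is stable across thresholds
        rng = np.random.default_rng(1)
        fs = 500.0
        gx = 0.005 * rng.standard_normal((5, 1000))
        gy = 0.005 * rng.standard_normal((5, 1000))
        onsets = [300 + 50 * tr for tr in range(5)]
        for tr, on in enumerate(onsets):
            gx[tr, on:] += 1.0
        out = st.detect_microsaccades(gx, gy, fs=fs, lam=lam)
        found = 0
        for tr, on in enumerate(onsets):
            ev = out[out["trial"] == tr]
            found += (np.abs(ev["onset_index"] - on) <= 0.010 * fs).any()
        assert found == 5

    def test_criterion_scale_equivariance(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(5000)
        c1 = st._robust_criterion(v)
        c2 = st._robust_criterion(3.0 * v)
        assert c2 == pytest.approx(3.0 * c1, rel=1e-9)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            st.detect_microsaccades(np.zeros((1, 10)), np.zeros((1, 10)),
                                    fs=500.0)


class TestPupil:
    TIME = -1.3 + np.arange(1400) / 500.0

    def test_baseline_mean_maps_to_zero(self, rng):
        pupil = 5.0 + 0.1 * rng.standard_normal((4, self.TIME.size))
        z, flag = st.pupil_response(pupil, self.TIME)
        base = (self.TIME >= -1.0) & (self.TIME < 0.0)
        assert np.allclose(z[:, base].mean(axis=1), 0.0, atol=1e-9)
        assert not flag.any()

    def test_planted_constriction_recovered(self):
        rng = np.random.default_rng(6)
        trials = sio.generate_natural_sequence(2, 5, 2, 4, seed=0)
        eye = sio.synthesize_eye_traces(trials, pupil_constriction=2.0,
                                        pupil_latency=0.4, seed=3)
        z, _ = st.pupil_response(eye.pupil, eye.time)
        mean_z = z.mean(axis=0)
        t_min = eye.time[np.argmin(mean_z)]
        assert abs(t_min - 0.4) < 0.05
        assert mean_z.min() < -1.0

    def test_zero_variance_baseline_flagged(self):
        pupil = np.ones((2, self.TIME.size))
        pupil[1] += np.linspace(0, 1, self.TIME.size)  # nonconstant baseline
        z, flag = st.pupil_response(pupil, self.TIME)
        assert flag[0] and not flag[1]
        assert np.isnan(z[0]).all()


class TestBinnedMeans:
    def test_centered_seven_trial_bins(self):
        vals = np.arange(1.0, 11.0)
        tn = np.arange(1, 11)
        out = st.binned_means(vals, tn, half_width=3)
        assert out[4] == pytest.approx(np.mean(vals[1:8]))
        assert out[0] == pytest.approx(np.mean(vals[:4]))
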