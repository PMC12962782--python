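"""dF/F preprocessing chain and trial-level response quantification."""

import numpy as np
import pytest
from scipy import signal, stats

from cholinepipe import photometry as ph
from cholinepipe.synthetic import gen_photometry, gen_task_session
from cholinepipe.types import CalciumSignal, PhotometrySession, ValidationError


def chain_filter(x, fs, lowpass_hz=20.0, highpass_hz=0.2, order=4):
    """The same zero-phase band limitation the dF/F output carries."""
    lp = signal.butter(order, lowpass_hz, btype="low", fs=fs, output="sos")
    hp = signal.butter(order, highpass_hz, btype="high", fs=fs, output="sos")
    return signal.sosfiltfilt(hp, signal.sosfiltfilt(lp, x))


class TestPreprocessDff:
    def test_identical_constant_channels_give_zero(self):
        t = np.arange(3000) / 100.0
        sess = PhotometrySession(t=t, f465=np.full(3000, 100.0), f405=np.full(3000, 100.0), fs=100.0)
        sig = ph.preprocess_dff(sess)
        np.testing.assert_allclose(sig.dff, 0.0, atol=1e-9)

    def test_pure_gain_difference_absorbed(self):
        t = np.arange(6000) / 100.0
        drift = 100.0 + 5.0 * np.exp(-t / 30.0)
        sess = PhotometrySession(t=t, f465=1.1 * drift, f405=drift, fs=100.0)
        sig = ph.preprocess_dff(sess)
        assert np.max(np.abs(sig.dff)) < 1e-6

    def test_generator_recovery_and_artifact_rejection(self):
        sess, truth = gen_photometry(seed=21)
        sig = ph.preprocess_dff(sess)
        target = chain_filter(truth.params["clean_dff"], sess.fs)
        assert np.corrcoef(sig.dff, target)[0, 1] >= 0.9
        # artifact variance: transient-free session, corrected vs naive
        null_sess, _ = gen_photometry(seed=21, n_transients=0)
        null_dff = ph.preprocess_dff(null_sess).dff
        naive = (null_sess.f465 - null_sess.f465.mean()) / null_sess.f465.mean() * 100
        assert np.var(null_dff) <= 0.2 * np.var(naive)

    def test_common_scaling_invariance(self):
        sess, _ = gen_photometry(duration=60.0, seed=2)
        scaled = PhotometrySession(t=sess.t, f465=3.7 * sess.f465, f405=3.7 * sess.f405, fs=sess.fs)
        a = ph.preprocess_dff(sess).dff
        b = ph.preprocess_dff(scaled).dff
        np.testing.assert_allclose(a, b, atol=1e-9 * max(1.0, np.abs(a).max()))

    def test_zero_phase_no_peak_shift(self):
        fs = 100.0
        t = np.arange(6000) / fs
        bump = 4.0 * np.exp(-0.5 * ((t - 30.0) / 0.3) ** 2)
        sess = PhotometrySession(
            t=t, f465=100.0 * (1 + bump / 100.0), f405=np.full_like(t, 100.0), fs=fs
        )
        sig = ph.preprocess_dff(sess)
        assert abs(np.argmax(sig.dff) - np.argmax(bump)) <= 1

    def test_short_session_rejected(self):
        t = np.arange(500) / 100.0
        sess = PhotometrySession(t=t, f465=np.full(500, 1.0), f405=np.full(500, 1.0), fs=100.0)
        with pytest.raises(ValidationError, match="10 s"):
            ph.preprocess_dff(sess)

    def test_low_fs_rejected(self):
        t = np.arange(300) / 10.0
        sess = PhotometrySession(t=t, f465=np.ones(300), f405=np.ones(300), fs=10.0)
        with pytest.raises(ValidationError, match="low-pass"):
            ph.preprocess_dff(sess)

    def test_amplitude_ratio_recovery(self):
        """Transients of 1/2/4 %dF/F recover peak ratios 1:2:4 within 15%."""
        ratios = []
        for seed in range(10):
            peaks = []
            for amp in (1.0, 2.0, 4.0):
                sess, truth = gen_photometry(
                    duration=120.0,
                    transient_times=np.arange(10.0, 110.0, 10.0),
                    amplitudes=amp,
                    noise_sd=0.02,
                    seed=seed,
                )
                sig = ph.preprocess_dff(sess)
                # median peak height at the known transient times
                idx = (truth.params["transient_times"] * sess.fs).astype(int)
                peaks.append(np.median([sig.dff[i : i + 30].max() for i in idx]))
            ratios.append((peaks[1] / peaks[0], peaks[2] / peaks[0]))
        r2, r4 = np.mean(ratios, axis=0)
        assert r2 == pytest.approx(2.0, rel=0.15)
        assert r4 == pytest.approx(4.0, rel=0.15)


def _trial_peth_from_trace(trace, fs=50.0, n_trials=1, window=(-2.0, 3.0)):
    """Build a TrialPETH directly from a constructed mean trace."""
    n = len(trace)
    rel = (np.arange(n) + 0.5) / fs + window[0]
    matrix = np.tile(trace, (n_trials, 1))
    return ph.TrialPETH(bin_centers=rel, matrix=matrix, mean=matrix.mean(axis=0), n_trials=n_trials, fs=fs)


class TestZscoreToBaseline:
    def _session_with_trials(self, seed=1, n_trials=50):
        trials, _, _, _ = gen_task_session(n_trials=n_trials, seed=seed)
        duration = trials.df["cue_time"].max() + 20.0
        sess, truth = gen_photometry(duration=duration, fs=50.0, n_transients=30, seed=seed)
        sig = ph.preprocess_dff(sess)
        return sig, trials

    def test_per_trial_baseline_statistics(self):
        sig, trials = self._session_with_trials()
        peth = ph.zscore_to_baseline(sig, trials)
        base_cols = peth.window_slice(-2.0, 0.0)
        assert peth.matrix[:, base_cols].mean() == pytest.approx(0.0, abs=0.05)
        assert peth.matrix[:, base_cols].std(axis=1).mean() == pytest.approx(1.0, abs=0.1)

    def test_constant_trace_zero_sd_excluded(self):
        t = np.arange(5000) / 50.0
        sig = CalciumSignal(t=t, dff=np.zeros(5000), fs=50.0)
        trials, *_ = gen_task_session(n_trials=5, seed=2)
        import pandas as pd

        from cholinepipe.types import TrialTable

        df = trials.df.copy()
        df["cue_time"] = np.linspace(10, 80, 5)
        with pytest.raises(ValidationError):
            # all trials excluded -> empty matrix surfaces as an error
            peth = ph.zscore_to_baseline(sig, TrialTable(df))
            if peth.n_trials == 0:
                raise ValidationError("no usable trials")

    def test_simple_z_values(self):
        """A sample at baseline-mean + 2 SD maps to z = 2."""
        fs = 50.0
        t = np.arange(5000) / fs
        rng = np.random.default_rng(3)
        trace = rng.normal(0.0, 1.0, size=5000)
        sig = CalciumSignal(t=t, dff=trace, fs=fs)
        import pandas as pd

        from cholinepipe.types import TrialTable

        df = pd.DataFrame(
            {
                "cue_time": [20.0],
                "cue_id": [1],
                "outcome_time": [20.5],
                "outcome": ["reward"],
            }
        )
        peth = ph.zscore_to_baseline(sig, TrialTable(df))
        base = peth.window_slice(-2.0, 0.0)
        i0 = int(round(20.0 * fs))
        mu = trace[i0 - 100 : i0].mean()
        sd = trace[i0 - 100 : i0].std()
        expect = (trace[i0 - 100 : i0 + 150] - mu) / sd
        np.testing.assert_allclose(peth.matrix[0], expect, atol=1e-9)
        np.testing.assert_allclose(peth.matrix[0, base].mean(), 0.0, atol=1e-12)


class TestResponseMetrics:
    def test_gaussian_fwhm_and_latency(self):
        fs = 1000.0
        rel_len = int(5.0 * fs)
        t = (np.arange(rel_len) + 0.5) / fs - 2.0
        trace = 4.0 * np.exp(-0.5 * ((t - 0.4) / 0.1) ** 2)
        peth = ph.TrialPETH(bin_centers=t, matrix=trace[None, :], mean=trace, n_trials=1, fs=fs)
        m = ph.response_metrics(peth)
        fwhm = 2 * np.sqrt(2 * np.log(2)) * 0.1
        assert m.duration == pytest.approx(fwhm, abs=2 / fs)
        assert m.latency == pytest.approx(0.4, abs=1.5 / fs)
        assert m.peak == pytest.approx(4.0, abs=1e-3)  # half-sample grid offset

    def test_triangular_pulse_duration_and_auc(self):
        fs = 1000.0
        rel_len = int(5.0 * fs)
        t = (np.arange(rel_len) + 0.5) / fs - 2.0
        trace = np.maximum(0.0, 1.0 - np.abs(t - 0.3) / 0.1)  # base 200 ms, apex 1
        peth = ph.TrialPETH(bin_centers=t, matrix=trace[None, :], mean=trace, n_trials=1, fs=fs)
        m = ph.response_metrics(peth)
        assert m.duration == pytest.approx(0.100, abs=2 / fs)
        lo = np.searchsorted(t, 0.3 - 0.05)
        hi = np.searchsorted(t, 0.3 + 0.05)
        auc_oracle = np.trapezoid(trace[lo:hi], dx=1 / fs)
        assert m.auc == pytest.approx(auc_oracle, rel=0.01)

    def test_flat_zero_trace_flagged(self):
        fs = 100.0
        t = (np.arange(500) + 0.5) / fs - 2.0
        trace = np.zeros(500)
        peth = ph.TrialPETH(bin_centers=t, matrix=trace[None, :], mean=trace, n_trials=1, fs=fs)
        m = ph.response_metrics(peth)
        assert m.peak == 0.0
        assert m.flag == "no positive response"
        assert m.duration == pytest.approx(1.0, abs=0.05)  # full response window

    def test_matches_independent_scan_oracle(self):
        rng = np.random.default_rng(7)
        fs = 100.0
        t = (np.arange(500) + 0.5) / fs - 2.0
        trace = rng.normal(0, 1, size=500)
        peth = ph.TrialPETH(bin_centers=t, matrix=trace[None, :], mean=trace, n_trials=1, fs=fs)
        m = ph.response_metrics(peth)
        resp = np.flatnonzero((t >= 0) & (t < 1.0))
        k = resp[np.argmax(trace[resp])]
        assert m.peak == trace[k]
        assert m.latency == t[k]


class TestTrialwiseCueTest:
    def _peth(self, matrix, fs=50.0):
        n = matrix.shape[1]
        rel = (np.arange(n) + 0.5) / fs - 1.0
        return ph.TrialPETH(
            bin_centers=rel, matrix=matrix, mean=matrix.mean(axis=0), n_trials=matrix.shape[0], fs=fs
        )

    def test_identical_windows_not_significant(self):
        rng = np.random.default_rng(1)
        matrix = rng.normal(size=(20, 100))  # grid (-1, 1) s at 50 Hz
        matrix[:, 50:75] = matrix[:, 25:50]  # response window == baseline window
        out = ph.trialwise_cue_test(self._peth(matrix))
        assert not out["significant"] and out["p"] == 1.0

    def test_uniform_shift_significant_with_exact_p(self):
        rng = np.random.default_rng(2)
        matrix = rng.normal(size=(20, 100))
        shift = np.linspace(0.5, 1.5, 20)[:, None]
        matrix[:, 50:75] = matrix[:, 25:50] + shift  # distinct positive differences
        out = ph.trialwise_cue_test(self._peth(matrix))
        assert out["significant"]
        assert out["p"] == pytest.approx(2.0**-20, rel=1e-9)

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(200):
            matrix = rng.normal(size=(30, 100))
            out = ph.trialwise_cue_test(self._peth(matrix))
            hits += out["significant"]
        assert hits / 200 <= 0.075

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValidationError):
            ph.trialwise_cue_test(self._peth(np.zeros((5, 100))))
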