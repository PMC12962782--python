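"""Autocorrelogram computation and firing-pattern statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cholinepipe import acg
from cholinepipe.synthetic import (
    gen_bursting_train,
    gen_poisson_train,
    gen_regular_theta_train,
)
from cholinepipe.types import SpikeTrain, ValidationError

from conftest import brute_force_acg_counts


class TestComputeAcg:
    def test_exhaustive_pairs_three_regular_spikes(self, regular_train):
        a = acg.compute_acg(regular_train, bin_width=0.0005, max_lag=0.1)
        # pairs: two at 10 ms lag, one at 20 ms
        assert a.counts[int(0.010 / 0.0005)] == 2
        assert a.counts[int(0.020 / 0.0005)] == 1
        assert a.counts.sum() == 3
        assert a.n_spikes_used == 3

    def test_zero_lag_self_pairs_excluded(self):
        tr = SpikeTrain("u", np.array([0.1, 0.2, 0.3]), 0.0, 1.0)
        a = acg.compute_acg(tr, bin_width=0.0005, max_lag=0.05)
        assert a.counts[0] == 0  # no self-pairs at lag 0

    def test_mean_normalization(self, regular_train):
        a = acg.compute_acg(regular_train, bin_width=0.0005, max_lag=0.1)
        assert a.norm.mean() == pytest.approx(1.0, abs=1e-9)

    def test_poisson_acg_flat_after_smoothing(self):
        tr, _ = gen_poisson_train(20.0, 500.0, seed=7)
        a = acg.smooth_acg(acg.compute_acg(tr), window=0.0025)
        assert np.all(a.norm > 0.8) and np.all(a.norm < 1.2)

    def test_matches_bruteforce_on_poisson(self):
        tr, _ = gen_poisson_train(15.0, 60.0, seed=3)
        a = acg.compute_acg(tr, bin_width=0.0005, max_lag=0.5)
        expected = brute_force_acg_counts(tr.times, 0.0005, 0.5)
        np.testing.assert_array_equal(a.counts, expected)

    def test_spike_cap_uses_first_spikes(self):
        times = np.arange(0, 60.001, 0.01)  # 6001 regular spikes
        tr = SpikeTrain("dense", times, 0.0, 61.0)
        a = acg.compute_acg(tr, bin_width=0.0005, max_lag=0.1, spike_cap=5000)
        assert a.n_spikes_used == 5000
        expected = brute_force_acg_counts(times[:5000], 0.0005, 0.1)
        np.testing.assert_array_equal(a.counts, expected)

    def test_too_few_spikes_error(self):
        tr = SpikeTrain("one", np.array([0.5]), 0.0, 1.0)
        with pytest.raises(ValidationError, match="insufficient"):
            acg.compute_acg(tr)

    def test_bad_cap_error(self, regular_train):
        with pytest.raises(ValidationError):
            acg.compute_acg(regular_train, spike_cap=1)


class TestSmoothAcg:
    def _make(self, counts):
        counts = np.asarray(counts, dtype=float)
        lags = (np.arange(len(counts)) + 0.5) * 0.0005
        return acg.Autocorrelogram(
            lags=lags, counts=counts, norm=counts / counts.mean() if counts.mean() else counts,
            bin_width=0.0005, n_spikes_used=10,
        )

    def test_impulse_becomes_plateau(self):
        counts = np.zeros(50)
        counts[20] = 5
        sm = acg.smooth_acg(self._make(counts), window=0.0025)
        np.testing.assert_allclose(sm.counts[18:23], 1.0)
        assert np.all(sm.counts[:18] == 0) and np.all(sm.counts[23:] == 0)

    def test_flat_acg_unchanged(self):
        sm = acg.smooth_acg(self._make(np.full(40, 3.0)), window=0.0025)
        np.testing.assert_allclose(sm.counts, 3.0, atol=1e-12)

    def test_matches_convolution_oracle(self, rng):
        counts = rng.integers(0, 20, size=200).astype(float)
        sm = acg.smooth_acg(self._make(counts), window=0.0025)
        # brute-force: shrink-to-valid 5-point average
        expected = np.array(
            [counts[max(0, i - 2) : i + 3].mean() for i in range(len(counts))]
        )
        np.testing.assert_allclose(sm.counts, expected, atol=1e-12)

    def test_interior_mass_preserved(self, rng):
        counts = rng.integers(0, 10, size=100).astype(float)
        sm = acg.smooth_acg(self._make(counts), window=0.0025)
        # a centered box filter conserves the sum away from the edges
        assert sm.counts[2:-2].sum() == pytest.approx(
            np.convolve(counts, np.ones(5) / 5, "valid").sum(), rel=1e-12
        )

    def test_misaligned_window_rejected(self):
        with pytest.raises(ValidationError):
            acg.smooth_acg(self._make(np.ones(40)), window=0.0012)


def _acg_from_values(values, bin_width=0.0005):
    values = np.asarray(values, dtype=float)
    lags = (np.arange(len(values)) + 0.5) * bin_width
    return acg.Autocorrelogram(
        lags=lags,
        counts=np.maximum(values, 0),
        norm=values,
        bin_width=bin_width,
        n_spikes_used=100,
    )


class TestBurstIndex:
    def test_flat_acg_zero(self):
        assert acg.burst_index(_acg_from_values(np.full(1000, 2.0))) == 0.0

    def test_empty_baseline_band_gives_one(self):
        values = np.zeros(1000)
        values[:50] = 3.0  # 0-25 ms occupied, 180-200 ms empty
        assert acg.burst_index(_acg_from_values(values)) == 1.0

    def test_bursting_train_exceeds_half_and_matches_formula(self):
        tr, _ = gen_bursting_train(
            burst_rate=0.3, spikes_per_burst=(4, 4), intra_isi=0.006, duration=600.0, seed=11
        )
        a = acg.compute_acg(tr)
        bi = acg.burst_index(a)
        assert bi > 0.5
        # independent evaluation of the formula on the brute-force histogram
        counts = brute_force_acg_counts(tr.times, 0.0005, 0.5).astype(float)
        norm = counts / counts.mean()
        lags = (np.arange(len(norm)) + 0.5) * 0.0005
        mb = norm[(lags >= 0) & (lags < 0.025)].max()
        bb = norm[(lags >= 0.180) & (lags < 0.200)].mean()
        assert bi == pytest.approx((mb - bb) / max(mb, bb), abs=1e-12)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValidationError):
            acg.burst_index(_acg_from_values(np.ones(1000)), (0.0, 0.2), (0.18, 0.2))

    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_bounds_and_scale_invariance(self, scale, seed):
        values = np.random.default_rng(seed).uniform(0, 5, size=1000)
        bi = acg.burst_index(_acg_from_values(values))
        assert -1.0 <= bi <= 1.0
        assert acg.burst_index(_acg_from_values(values * scale)) == pytest.approx(bi, abs=1e-9)


class TestThetaIndex:
    def test_flat_acg_zero(self):
        assert acg.theta_index(_acg_from_values(np.full(1000, 1.5))) == 0.0

    def test_raised_cosine_positive_and_matches_oracle(self):
        lags = (np.arange(1000) + 0.5) * 0.0005
        values = 1 + 0.5 * np.cos(2 * np.pi * lags / 0.150)  # 150 ms period
        a = _acg_from_values(values)
        ti = acg.theta_index(a)
        assert ti > 0
        # oracle: direct formula on the constructed array
        search = (lags >= 0.1) & (lags < 0.2)
        peak_lag = lags[search][np.argmax(values[search])]
        peak = values[(lags >= peak_lag - 0.025) & (lags < peak_lag + 0.025)].mean()
        flank = values[((lags >= 0.05) & (lags < 0.075)) | ((lags >= 0.225) & (lags < 0.25))].mean()
        assert ti == pytest.approx((peak - flank) / max(peak, flank), abs=1e-12)

    def test_trough_in_theta_band_negative(self):
        lags = (np.arange(1000) + 0.5) * 0.0005
        values = np.ones(1000)
        values[(lags >= 0.1) & (lags < 0.2)] = 0.2
        assert acg.theta_index(_acg_from_values(values)) < 0

    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_bounds_and_scale_invariance(self, scale, seed):
        values = np.random.default_rng(seed).uniform(0, 5, size=1000)
        ti = acg.theta_index(_acg_from_values(values))
        assert -1.0 <= ti <= 1.0
        assert acg.theta_index(_acg_from_values(values * scale)) == pytest.approx(ti, abs=1e-9)


class TestRefractoryPeriod:
    def test_step_edge_recovered_near_edge(self):
        lags = (np.arange(1000) + 0.5) * 0.0005
        values = np.where(lags < 0.010, 0.0, 1.0)
        rp = acg.refractory_period(_acg_from_values(values))
        assert 0.005 <= rp <= 0.015  # within the 10 ms smoothing half-window

    def test_flat_acg_zero(self):
        assert acg.refractory_period(_acg_from_values(np.full(1000, 1.0))) == 0.0

    def test_dead_time_train_recovered(self):
        tr, _ = gen_regular_theta_train(rate=4.0, dead_time=0.060, duration=900.0, seed=3)
        a = acg.compute_acg(tr)
        rp = acg.refractory_period(a)
        assert 0.045 <= rp <= 0.075

    def test_all_zero_acg_error(self):
        with pytest.raises(ValidationError, match="degenerate"):
            acg.refractory_period(_acg_from_values(np.zeros(1000)))


class TestClassification:
    @pytest.mark.parametrize(
        "bi,ti,refr,label",
        [
            (0.8, 0.0, 0.003, "Burst-SB"),
            (0.1, 0.3, 0.080, "Reg"),
            (0.1, -0.2, 0.080, "Burst-PL"),
            (0.2, 0.0, 0.005, "Burst-PL"),
            (np.nan, 0.0, 0.01, "unclassifiable"),
        ],
    )
    def test_rule(self, bi, ti, refr, label):
        assert acg.classify_firing_pattern(bi, ti, refr).label == label

    def test_generator_panel_recovery(self):
        """Bursting / Poisson-like / regular phenotypes recovered >= 90%."""
        correct = total = 0
        for seed in range(10):
            tr, _ = gen_bursting_train(duration=400.0, seed=seed)
            correct += _classify(tr) == "Burst-SB"
            total += 1
        for seed in range(10):
            tr, _ = gen_poisson_train(8.0, 400.0, seed=100 + seed)
            correct += _classify(tr) == "Burst-PL"
            total += 1
        for seed in range(5):
            tr, _ = gen_regular_theta_train(duration=900.0, seed=200 + seed)
            correct += _classify(tr) == "Reg"
            total += 1
        assert correct / total >= 0.9


def _classify(train):
    a = acg.compute_acg(train)
    sm = acg.smooth_acg(a)
    bi = acg.burst_index(sm)
    ti = acg.theta_index(sm)
    rp = acg.refractory_period(a)
    return acg.classify_firing_pattern(bi, ti, rp).label
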