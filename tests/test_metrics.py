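"""Peak metrics, LFP averaging, ranking and correlation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oisi
from oisi.core import LFPTrace, TimeCourse
from oisi.metrics import fit_gamma_kernel


def _tc(y, dt=0.2, onset=0.0, **kw):
    y = np.asarray(y, dtype=float)
    return TimeCourse(t=np.arange(y.size) * dt, y=y, stim_onset_s=onset, **kw)


# --- independent brute-force oracles -------------------------------------


def brute_percentile_95(values):
    """Sort-and-interpolate percentile (linear between order statistics)."""
    v = sorted(values)
    h = 0.95 * (len(v) - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def brute_peak_position(t, y, onset, amplitude):
    for ti, yi in zip(t, y):
        if ti >= onset and yi >= amplitude:
            return ti - onset
    raise AssertionError


def brute_half_recovery(t, y, t_peak, amplitude):
    target = 0.5 * amplitude
    prev_t = prev_y = None
    for ti, yi in zip(t, y):
        if ti < t_peak - 1e-9:  # same grid tolerance as the operator
            continue
        if prev_t is not None and yi <= target:
            if prev_y == yi:
                return ti - t_peak
            frac = (prev_y - target) / (prev_y - yi)
            return prev_t + frac * (ti - prev_t) - t_peak
        prev_t, prev_y = ti, yi
    return None


class TestPeakAmplitude:
    def test_constant_signal(self):
        assert oisi.peak_amplitude(_tc(np.full(30, 0.04))) == pytest.approx(4.0)

    def test_twenty_point_ramp_is_18_05(self):
        """0..19 -> the interpolated 95th percentile 18.05."""
        amp = oisi.peak_amplitude(_tc(np.arange(20.0)), as_percent=False)
        assert amp == pytest.approx(18.05, abs=1e-12)
        assert amp == pytest.approx(brute_percentile_95(np.arange(20.0)), abs=1e-12)

    @given(scale=st.floats(0.1, 50.0))
    def test_homogeneity(self, scale):
        y = np.sin(np.linspace(0, 3, 40))
        a1 = oisi.peak_amplitude(_tc(y), as_percent=False)
        a2 = oisi.peak_amplitude(_tc(scale * y), as_percent=False)
        assert a2 == pytest.approx(scale * a1, rel=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            oisi.peak_amplitude(_tc(np.ones(10)), window=(100.0, 101.0))


class TestPeakPosition:
    def test_monotone_ramp_peaks_at_trace_end(self):
        tc = _tc(np.linspace(0, 1, 26), onset=1.0)
        amp = oisi.peak_amplitude(tc, as_percent=False)
        pos = oisi.peak_position(tc, amp, amplitude_is_percent=False)
        expected = brute_peak_position(tc.t, tc.y, 1.0, amp)
        assert pos == expected

    def test_plateau_takes_first_crossing(self):
        y = np.array([0, 0, 1, 1, 1, 0, 0], dtype=float)
        tc = _tc(y)
        pos = oisi.peak_position(tc, 1.0, amplitude_is_percent=False)
        assert pos == pytest.approx(0.4)


class TestHalfRecovery:
    def test_symmetric_triangle(self):
        """Rise time R implies half-recovery R/2 after the peak."""
        y = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
        tc = _tc(y, dt=0.5)
        t05 = oisi.half_recovery(tc, 1.0, 5.0, amplitude_is_percent=False)
        assert t05 == pytest.approx(2.5, abs=1e-9)

    def test_exponential_decay_ln2_over_k(self):
        k = 0.13
        t = np.arange(0, 60, 0.2)
        y = np.exp(-k * np.maximum(t - 4.0, 0.0))
        tc = TimeCourse(t=t, y=y, stim_onset_s=0.0)
        t05 = oisi.half_recovery(tc, 1.0, 4.0, amplitude_is_percent=False)
        assert t05 == pytest.approx(np.log(2) / k, abs=0.2)

    def test_never_recovering_trace_is_unresolved(self):
        tc = _tc(np.ones(30))
        assert oisi.half_recovery(tc, 1.0, 1.0, amplitude_is_percent=False) is None

    def test_neonatal_scattering_trace_recovers_at_25s(self, bands):
        c = oisi.simulate_chromophores(oisi.NEONATAL)
        tc = TimeCourse(t=c.t, y=c.d_s, stim_onset_s=c.stim_onset_s, polarity="raw")
        amp = float(c.d_s.max())
        peak = float(c.t[np.argmax(c.d_s)] - c.stim_onset_s)
        t05 = oisi.half_recovery(tc, amp, peak, amplitude_is_percent=False)
        assert t05 == pytest.approx(25.0, abs=0.2)


def test_metric_operators_match_brute_force_on_random_traces():
    """Percentile / first-crossing / half-recovery vs O(n^2) reimplementations."""
    rng = np.random.default_rng(12)
    for _ in range(1000):
        n = rng.integers(20, 60)
        y = rng.normal(0, 1, n).cumsum() / 5.0
        tc = _tc(y, dt=0.2, onset=0.4)
        amp = oisi.peak_amplitude(tc, as_percent=False)
        assert amp == pytest.approx(
            brute_percentile_95(y[tc.t >= 0.4]), abs=1e-12
        )
        pos = oisi.peak_position(tc, amp, amplitude_is_percent=False)
        assert pos == pytest.approx(
            brute_peak_position(tc.t, tc.y, 0.4, amp - 1e-15), abs=1e-12
        )
        # half-recovery presumes a positive-going response peaking before trace end
        if amp > 0 and 0.4 + pos < tc.t[-1]:
            t05 = oisi.half_recovery(tc, amp, pos, amplitude_is_percent=False)
            oracle = brute_half_recovery(tc.t, tc.y, 0.4 + pos, amp)
            if t05 is None:
                assert oracle is None
            else:
                assert t05 == pytest.approx(oracle, abs=1e-9)


class TestAverageLFP:
    def test_flat_zero(self):
        lfp = LFPTrace(t=np.arange(0, 20, 0.001), v=np.zeros(20000), stim_onset_s=5.0, stim_rate_hz=1.0)
        assert oisi.average_lfp(lfp, (5.0, 15.0)) == 0.0

    def test_constant_magnitude(self):
        t = np.arange(0, 20, 0.001)
        lfp = LFPTrace(t=t, v=np.full(t.size, -40.0), stim_onset_s=5.0, stim_rate_hz=1.0)
        assert oisi.average_lfp(lfp, (5.0, 15.0)) == pytest.approx(40.0, rel=1e-9)

    def test_linearity(self):
        t = np.arange(0, 20, 0.001)
        v = np.sin(t)
        a1 = oisi.average_lfp(LFPTrace(t=t, v=v, stim_onset_s=5, stim_rate_hz=1), (5, 15))
        a2 = oisi.average_lfp(LFPTrace(t=t, v=2 * v, stim_onset_s=5, stim_rate_hz=1), (5, 15))
        assert a2 == pytest.approx(2 * a1, rel=1e-12)


class TestRateRanking:
    def test_top_three_by_amplitude(self):
        amps = {1.0: 0.1, 2.0: 0.3, 5.0: 0.2, 10.0: 0.05}
        assert oisi.rank_stimulation_rates(amps) == [2.0, 5.0, 1.0]

    def test_ties_break_toward_lower_rate(self):
        amps = {10.0: 0.2, 1.0: 0.2, 5.0: 0.2, 2.0: 0.2}
        assert oisi.rank_stimulation_rates(amps) == [1.0, 2.0, 5.0]

    def test_input_order_irrelevant(self):
        amps = {1.0: 0.1, 2.0: 0.3, 5.0: 0.2, 10.0: 0.05}
        shuffled = dict(reversed(list(amps.items())))
        assert oisi.rank_stimulation_rates(shuffled) == oisi.rank_stimulation_rates(amps)

    def test_fewer_than_three_rates_rejected(self):
        with pytest.raises(ValueError):
            oisi.rank_stimulation_rates({1.0: 0.1, 2.0: 0.2})


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert oisi.pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert oisi.pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_optimal_rates_vs_age_centers(self):
        """Seven printed optimal rates vs. age-group centers correlate at 0.65."""
        rates = [1, 1, 2, 5, 10, 10, 10]
        centers = [4.5, 6.5, 9.0, 12.5, 16.5, 23.0, 75.0]
        assert round(oisi.pearson_correlation(rates, centers), 2) == 0.65

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            oisi.pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_saturating_amplitude_lfp_link_stays_correlated(self):
        """OIS amplitude vs. average LFP with a saturating link + noise: r >= 0.6
        in at least 90% of seeds (monotone coupling survives measurement noise)."""
        good = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            lfp = rng.uniform(5.0, 80.0, 200)
            amp = 0.1 * lfp / (lfp + 30.0) + rng.normal(0, 0.015, 200)
            if oisi.pearson_correlation(lfp, amp) >= 0.6:
                good += 1
        assert good >= 18


class TestGammaKernelFit:
    def test_recovers_clean_kernel_parameters(self):
        c = oisi.simulate_chromophores(oisi.NEONATAL)
        tc = TimeCourse(t=c.t, y=c.d_s, stim_onset_s=c.stim_onset_s, polarity="raw")
        fit = fit_gamma_kernel(tc)
        assert fit.peak_time_s == pytest.approx(10.0, abs=0.01)
        assert fit.half_recovery_s == pytest.approx(25.0, abs=0.05)
        assert fit.amplitude == pytest.approx(oisi.NEONATAL.ls_amp, rel=1e-3)

    def test_fits_delayed_negative_response(self):
        c = oisi.simulate_chromophores(oisi.NEONATAL)
        tc = TimeCourse(t=c.t, y=c.d_hbr, stim_onset_s=c.stim_onset_s, polarity="raw")
        fit = fit_gamma_kernel(tc, fit_delay=True, flip=True)
        assert fit.peak_time_s == pytest.approx(30.0, abs=0.1)
        assert fit.amplitude == pytest.approx(oisi.NEONATAL.hbr_amp, rel=1e-2)
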