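"""Trend indices: windowed-mean equivalences, wavelet MRA, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupiltrend import (
    binocular_trend,
    conservative_trend,
    decomposed_trend,
    moving_average,
    mra_decompose,
    px_to_mm,
    smoothed_trend,
)
from pupiltrend.trends import TrendValue

from conftest import make_series


def window_mean_oracle(series, t_lo, t_hi):
    """Independent inclusive-index window mean (the documented convention)."""
    rate = series.sample_rate / 1000.0
    i = int(round((t_lo - series.t[0]) * rate))
    j = int(round((t_hi - series.t[0]) * rate))
    return series.value[i : j + 1].mean()


class TestMovingAverage:
    def test_constant_preserved(self):
        s = make_series(np.full(20000, 7.5))
        ma = moving_average(s, 5.0)
        assert np.nanmax(np.abs(ma - 7.5)) < 1e-12

    def test_ramp_preserved_at_interior(self):
        t_s = np.arange(30000) / 1000.0
        s = make_series(2.0 * t_s)
        ma = moving_average(s, 10.0)
        interior = slice(5000, 25000)
        assert np.max(np.abs(ma[interior] - 2.0 * t_s[interior])) < 1e-9

    def test_matches_brute_force_windowed_means(self, rng):
        s = make_series(3000 + 50 * rng.standard_normal(60000))
        ma = moving_average(s, 10.0)
        h = 5000
        for j in rng.integers(h, 60000 - h, size=100):
            assert ma[j] == pytest.approx(s.value[j - h : j + h + 1].mean(), abs=1e-9)

    def test_edges_unavailable_not_partial(self):
        s = make_series(np.arange(12000, dtype=float))
        ma = moving_average(s, 10.0)
        assert np.isnan(ma[:5000]).all() and np.isnan(ma[-5000:]).all()

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError, match="window too long"):
            moving_average(make_series(np.ones(500)), 10.0)


class TestSmoothedTrend:
    def test_constant_gives_zero(self):
        s = make_series(np.full(40000, 3000.0))
        for w in (5.0, 10.0, 15.0):
            assert smoothed_trend(s, 20000, w).value_px == pytest.approx(0.0, abs=1e-9)

    def test_ramp_analytic_value(self):
        # slope 1 px/s, 10 s window -> trend = 10 px
        t_s = np.arange(40000) / 1000.0
        s = make_series(t_s)
        tv = smoothed_trend(s, 20000, 10.0)
        assert tv.value_px == pytest.approx(10.0, abs=1e-6)

    def test_full_period_sinusoid_cancels(self):
        # 1 Hz sinusoid, amplitude 50 px, event at an integer second
        t_s = np.arange(40000) / 1000.0
        s = make_series(50 * np.sin(2 * np.pi * t_s))
        tv = smoothed_trend(s, 20000, 10.0)
        assert abs(tv.value_px) < 1e-6

    def test_equals_two_window_means_difference(self, rng):
        s = make_series(3000 + 40 * rng.standard_normal(50000))
        t0 = 25000.0
        tv = smoothed_trend(s, t0, 10.0)
        oracle = window_mean_oracle(s, t0, t0 + 10000) - window_mean_oracle(s, t0 - 10000, t0)
        assert tv.value_px == pytest.approx(oracle, abs=1e-9)

    def test_matches_moving_average_readout(self, rng):
        """smoothed trend == centered moving average at +w/2 minus at -w/2."""
        s = make_series(3000 + 40 * rng.standard_normal(50000))
        ma = moving_average(s, 10.0)
        tv = smoothed_trend(s, 25000.0, 10.0)
        assert tv.value_px == pytest.approx(ma[30000] - ma[20000], abs=1e-9)

    def test_incomplete_near_edge(self):
        s = make_series(np.ones(30000))
        assert smoothed_trend(s, 4000, 10.0).quality == "incomplete"

    def test_event_outside_recording_errors(self):
        s = make_series(np.ones(1000))
        with pytest.raises(ValueError, match="event outside"):
            smoothed_trend(s, 5000, 0.5)

    def test_rejected_when_flanks_mostly_interpolated(self):
        interp = np.zeros(50000, dtype=bool)
        interp[10000:24000] = True  # most of the pre-event window
        s = make_series(np.ones(50000), interpolated=interp)
        assert smoothed_trend(s, 25000, 10.0).quality == "rejected"

    def test_linearity_and_constant_invariance(self, rng):
        x = 30 * rng.standard_normal(50000)
        y = 30 * rng.standard_normal(50000)
        sx, sy = make_series(x), make_series(y)
        sxy = make_series(2 * x - 3 * y)
        t0 = 25000.0
        for w in (5.0, 10.0):
            vx = smoothed_trend(sx, t0, w).value_px
            vy = smoothed_trend(sy, t0, w).value_px
            vxy = smoothed_trend(sxy, t0, w).value_px
            assert vxy == pytest.approx(2 * vx - 3 * vy, abs=1e-9)
            shifted = smoothed_trend(make_series(x + 1234.5), t0, w).value_px
            assert shifted == pytest.approx(vx, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        offset=st.floats(-1e4, 1e4, allow_nan=False),
        scale=st.floats(0.1, 100.0),
    )
    def test_affine_input_maps_affinely(self, seed, offset, scale):
        """trend(a*x + c) == a*trend(x) for every window: the indices are
        linear and offset-free."""
        rng = np.random.default_rng(seed)
        x = 50 * rng.standard_normal(30000)
        base = smoothed_trend(make_series(x), 15000.0, 10.0).value_px
        mapped = smoothed_trend(make_series(scale * x + offset), 15000.0, 10.0).value_px
        assert mapped == pytest.approx(scale * base, rel=1e-9, abs=1e-7)

    def test_fast_sinusoid_attenuated_by_boxcar(self):
        """A 2 Hz carrier leaves at most the boxcar-attenuated amplitude."""
        t_s = np.arange(60000) / 1000.0
        amp, f, w = 50.0, 2.0, 10.0
        s = make_series(amp * np.sin(2 * np.pi * f * (t_s + 0.1234)))
        # each window mean is bounded by amp/(pi f w); trend by twice that
        bound = 2 * amp / (np.pi * f * w) * 1.05
        tv = smoothed_trend(s, 30000.0, w)
        assert abs(tv.value_px) < bound


class TestConservativeTrend:
    def test_constant_zero(self):
        s = make_series(np.full(40000, 3000.0))
        assert conservative_trend(s, 20000).value_px == pytest.approx(0.0, abs=1e-9)

    def test_ramp_analytic_14s_span(self):
        # windows centered at +-7 s -> slope 1 px/s gives 14 px
        t_s = np.arange(40000) / 1000.0
        assert conservative_trend(make_series(t_s), 20000).value_px == pytest.approx(14.0, abs=1e-6)

    def test_exact_transient_immunity(self, rng):
        """Any signal confined to (t0-2 s, t0+2 s) contributes exactly 0."""
        base = np.full(40000, 3000.0)
        for _ in range(20):
            x = base.copy()
            lo = 20000 - 1500 + rng.integers(0, 500)
            width = rng.integers(100, 2500)
            hi = min(lo + width, 20000 + 1500)
            x[lo:hi] += 500 * rng.standard_normal(hi - lo)
            tv = conservative_trend(make_series(x), 20000)
            assert tv.value_px == 0.0

    def test_matches_window_mean_oracle(self, rng):
        s = make_series(3000 + 40 * rng.standard_normal(50000))
        t0 = 25000.0
        oracle = window_mean_oracle(s, t0 + 2000, t0 + 12000) - window_mean_oracle(
            s, t0 - 12000, t0 - 2000
        )
        assert conservative_trend(s, t0).value_px == pytest.approx(oracle, abs=1e-9)


class TestMRA:
    def test_constant_series_all_details_near_zero(self):
        s = make_series(np.full(140000, 2500.0))
        comp = mra_decompose(s, 32768.0)
        for scale, d in comp.details.items():
            assert np.max(np.abs(d)) < 1e-6 * 2500.0, scale
        assert comp.approximation == pytest.approx(2500.0, abs=1e-3)

    def test_reconstruction_within_tolerance(self, rng):
        s = make_series(3000 + 50 * rng.standard_normal(100000))
        comp = mra_decompose(s, 32768.0)
        err = np.max(np.abs(comp.reconstruct() - s.value)) / np.max(np.abs(s.value))
        assert err < 1e-6

    def test_details_near_zero_mean(self, rng):
        s = make_series(3000 + 50 * rng.standard_normal(100000))
        comp = mra_decompose(s, 32768.0)
        for scale, d in comp.details.items():
            # the coarsest level fits only a few oscillations into the
            # session, so "near-zero" is relative to the component's spread
            assert abs(d.mean()) < 0.2 * d.std() + 1e-9

    def test_energy_concentrates_in_matching_band(self):
        """A sinusoid with period interior to the level passband lands
        mostly in that component; a period exactly at the dyadic band edge
        splits between the two adjacent components."""
        n = 300000
        t = np.arange(n, dtype=float)
        interior = np.sin(2 * np.pi * t / 11585.0)  # 2^13.5 samples
        comp = mra_decompose(make_series(interior), 32768.0)
        en = {k: float(np.sum(v**2)) for k, v in comp.details.items()}
        tot = sum(en.values())
        assert en[8192.0] / tot > 0.6
        edge = np.sin(2 * np.pi * t / 8192.0)
        comp = mra_decompose(make_series(edge), 32768.0)
        en = {k: float(np.sum(v**2)) for k, v in comp.details.items()}
        tot = sum(en.values())
        assert (en[4096.0] + en[8192.0]) / tot > 0.95

    def test_series_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            mra_decompose(make_series(np.ones(1000)), 32768.0)

    def test_non_dyadic_scale_rejected(self):
        with pytest.raises(ValueError, match="dyadic"):
            mra_decompose(make_series(np.ones(100000)), 10000.0)

    def test_scale_labels_follow_sample_rate(self):
        """At 250 Hz the dyadic scales are still labelled in ms."""
        s = make_series(np.ones(40000), rate=250.0)
        comp = mra_decompose(s, 32768.0)
        assert 32768.0 in comp.details and 4096.0 in comp.details
        assert min(comp.details) == pytest.approx(8.0)  # 2 samples at 4 ms


class TestDecomposedTrend:
    def test_constant_zero_every_scale(self):
        comp = mra_decompose(make_series(np.full(140000, 2500.0)), 32768.0)
        for scale in (4096.0, 8192.0, 16384.0, 32768.0):
            tv = decomposed_trend(comp, 70000.0, scale)
            assert tv.value_px == pytest.approx(0.0, abs=1e-6)

    def test_equals_two_point_readout_of_component(self, rng):
        s = make_series(3000 + 50 * rng.standard_normal(140000))
        comp = mra_decompose(s, 32768.0)
        t0, scale = 70000.0, 8192.0
        tv = decomposed_trend(comp, t0, scale)
        d = comp.details[scale]
        assert tv.value_px == pytest.approx(d[70000 + 4096] - d[70000 - 4096], abs=1e-12)

    def test_rising_oscillation_reads_positive(self):
        """Readout spacing of half the oscillation period at a rising zero
        crossing captures trough-to-peak: positive by construction."""
        n = 300000
        t = np.arange(n, dtype=float)
        scale = 8192.0
        x = 50 * np.sin(2 * np.pi * t / (2 * scale))
        comp = mra_decompose(make_series(x), 32768.0)
        t0 = (n // 2 // int(2 * scale)) * 2 * scale  # rising zero crossing
        tv = decomposed_trend(comp, t0, scale)
        assert tv.value_px > 10.0

    def test_unsupported_scale_lists_alternatives(self):
        comp = mra_decompose(make_series(np.full(140000, 1.0)), 32768.0)
        with pytest.raises(ValueError, match="supported scales"):
            decomposed_trend(comp, 70000.0, 5000.0)

    def test_boundary_readout_incomplete(self):
        comp = mra_decompose(make_series(np.full(140000, 1.0)), 32768.0)
        assert decomposed_trend(comp, 20000.0, 32768.0).quality == "incomplete"


class TestBinocularAndCalibration:
    def tv(self, value, quality="complete"):
        return TrendValue("t1", "smoothed", 10000.0, value, "left", quality)

    def test_mean_of_two_complete_eyes(self):
        out = binocular_trend(self.tv(10.0), self.tv(20.0))
        assert out.value_px == 15.0 and out.eye == "binocular" and not out.monocular

    def test_single_eye_flagged_monocular(self):
        out = binocular_trend(self.tv(10.0), self.tv(np.nan, "rejected"))
        assert out.value_px == 10.0 and out.monocular

    def test_both_rejected_is_rejected(self):
        out = binocular_trend(self.tv(np.nan, "rejected"), self.tv(np.nan, "incomplete"))
        assert out.quality == "rejected"

    def test_mismatched_metadata_rejected(self):
        other = TrendValue("t2", "smoothed", 10000.0, 1.0, "right", "complete")
        with pytest.raises(ValueError, match="mismatched"):
            binocular_trend(self.tv(1.0), other)

    @pytest.mark.parametrize(
        "px,expected",
        [(51.13, 0.070), (3300.0, 4.5), (0.0, 0.0), (59.23, 0.081), (56.61, 0.077)],
    )
    def test_pixel_calibration(self, px, expected):
        """3,300 px corresponds to 4.5 mm; printed trend differences map to
        their printed mm equivalents at 3 decimals."""
        assert round(px_to_mm(px), 3) == pytest.approx(expected, abs=5e-4)

    def test_nonpositive_calibration_rejected(self):
        with pytest.raises(ValueError):
            px_to_mm(10.0, calib_px=0.0)
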