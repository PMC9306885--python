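"""Blink handling, filtering, downsampling, z-transform and minute bins."""

import numpy as np
import pytest

from vigilpupil import preprocess
from vigilpupil.preprocess import (
    SampleSeries,
    detect_blinks,
    downsample,
    extend_and_interpolate,
    lowpass_butterworth,
    minute_bins,
    zscore_series,
)


def make_series(pupil, rate=250, t0=0.0):
    return SampleSeries(rate, t0, np.asarray(pupil, dtype=float))


class TestDetectBlinks:
    def test_clean_series_has_no_blinks(self):
        assert detect_blinks(make_series(np.full(1000, 4000.0))) == []

    def test_single_run_detected_with_exact_extent(self):
        pupil = np.full(1000, 4000.0)
        pupil[100:151] = 0.0
        (b,) = detect_blinks(make_series(pupil))
        assert b.start_ms == 100 * 4.0
        assert b.end_ms == 151 * 4.0  # 51 samples = 204 ms

    def test_runs_at_series_edges(self):
        pupil = np.full(100, 4000.0)
        pupil[:10] = 0.0
        pupil[-5:] = 0.0
        blinks = detect_blinks(make_series(pupil))
        assert len(blinks) == 2
        assert blinks[0].start_ms == 0.0
        assert blinks[1].end_ms == 100 * 4.0

    def test_matches_bruteforce_run_scanner(self, rng):
        pupil = np.full(2000, 4000.0)
        for start in rng.integers(0, 1900, size=15):
            pupil[start:start + int(rng.integers(1, 60))] = 0.0
        blinks = detect_blinks(make_series(pupil))
        # brute-force oracle: scan every sample
        covered = np.zeros(2000, dtype=bool)
        for b in blinks:
            covered[int(b.start_ms / 4):int(b.end_ms / 4)] = True
        np.testing.assert_array_equal(covered, pupil == 0.0)
        # maximality: each interval is flanked by valid samples
        for b in blinks:
            i0, i1 = int(b.start_ms / 4), int(b.end_ms / 4)
            if i0 > 0:
                assert pupil[i0 - 1] != 0.0
            if i1 < 2000:
                assert pupil[i1] != 0.0


class TestExtendAndInterpolate:
    def test_linear_reconstruction_between_boundaries(self):
        pupil = np.full(1000, 4000.0)
        pupil[250:300] = 0.0  # 1000-1200 ms at 250 Hz
        pupil[:250] = 4000.0
        pupil[300:] = 4200.0
        s = make_series(pupil)
        out = extend_and_interpolate(s, detect_blinks(s), pad_ms=100.0)
        # widened interval: 900-1300 ms -> indices 225..325
        assert out.interp_mask[225:325].all()
        assert not out.interp_mask[:225].any() and not out.interp_mask[326:].any()
        mid = out.pupil[275]
        lo, hi = out.pupil[224], out.pupil[325]
        assert lo <= mid <= hi
        inside = out.pupil[225:325]
        assert np.all(np.diff(inside) >= -1e-9)  # monotone between boundaries

    def test_pad_widens_200ms_blink_to_400ms_of_mask(self):
        pupil = np.full(2000, 4000.0)
        pupil[500:550] = 0.0  # 200 ms
        s = make_series(pupil)
        out = extend_and_interpolate(s, detect_blinks(s), pad_ms=100.0)
        assert out.interp_mask.sum() == 100  # 400 ms at 250 Hz

    def test_close_runs_merge_after_extension(self):
        pupil = np.full(1000, 4000.0)
        pupil[100:110] = 0.0
        pupil[111:120] = 0.0  # one valid sample apart
        s = make_series(pupil)
        out = extend_and_interpolate(s, detect_blinks(s), pad_ms=100.0)
        covered = np.flatnonzero(out.interp_mask)
        assert np.all(np.diff(covered) == 1)  # a single merged interval

    def test_mask_fraction_matches_interval_union_oracle(self, short_session):
        raw = short_session["raw"]
        blinks = detect_blinks(raw)
        out = extend_and_interpolate(raw, blinks, pad_ms=100.0)
        # independent interval-union computation in continuous time
        n = raw.pupil.size
        covered = np.zeros(n, dtype=bool)
        for b in blinks:
            i0 = max(int(np.floor((b.start_ms - 100.0) / 4.0)), 0)
            i1 = min(int(np.ceil((b.end_ms + 100.0) / 4.0)), n)
            covered[i0:i1] = True
        assert out.interp_mask.mean() == pytest.approx(covered.mean())

    def test_edge_blink_filled_with_nearest_valid(self):
        pupil = np.full(500, 4000.0)
        pupil[:50] = 0.0
        pupil[100:] = 4100.0
        s = make_series(pupil)
        out = extend_and_interpolate(s, detect_blinks(s), pad_ms=100.0)
        assert np.all(np.isfinite(out.pupil))
        assert out.pupil[0] == pytest.approx(4000.0)

    def test_total_blink_coverage_is_an_error(self):
        s = make_series(np.zeros(100))
        with pytest.raises(preprocess.PreprocessError):
            extend_and_interpolate(s, detect_blinks(s))


class TestButterworth:
    def test_dc_gain_unity(self):
        s = make_series(np.full(2000, 1234.5))
        out = lowpass_butterworth(s)
        np.testing.assert_allclose(out.pupil, 1234.5)

    @pytest.mark.parametrize(
        "freq,limit,mode",
        [(20.0, 0.05, "stop"), (0.5, 0.02, "pass")],
    )
    def test_magnitude_response(self, freq, limit, mode):
        """20 Hz is attenuated below 5%; 0.5 Hz passes within 2%."""
        t = np.arange(0, 20.0, 1 / 250.0)
        s = make_series(np.sin(2 * np.pi * freq * t))
        out = lowpass_butterworth(s)
        amp = np.abs(out.pupil[1000:-1000]).max()
        if mode == "stop":
            assert amp < limit
        else:
            assert abs(amp - 1.0) < limit

    def test_cutoff_above_nyquist_rejected(self):
        s = make_series(np.zeros(100), rate=50)
        with pytest.raises(preprocess.PreprocessError):
            lowpass_butterworth(s, cutoff_hz=30.0)

    def test_additive_constant_commutes(self, rng):
        x = rng.normal(size=3000)
        a = lowpass_butterworth(make_series(x)).pupil
        b = lowpass_butterworth(make_series(x + 100.0)).pupil
        np.testing.assert_allclose(a + 100.0, b, atol=1e-8)


class TestDownsample:
    def test_block_mean_and_length(self):
        s = make_series(np.array([1, 2, 3, 4, 5] * 10, dtype=float))
        out = downsample(s, target_hz=50)
        assert out.pupil.size == 10
        np.testing.assert_allclose(out.pupil, 3.0)

    def test_mask_any_propagation(self):
        s = make_series(np.zeros(10))
        s.interp_mask[3] = True
        out = downsample(s, target_hz=50)
        assert out.interp_mask.tolist() == [True, False]

    def test_non_divisible_rate_rejected(self):
        with pytest.raises(preprocess.PreprocessError):
            downsample(make_series(np.zeros(100)), target_hz=60)


class TestZScoreAndBins:
    def test_zero_mean_unit_population_sd(self, rng):
        out = zscore_series(make_series(rng.normal(4000, 100, 5000)))
        assert out.pupil.mean() == pytest.approx(0.0, abs=1e-10)
        assert out.pupil.std() == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=1000)
        a = zscore_series(make_series(x)).pupil
        b = zscore_series(make_series(3.5 * x + 200.0)).pupil
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_matches_two_pass_oracle(self, short_session):
        s = short_session["series_au"]
        out = zscore_series(s)
        mean = sum(s.pupil) / s.pupil.size
        var = sum((v - mean) ** 2 for v in s.pupil) / s.pupil.size
        np.testing.assert_allclose(out.pupil, (s.pupil - mean) / np.sqrt(var),
                                   atol=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(preprocess.PreprocessError):
            zscore_series(make_series(np.full(100, 7.0)))

    def test_minute_bins_count_and_oracle(self, short_session):
        z = short_session["series_z"]
        bins = minute_bins(z)
        assert bins.size == 6  # six-minute session
        per_min = z.rate_hz * 60
        expected = [z.pupil[i * per_min:(i + 1) * per_min].mean() for i in range(6)]
        np.testing.assert_allclose(bins, expected)

    def test_constant_zero_series_gives_zero_bins(self):
        z = make_series(np.zeros(50 * 90), rate=50)
        np.testing.assert_allclose(minute_bins(z), 0.0)
        assert minute_bins(z).size == 2  # trailing partial minute included


class TestPipelineOrder:
    def test_stage_order_is_detect_interp_filter_downsample_z(self, monkeypatch):
        calls = []
        orig = dict(
            detect_blinks=preprocess.detect_blinks,
            extend_and_interpolate=preprocess.extend_and_interpolate,
            lowpass_butterworth=preprocess.lowpass_butterworth,
            downsample=preprocess.downsample,
            zscore_series=preprocess.zscore_series,
        )
        for name, fn in orig.items():
            def wrapper(*a, __name=name, __fn=fn, **k):
                calls.append(__name)
                return __fn(*a, **k)
            monkeypatch.setattr(preprocess, name, wrapper)
        rng = np.random.default_rng(0)
        raw = make_series(rng.normal(4000, 50, 250 * 10))
        preprocess.preprocess_session(raw)
        assert calls == ["detect_blinks", "extend_and_interpolate",
                         "lowpass_butterworth", "downsample", "zscore_series"]

    def test_session_interpolated_fraction_in_plausible_band(self, short_session):
        frac = short_session["series_au"].interpolated_fraction
        assert 0.02 <= frac <= 0.15
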