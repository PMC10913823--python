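import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsfc.montage import default_montage
from nirsfc.preprocess import (
    MbllParams,
    QcParams,
    WaveletParams,
    bandpass,
    flag_saturation,
    forward_mbll,
    intensity_to_od,
    mbll,
    prune_channels,
    sci_psp_windows,
    wavelet_motion_correct,
)
from nirsfc.recording import OdRecording

from conftest import toy_raw


def toy_od(series, fs=25.0):
    """(n_ch, 2, T) OD record from an array, with empty accelerometer."""
    od = np.asarray(series, dtype=float)
    return OdRecording(od=od, accelerometer=np.zeros((3, od.shape[2])),
                       annotations=[], sampling_rate_hz=fs)


class TestIntensityToOd:
    def test_constant_intensity_gives_zero_od(self):
        raw = toy_raw(np.full((1, 2, 100), 7.3))
        od = intensity_to_od(raw)
        assert np.allclose(od.od, 0.0)
        assert od.stage == "od"

    def test_matches_direct_recomputation(self, rng):
        I = rng.uniform(0.5, 2.0, (3, 2, 200))
        raw = toy_raw(I)
        od = intensity_to_od(raw)
        want = -np.log(I / I.mean(axis=2, keepdims=True))
        assert np.allclose(od.od, want, atol=1e-12)

    def test_od_is_zero_mean_up_to_jensen_term(self, rng):
        # mean(OD) = -mean(ln I) + ln(mean I) >= 0, small for small fluctuations
        I = np.exp(rng.normal(0, 0.01, (1, 2, 500)))
        od = intensity_to_od(toy_raw(I))
        assert np.abs(od.od.mean()) < 1e-3

    def test_nonpositive_sample_identified(self):
        I = np.ones((2, 2, 50))
        I[1, 0, 7] = 0.0
        with pytest.raises(ValueError, match="channel 2.*sample 7"):
            intensity_to_od(toy_raw(I))


class TestWaveletCorrection:
    fs = 25.0

    def test_low_frequency_sinusoid_passes_unchanged(self):
        t = np.arange(0, 120, 1 / self.fs)
        x = np.sin(2 * np.pi * 0.05 * t)
        od = toy_od(x[None, None, :] * np.ones((1, 2, 1)))
        out = wavelet_motion_correct(od)
        rms_change = np.sqrt(np.mean((out.od - od.od) ** 2)) / np.sqrt(np.mean(od.od**2))
        assert rms_change <= 0.02

    def test_spike_suppressed_sinusoid_preserved(self):
        t = np.arange(0, 120, 1 / self.fs)
        sine = np.sin(2 * np.pi * 0.05 * t)
        spike = 10.0 * np.exp(-0.5 * ((t - 60.0) / 0.2) ** 2)
        od = toy_od((sine + spike)[None, None, :] * np.ones((1, 2, 1)))
        out = wavelet_motion_correct(od)
        # independent peak measurement: excess over the clean sinusoid near the spike
        region = (t > 58) & (t < 62)
        peak_before = np.max(np.abs((sine + spike - sine))[region])
        peak_after = np.max(np.abs(out.od[0, 0] - sine)[region])
        assert peak_after <= 0.2 * peak_before
        away = t < 50
        rms_in = np.sqrt(np.mean(sine[away] ** 2))
        rms_out = np.sqrt(np.mean(out.od[0, 0][away] ** 2))
        assert abs(rms_out - rms_in) / rms_in <= 0.10

    def test_all_zero_signal_stays_zero(self):
        out = wavelet_motion_correct(toy_od(np.zeros((1, 2, 300))))
        assert np.allclose(out.od, 0.0)

    def test_idempotent_within_one_percent(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 120, 1 / self.fs)
        x = np.sin(2 * np.pi * 0.03 * t) + 5.0 * (t > 60)  # step artifact
        x = x + 0.05 * rng.standard_normal(t.size)
        once = wavelet_motion_correct(toy_od(x[None, None, :] * np.ones((1, 2, 1))))
        twice = wavelet_motion_correct(once)
        denom = np.sqrt(np.mean(once.od**2))
        assert np.sqrt(np.mean((twice.od - once.od) ** 2)) / denom <= 0.01

    def test_short_series_passes_through_with_warning(self):
        od = toy_od(np.ones((1, 2, 3)))
        with pytest.warns(UserWarning, match="too short"):
            out = wavelet_motion_correct(od, WaveletParams(max_level=0))
        assert np.allclose(out.od, od.od)

    def test_invalid_iqr_rejected(self):
        with pytest.raises(ValueError):
            WaveletParams(iqr_multiplier=0.0)


class TestSciPsp:
    fs = 25.0

    def _od_two_wavelengths(self, w1, w2):
        return toy_od(np.stack([w1, w2])[None, :, :], fs=self.fs)

    def test_identical_cardiac_gives_sci_one_everywhere(self):
        t = np.arange(0, 30, 1 / self.fs)
        cardiac = np.sin(2 * np.pi * 1.2 * t)
        res = sci_psp_windows(self._od_two_wavelengths(cardiac, cardiac))
        sci, psp = res[1]
        assert np.all(np.abs(sci - 1.0) < 1e-6)
        assert np.all(psp > 0.06)  # strong cardiac peak

    def test_negated_wavelength_gives_sci_minus_one(self):
        t = np.arange(0, 30, 1 / self.fs)
        cardiac = np.sin(2 * np.pi * 1.2 * t)
        sci, _ = sci_psp_windows(self._od_two_wavelengths(cardiac, -cardiac))[1]
        assert np.all(np.abs(sci + 1.0) < 1e-6)

    def test_independent_noise_gives_low_sci_and_psp(self, rng):
        n = int(60 * 3 * self.fs)  # 60 windows
        w1, w2 = rng.standard_normal((2, n))
        sci, psp = sci_psp_windows(self._od_two_wavelengths(w1, w2))[1]
        assert len(sci) >= 50
        # null |SCI| scale for band-limited 3-s windows is ~sqrt(2/(pi*dof)) ~ 0.23
        assert np.mean(np.abs(sci)) < 0.3
        assert abs(np.mean(sci)) < 0.1
        assert np.mean(sci > 0.6) < 0.1
        assert np.median(psp) < 0.06

    def test_zero_variance_window_scores_zero(self):
        n = int(6 * self.fs)
        od = self._od_two_wavelengths(np.zeros(n), np.zeros(n))
        sci, psp = sci_psp_windows(od)[1]
        assert np.all(sci == 0.0)
        assert np.all(psp == 0.0)

    def test_trailing_partial_window_discarded(self):
        n = int(3.8 * 3 * self.fs)  # 3 full windows + remainder... 3*3s=225 samples
        t = np.arange(n) / self.fs
        cardiac = np.sin(2 * np.pi * 1.2 * t)
        sci, _ = sci_psp_windows(self._od_two_wavelengths(cardiac, cardiac))[1]
        assert len(sci) == n // int(3 * self.fs)

    def test_shorter_than_one_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sci_psp_windows(self._od_two_wavelengths(np.zeros(10), np.zeros(10)))


class TestPruneChannels:
    def _windows(self, sci, psp):
        return {5: (np.asarray(sci, dtype=float), np.asarray(psp, dtype=float))}

    def test_all_good_windows_kept(self):
        report = prune_channels(self._windows([0.9] * 10, [0.5] * 10))
        assert report.channels[5].keep

    def test_sixty_percent_boundary_is_strict(self):
        bad_sci = [0.1] * 61 + [0.9] * 39
        bad_psp = [0.01] * 61 + [0.5] * 39
        drop = prune_channels(self._windows(bad_sci, bad_psp))
        assert not drop.channels[5].keep
        keep = prune_channels(self._windows([0.1] * 60 + [0.9] * 40,
                                            [0.01] * 60 + [0.5] * 40))
        assert keep.channels[5].keep

    def test_conjunction_required_sci_alone_not_enough(self):
        # SCI below threshold everywhere but PSP healthy: channel survives
        report = prune_channels(self._windows([0.1] * 100, [0.5] * 100))
        assert report.channels[5].keep
        assert report.channels[5].fraction_bad == 0.0

    def test_ssc_channels_scored_and_flagged(self, montage):
        windows = {cid: (np.full(10, 0.9), np.full(10, 0.5))
                   for cid in montage.channel_ids}
        report = prune_channels(windows, montage=montage)
        assert report.channels[12].is_short_separation
        assert report.channels[37].is_short_separation
        assert len(report.kept_ids()) == 48

    @given(
        sci=st.lists(st.floats(-1, 1), min_size=5, max_size=40),
        psp=st.lists(st.floats(0, 1), min_size=5, max_size=40),
        d_sci=st.floats(0, 0.5),
        d_psp=st.floats(0, 0.1),
    )
    @settings(max_examples=50, deadline=None)
    def test_raising_thresholds_never_rescues_a_channel(self, sci, psp, d_sci, d_psp):
        n = min(len(sci), len(psp))
        windows = {1: (np.array(sci[:n]), np.array(psp[:n]))}
        base = QcParams()
        stricter = QcParams(sci_threshold=base.sci_threshold + d_sci,
                            psp_threshold=base.psp_threshold + d_psp)
        kept_base = prune_channels(windows, base).channels[1].keep
        kept_strict = prune_channels(windows, stricter).channels[1].keep
        if not kept_base:
            assert not kept_strict

    def test_report_frame_columns(self):
        df = prune_channels(self._windows([0.9] * 4, [0.5] * 4)).to_frame()
        assert {"channel_id", "n_windows", "fraction_bad", "verdict"} <= set(df.columns)


def test_saturation_flag_marks_ceiling_channels():
    I = np.ones((2, 2, 100))
    I[0, :, :10] = 10.0  # 10% of samples at ceiling on channel 1
    flags = flag_saturation(toy_raw(I), ceiling=10.0, max_fraction=0.05)
    assert flags == {1: True, 2: False}


class TestBandpass:
    fs = 25.0

    def _amplitude(self, x, freq, t):
        # independent amplitude estimator: least-squares sinusoid regression
        X = np.column_stack([np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)])
        beta, *_ = np.linalg.lstsq(X, x, rcond=None)
        return float(np.hypot(*beta))

    def test_dc_offset_rejected(self):
        od = toy_od(np.full((1, 2, 2000), 3.0))
        out = bandpass(od)
        assert np.max(np.abs(out.od)) < 1e-6 * 3.0

    def test_midband_sinusoid_preserved(self):
        t = np.arange(0, 600, 1 / self.fs)
        x = np.sin(2 * np.pi * 0.03 * t)
        out = bandpass(toy_od(x[None, None, :] * np.ones((1, 2, 1))))
        keep = (t > 60) & (t < 540)
        amp = self._amplitude(out.od[0, 0][keep], 0.03, t[keep])
        assert abs(amp - 1.0) <= 0.05

    def test_cardiac_sinusoid_rejected(self):
        t = np.arange(0, 600, 1 / self.fs)
        x = np.sin(2 * np.pi * 1.1 * t)
        out = bandpass(toy_od(x[None, None, :] * np.ones((1, 2, 1))))
        keep = (t > 60) & (t < 540)
        amp = self._amplitude(out.od[0, 0][keep], 1.1, t[keep])
        assert amp < 0.01

    def test_band_edges_validated(self):
        od = toy_od(np.zeros((1, 2, 100)))
        with pytest.raises(ValueError, match="band edges"):
            bandpass(od, low_hz=0.08, high_hz=0.009)
        with pytest.raises(ValueError, match="band edges"):
            bandpass(od, low_hz=0.009, high_hz=13.0)


class TestMbll:
    def test_zero_od_gives_zero_concentration(self, montage):
        od = toy_od(np.zeros((48, 2, 50)))
        conc = mbll(od, montage=montage)
        assert np.allclose(conc.conc, 0.0)

    def test_round_trip_with_forward_model(self, montage, rng):
        conc_true = rng.normal(0, 0.5, (48, 2, 100))
        od_arr = forward_mbll(conc_true, montage=montage)
        conc = mbll(toy_od(od_arr), montage=montage)
        assert np.allclose(conc.conc, conc_true, rtol=1e-10, atol=1e-12)

    def test_linearity(self, montage, rng):
        od_arr = rng.normal(0, 0.01, (48, 2, 20))
        c1 = mbll(toy_od(od_arr), montage=montage).conc
        c2 = mbll(toy_od(2 * od_arr), montage=montage).conc
        assert np.allclose(c2, 2 * c1, rtol=1e-10)

    def test_pruned_channels_left_nan(self, montage):
        mask = np.ones(48, dtype=bool)
        mask[3] = False
        conc = mbll(toy_od(np.zeros((48, 2, 10))), montage=montage, channel_mask=mask)
        assert np.isnan(conc.conc[3]).all()
        assert np.isfinite(conc.conc[4]).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_round_trip_over_random_extinction_tables(self, seed):
        rng = np.random.default_rng(seed)
        eps = rng.uniform(0.2, 2.0, (2, 2))
        if abs(np.linalg.det(eps)) < 0.05:
            return  # nearly singular tables are rejected elsewhere
        params = MbllParams(extinction=eps)
        montage = default_montage()
        conc_true = rng.normal(0, 1.0, (48, 2, 16))
        od_arr = forward_mbll(conc_true, params, montage)
        conc = mbll(toy_od(od_arr), params, montage)
        assert np.allclose(conc.conc, conc_true, rtol=1e-8, atol=1e-10)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ValueError, match="invertible"):
            MbllParams(extinction=np.ones((2, 2)))

    def test_dpf_pairing_default(self):
        params = MbllParams()
        assert params.dpf == (5.4, 4.6)
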