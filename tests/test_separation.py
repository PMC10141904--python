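"""Channel aggregation, band separation, bout detection, RR rate."""

import numpy as np
import pytest
from scipy import signal as sps

from smrr.config import BandConfig, GeneratorConfig, LatencyParams
from smrr.separation import (
    BandStreams,
    NoSignalError,
    RawRecording,
    aggregate_channels,
    detect_sm_bouts,
    instantaneous_rr,
    separate_bands,
)
from smrr.synthetic import generate_night

FS = 54.0


def _band_energy(x, fs, lo, hi):
    freqs, psd = sps.periodogram(x, fs=fs)
    return psd[(freqs >= lo) & (freqs <= hi)].sum()


class TestAggregateChannels:
    def test_single_channel_identity(self, sine_recording):
        pair = aggregate_channels(sine_recording)
        ref = sine_recording.signal[:, 0]
        ref = (ref - ref.mean()) / ref.std()
        np.testing.assert_allclose(pair.sm, ref, atol=1e-9)
        np.testing.assert_allclose(pair.rr, ref, atol=1e-9)

    def test_noise_channel_downweighted(self):
        rng = np.random.default_rng(0)
        t = np.arange(int(600 * FS)) / FS
        clean = np.sin(2 * np.pi * 0.37 * t)
        noisy = 1e-3 * rng.normal(size=len(t))
        rec = RawRecording(
            signal=np.stack([clean, noisy], axis=1), sampling_rate=FS
        )
        pair = aggregate_channels(rec)
        r = np.corrcoef(pair.rr, clean)[0, 1]
        assert r > 0.99

    def test_all_zero_raises(self):
        rec_signal = np.zeros((int(600 * FS), 3))
        with pytest.raises(NoSignalError):
            aggregate_channels(RawRecording(signal=rec_signal, sampling_rate=FS))


class TestSeparateBands:
    def test_pure_rr_tone_stays_out_of_sm_stream(self):
        t = np.arange(int(600 * FS)) / FS
        streams = separate_bands(np.sin(2 * np.pi * 0.37 * t), FS)
        e_sm = _band_energy(streams.sm, FS, 0.3, 0.45)
        e_rr = _band_energy(streams.rr, FS, 0.3, 0.45)
        assert e_sm < 0.01 * e_rr

    def test_pure_sm_tone_stays_out_of_rr_stream(self):
        t = np.arange(int(600 * FS)) / FS
        streams = separate_bands(np.sin(2 * np.pi * 0.08 * t), FS)
        e_sm = _band_energy(streams.sm, FS, 0.05, 0.12)
        e_rr = _band_energy(streams.rr, FS, 0.05, 0.12)
        assert e_rr < 0.01 * e_sm

    def test_zero_input_zero_output(self):
        streams = separate_bands(np.zeros(int(600 * FS)), FS)
        assert np.allclose(streams.sm, 0.0)
        assert np.allclose(streams.rr, 0.0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            separate_bands(np.zeros(1000), 1.0)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="time constant"):
            separate_bands(np.zeros(int(30 * FS)), FS)

    def test_zero_phase_pulse_centroid(self):
        """A symmetric pulse keeps its centre of mass within one sample."""
        n = int(600 * FS)
        x = np.zeros(n)
        centre = n // 2
        width = int(4 * FS)
        x[centre - width : centre + width + 1] = sps.windows.hann(2 * width + 1)
        streams = separate_bands(x, FS)
        for y in (streams.sm, streams.rr):
            w = y**2
            com = float(np.sum(np.arange(n) * w) / np.sum(w))
            assert abs(com - centre) <= 1.0

    def test_streams_aligned_same_length(self, sine_recording):
        pair = aggregate_channels(sine_recording)
        streams = separate_bands(pair.rr, FS)
        assert streams.sm.shape == streams.rr.shape == pair.rr.shape
        with pytest.raises(ValueError):
            BandStreams(sm=np.zeros(5), rr=np.zeros(6), sampling_rate=FS)


class TestDetectSMBouts:
    def test_recovers_injected_bouts(self, clean_processed):
        rec, truth, pair, streams, rate, bouts = clean_processed
        for tb in truth.bouts:
            nearest = min(bouts, key=lambda b: abs(b.onset_s - tb.onset_s))
            assert abs(nearest.onset_s - tb.onset_s) < 1.0

    def test_flat_stream_no_bouts(self):
        assert detect_sm_bouts(np.zeros(int(600 * FS)), FS) == []

    def test_close_bouts_merge(self, short_config):
        rec, truth = generate_night(
            short_config,
            LatencyParams(mean_ms=0.0, sd_ms=0.0),
            seed=2,
            bout_plan=[(600.0, 6.0, None), (611.0, 6.0, None)],
        )
        pair = aggregate_channels(rec)
        streams = separate_bands(pair.sm, FS)
        bouts = detect_sm_bouts(streams.sm, FS)
        overlapping = [b for b in bouts if b.onset_s < 620 and b.offset_s > 595]
        assert len(overlapping) == 1  # 5-s gap is below the 10-s merge gap

    def test_bouts_sorted_non_overlapping(self, clean_processed):
        *_, bouts = clean_processed
        for a, b in zip(bouts, bouts[1:]):
            assert a.onset_s < b.onset_s
            assert a.offset_s <= b.onset_s


class TestInstantaneousRR:
    def test_constant_tone_binned_rate(self):
        t = np.arange(int(600 * FS)) / FS
        rate = instantaneous_rr(np.sin(2 * np.pi * 0.37 * t), FS)
        assert rate.usable
        assert len(rate.binned_rate) == 5
        np.testing.assert_allclose(rate.binned_rate, 0.37 * 60.0, atol=0.05)

    def test_upregulation_visible(self, clean_processed):
        rec, truth, pair, streams, rate, bouts = clean_processed
        b = truth.coupled_bouts[0]
        i0 = int((b.event_onset_s + 5.0) * FS)
        i1 = int((b.event_onset_s + 15.0) * FS)
        base = 0.366
        assert np.median(rate.freq[i0:i1]) >= 1.10 * base

    def test_pure_noise_unusable(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=int(1200 * FS))
        streams = separate_bands((x - x.mean()) / x.std(), FS)
        with pytest.warns(UserWarning, match="undetectable"):
            rate = instantaneous_rr(streams.rr, FS)
        assert not rate.usable

    def test_binned_rate_matches_zero_crossing_oracle(self):
        """Independent oracle: count mean-crossings to estimate breaths/min."""
        t = np.arange(int(600 * FS)) / FS
        x = np.sin(2 * np.pi * 0.41 * t)
        rate = instantaneous_rr(x, FS)
        for k in range(len(rate.binned_rate)):
            seg = x[int(k * 120 * FS) : int((k + 1) * 120 * FS)]
            crossings = np.sum((seg[:-1] < 0) & (seg[1:] >= 0))
            oracle = crossings / 2.0  # per 2-min bin -> breaths/min
            assert abs(rate.binned_rate[k] - oracle) <= 1.0


class TestRawRecording:
    def test_rejects_nan(self):
        x = np.zeros((int(600 * FS), 2))
        x[5, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            RawRecording(signal=x, sampling_rate=FS)

    def test_rejects_short(self):
        with pytest.raises(ValueError, match="10 minutes"):
            RawRecording(signal=np.zeros((100, 2)), sampling_rate=FS)
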