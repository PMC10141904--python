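"""Raw multi-channel recording -> SM / RR streams, bout detection, RR rate.

The separation stage reduces the sensor array to two aligned single-channel
streams: a movement (SM) composite that follows the momentarily dominant
channel, and a respiration (RR) composite built as an SNR-weighted channel
mean that suppresses movement-contaminated sensors.  Both are filtered with
zero-phase Butterworth band-passes so that no group delay is introduced
between the streams (the downstream latencies are on the order of tens of
milliseconds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps
from scipy.ndimage import median_filter, uniform_filter1d

from .config import BandConfig, BoutDetectionConfig, RRRateConfig


class NoSignalError(ValueError):
    """All channels are flat: nothing to analyse."""


@dataclass
class RawRecording:
    """One night of uniformly sampled multi-channel pressure data."""

    signal: np.ndarray  # (n_samples, n_sensors)
    sampling_rate: float
    case_id: str = "case"
    night_index: int = 1

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim == 1:
            sig = sig[:, None]
        if sig.ndim != 2:
            raise ValueError("signal must be 1-D or 2-D (samples x sensors)")
        if not np.isfinite(sig).all():
            raise ValueError("signal contains NaN/inf; repair gaps on ingest")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if sig.shape[0] < 600 * self.sampling_rate:
            raise ValueError("recording shorter than 10 minutes")
        if self.night_index not in (1, 2):
            raise ValueError("night_index must be 1 or 2")
        self.signal = sig

    @property
    def n_samples(self) -> int:
        return int(self.signal.shape[0])

    @property
    def n_sensors(self) -> int:
        return int(self.signal.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class CompositePair:
    """Single-channel reductions of the array, one per processing path."""

    sm: np.ndarray
    rr: np.ndarray
    sampling_rate: float


@dataclass(frozen=True)
class BandStreams:
    sm: np.ndarray
    rr: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.sm.shape != self.rr.shape:
            raise ValueError("SM and RR streams must be aligned sample-for-sample")


@dataclass(frozen=True)
class SMBout:
    onset_s: float
    offset_s: float
    peak_amplitude: float
    auc: float

    def __post_init__(self) -> None:
        if self.onset_s >= self.offset_s:
            raise ValueError("bout onset must precede offset")


@dataclass
class RRRateSeries:
    """Instantaneous respiratory frequency plus its 2-min binned rates."""

    freq_raw: np.ndarray  # Hz, unsmoothed phase derivative (RR-band stream)
    freq: np.ndarray  # Hz, median-smoothed
    valid: np.ndarray  # bool per sample
    sampling_rate: float
    phase_wideband: Optional[np.ndarray] = None  # rad, transition-preserving
    bin_starts_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    binned_rate: np.ndarray = field(default_factory=lambda: np.empty(0))  # breaths/min
    bin_valid: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    usable: bool = True


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = float(np.std(x))
    return (x - np.mean(x)) / sd


def envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal."""
    return np.abs(sps.hilbert(x))


# ---------------------------------------------------------------------------
# channel aggregation


def aggregate_channels(
    raw: RawRecording, var_floor: float = 1e-12
) -> CompositePair:
    """Reduce the sensor array to one series per processing path.

    SM path: the signed sample of whichever channel has the largest envelope
    at that instant (follows the sensors under the moving body part).
    RR path: SNR-weighted channel mean, where each channel's weight is its
    respiration-band power squared over its out-of-band power, so that
    movement-loaded sensors contribute little to the respiration estimate.
    """
    x = raw.signal - raw.signal.mean(axis=0, keepdims=True)
    variances = x.var(axis=0)
    if np.all(variances <= var_floor):
        raise NoSignalError("all channels flat (variance below floor)")
    n, c = x.shape
    fs = raw.sampling_rate

    if c == 1:
        s = _standardize(x[:, 0])
        return CompositePair(sm=s, rr=s.copy(), sampling_rate=fs)

    envs = np.empty_like(x)
    for ch in range(c):
        envs[:, ch] = np.abs(sps.hilbert(x[:, ch]))
    dominant = np.argmax(envs, axis=1)
    sm = x[np.arange(n), dominant]
    del envs

    nperseg = min(n, 8192)
    freqs, psd = sps.welch(x, fs=fs, nperseg=nperseg, axis=0)
    # per-channel white-noise floor from a band with no physiological
    # content; subtracting it keeps the weights selective under noise
    noise_band = (freqs >= 5.0) & (freqs <= 20.0)
    if noise_band.any():
        floor = np.median(psd[noise_band], axis=0)
        psd = np.maximum(psd - floor[None, :], 0.0)
    resp_band = (freqs >= 0.25) & (freqs <= 0.55)
    move_band = (freqs >= 0.03) & (freqs <= 0.22)
    p_resp = psd[resp_band].sum(axis=0)
    p_move = psd[move_band].sum(axis=0)
    # movement power as excess over the channel median: clean channels
    # cluster at the (noise-driven) baseline, movement-loaded ones stand out
    p_move = np.maximum(p_move - 1.2 * float(np.median(p_move)), 0.0)
    eps = 1e-4 * max(float(np.median(p_resp)), var_floor)
    weights = p_resp**2 / (p_move + eps)
    weights = np.where(variances > var_floor, weights, 0.0)
    if weights.sum() <= 0:
        weights = np.where(variances > var_floor, variances, 0.0)
    rr = x @ (weights / weights.sum())

    return CompositePair(sm=_standardize(sm), rr=_standardize(rr), sampling_rate=fs)


# ---------------------------------------------------------------------------
# band separation


def _bandpass_sos(band: Tuple[float, float], fs: float, order: int):
    return sps.butter(order, band, btype="bandpass", fs=fs, output="sos")


def _check_band_pre(x: np.ndarray, fs: float, bands: BandConfig) -> None:
    hi = max(bands.sm_band[1], bands.rr_band[1])
    if fs < 2 * hi:
        raise ValueError(f"sampling rate {fs} Hz below Nyquist for {hi} Hz band edge")
    lo = min(bands.sm_band[0], bands.rr_band[0])
    tau = 1.0 / (2 * np.pi * lo)  # longest filter time constant
    if len(x) / fs < 10 * tau:
        raise ValueError("input shorter than 10x the longest filter time constant")


def separate_bands(
    composite: np.ndarray, sampling_rate: float, bands: Optional[BandConfig] = None
) -> BandStreams:
    """Split one composite into zero-phase SM- and RR-band streams."""
    bands = bands or BandConfig()
    x = np.asarray(composite, dtype=float)
    _check_band_pre(x, sampling_rate, bands)
    sm = sps.sosfiltfilt(_bandpass_sos(bands.sm_band, sampling_rate, bands.order), x)
    rr = sps.sosfiltfilt(_bandpass_sos(bands.rr_band, sampling_rate, bands.order), x)
    return BandStreams(sm=sm, rr=rr, sampling_rate=sampling_rate)


def band_streams_from_pair(
    pair: CompositePair, bands: Optional[BandConfig] = None
) -> BandStreams:
    """Filter each composite with its own band (the pipeline's default path)."""
    bands = bands or BandConfig()
    _check_band_pre(pair.sm, pair.sampling_rate, bands)
    sm = sps.sosfiltfilt(_bandpass_sos(bands.sm_band, pair.sampling_rate, bands.order), pair.sm)
    rr = sps.sosfiltfilt(_bandpass_sos(bands.rr_band, pair.sampling_rate, bands.order), pair.rr)
    return BandStreams(sm=sm, rr=rr, sampling_rate=pair.sampling_rate)


# ---------------------------------------------------------------------------
# bout detection


def _bool_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _merge_runs(runs: List[Tuple[int, int]], max_gap: int) -> List[Tuple[int, int]]:
    if not runs:
        return []
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < max_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    return [(a, b) for a, b in merged]


@dataclass
class BoutRefiner:
    """Context for sub-sample bout-onset refinement.

    The band-limited SM stream smears onsets over seconds, so refinement
    goes back to the raw array: for each bout, the single channel with the
    strongest local movement response is selected, its respiration content
    is cancelled coherently (scalar regression on the RR stream over a
    pre-bout segment), and the rising edge of the residual envelope is
    fitted with a line and extrapolated down to the pre-bout noise floor.
    """

    signal: np.ndarray  # (n_samples, n_sensors), demeaned
    rr_stream: np.ndarray
    sampling_rate: float

    @classmethod
    def from_recording(cls, raw: "RawRecording", rr_stream: np.ndarray) -> "BoutRefiner":
        x = raw.signal - raw.signal.mean(axis=0, keepdims=True)
        return cls(signal=x, rr_stream=rr_stream, sampling_rate=raw.sampling_rate)

    def refine(
        self,
        coarse_onset_s: float,
        coarse_offset_s: Optional[float] = None,
        *,
        fit_span_s: float = 0.25,
    ) -> float:
        # the band-limited coarse onset can be early by ~10 s (filter
        # smear), so the search zone must span the whole coarse interval
        fs = self.sampling_rate
        n = self.signal.shape[0]
        if coarse_offset_s is None:
            coarse_offset_s = coarse_onset_s + 15.0
        i_on = int(round(coarse_onset_s * fs))
        i_off = int(round(coarse_offset_s * fs))
        i0 = max(0, i_on - int(20 * fs))
        i1 = min(n, i_off + int(10 * fs))
        j_on = i_on - i0
        pre = slice(max(0, j_on - int(18 * fs)), max(1, j_on - int(2 * fs)))
        bout_zone = slice(j_on, max(j_on + 1, i_off - i0))

        # everything physiological lives below ~1 Hz; a gentle low-pass
        # cuts wideband noise without touching bout or breathing content
        seg = self.signal[i0:i1, :]
        lp = sps.butter(4, 3.0, btype="lowpass", fs=fs, output="sos")
        seg = sps.sosfiltfilt(lp, seg, axis=0)
        env_c = np.abs(sps.hilbert(seg, axis=0))
        # channel with the largest movement response relative to its own
        # pre-bout level
        lift = env_c[bout_zone].max(axis=0) - np.median(env_c[pre], axis=0)
        ch = int(np.argmax(lift))
        y = seg[:, ch]

        rr = self.rr_stream[i0:i1]
        t_loc = np.arange(len(rr)) / fs

        def residual_envelope(pre_sl: slice):
            # coherent respiration cancellation with a drifting gain:
            # regress the channel on [rr, t*rr] over a pre-bout segment so
            # slow amplitude drift keeps cancelling through the bout region
            tc = t_loc - t_loc[(pre_sl.start + pre_sl.stop) // 2]
            x_pre = np.stack([rr[pre_sl], tc[pre_sl] * rr[pre_sl]], axis=1)
            try:
                coef = np.linalg.solve(x_pre.T @ x_pre, x_pre.T @ y[pre_sl])
            except np.linalg.LinAlgError:
                return None, None
            resid = y - (coef[0] + coef[1] * tc) * rr
            # rectified residual with a short *centered* mean: unlike the
            # analytic-signal envelope this has no acausal pre-onset
            # spread, and a centered average of a linear rise is unbiased
            renv = uniform_filter1d(np.abs(resid), size=max(3, int(0.2 * fs)))
            return resid, renv

        def first_crossing(renv: np.ndarray, j_from: int, thr: float) -> Optional[int]:
            sustain = max(1, int(0.2 * fs))
            for s0, s1 in _bool_runs(renv[j_from:] > thr):
                if s1 - s0 >= sustain:
                    return j_from + s0
            return None

        resid, renv = residual_envelope(pre)
        if renv is None:
            return coarse_onset_s
        base = float(np.median(renv[pre]))
        noise = 1.4826 * float(np.median(np.abs(renv[pre] - base))) + 1e-12
        peak = float(np.max(renv[bout_zone]))
        if peak <= base:
            return coarse_onset_s
        cross = first_crossing(
            renv, max(0, j_on - int(4 * fs)), base + max(4.0 * noise, 0.08 * (peak - base))
        )
        if cross is None:
            return coarse_onset_s

        # second pass: re-anchor the cancellation window right before the
        # detected rise (the coarse onset can be ~10 s early, and gain-drift
        # extrapolated that far leaves a junk floor at the rise itself)
        pre2 = slice(max(0, cross - int(16 * fs)), max(1, cross - int(1.5 * fs)))
        resid2, renv2 = residual_envelope(pre2)
        if renv2 is not None:
            base_g = float(np.median(renv2[pre2]))
            noise_g = 1.4826 * float(np.median(np.abs(renv2[pre2] - base_g))) + 1e-12
            peak2 = float(np.max(renv2[bout_zone]))
            cross2 = first_crossing(
                renv2,
                max(0, j_on - int(4 * fs)),
                base_g + max(4.0 * noise_g, 0.08 * (peak2 - base_g)),
            )
            if cross2 is not None and peak2 > base_g:
                resid, renv, cross, base = resid2, renv2, cross2, base_g

        # short linear fit of the early rise, extrapolated to the floor
        # (a short span keeps carrier-cosine curvature negligible)
        span = max(4, int(fit_span_s * fs))
        yfit = renv[cross : cross + span]
        tt = np.arange(len(yfit)) / fs
        slope, intercept = np.polyfit(tt, yfit, 1)
        if slope <= 0:
            return (i0 + cross) / fs
        t0 = (base - intercept) / slope  # where the fitted rise meets the floor
        t0 = float(np.clip(t0, -1.0, 0.4))
        return (i0 + cross) / fs + t0


def detect_sm_bouts(
    sm_stream: np.ndarray,
    sampling_rate: float,
    config: Optional[BoutDetectionConfig] = None,
    *,
    refine_with: Optional[BoutRefiner] = None,
) -> List[SMBout]:
    """Threshold the smoothed SM envelope at median + k*MAD.

    Intervals closer than the merge gap are fused, short blips dropped.
    When a :class:`BoutRefiner` is given, each onset is re-estimated on the
    raw array to sub-sample precision.
    """
    config = config or BoutDetectionConfig()
    fs = sampling_rate
    x = np.asarray(sm_stream, dtype=float)
    if not np.any(x != 0.0):
        return []
    env = np.abs(sps.hilbert(x))
    env = uniform_filter1d(env, size=max(1, int(config.envelope_smooth_s * fs)))
    med = float(np.median(env))
    mad = float(np.median(np.abs(env - med)))
    thr = med + config.threshold_mads * mad
    if mad <= 0:
        return []
    runs = _merge_runs(_bool_runs(env > thr), int(config.merge_gap_s * fs))
    min_len = int(config.min_duration_s * fs)
    edge_guard = int(10 * fs)  # zero-phase filter transients at the ends
    bouts: List[SMBout] = []
    for start, stop in runs:
        if stop - start < min_len:
            continue
        if start < edge_guard or stop > len(env) - edge_guard:
            continue
        seg = env[start:stop]
        onset = start / fs
        if refine_with is not None:
            onset = min(refine_with.refine(onset, stop / fs), (stop - 1) / fs)
        bouts.append(
            SMBout(
                onset_s=onset,
                offset_s=stop / fs,
                peak_amplitude=float(seg.max()),
                auc=float(np.trapezoid(seg, dx=1.0 / fs)),
            )
        )
    bouts.sort(key=lambda b: b.onset_s)
    return bouts


# ---------------------------------------------------------------------------
# instantaneous respiratory rate


def _phase_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    analytic = sps.hilbert(x)
    phase = np.unwrap(np.angle(analytic))
    return np.gradient(phase) * fs / (2.0 * np.pi)


def instantaneous_rr(
    rr_stream: np.ndarray,
    sampling_rate: float,
    config: Optional[RRRateConfig] = None,
    *,
    wideband_source: Optional[np.ndarray] = None,
) -> RRRateSeries:
    """Respiratory frequency from the analytic-signal phase derivative.

    Samples are valid where the envelope is above the noise floor, the
    smoothed frequency lies in the plausible respiration band and the raw
    estimate does not jitter away from its smoothed version.  A night with
    under ``min_valid_fraction`` valid samples is flagged unusable.

    The narrow RR band smears frequency transitions over ~1 s, which is too
    coarse for ms-scale latency work, so when the broadband composite is
    supplied as ``wideband_source`` an additional transition-preserving
    *phase* series is computed from a lightly filtered (0.05-1.5 Hz)
    version of it (the modulation bandwidth of a band-pass is set by the
    distance from the carrier to the nearest band edge, so the refinement
    band must keep both edges far from ~0.37 Hz).  Event timing is then
    fitted on this phase directly (see :mod:`smrr.coupling`).
    """
    config = config or RRRateConfig()
    fs = sampling_rate
    x = np.asarray(rr_stream, dtype=float)
    analytic = sps.hilbert(x)
    env = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    freq_raw = np.gradient(phase) * fs / (2.0 * np.pi)
    k = int(config.freq_smooth_s * fs) | 1
    freq = median_filter(freq_raw, size=k, mode="nearest")

    phase_wb = None
    if wideband_source is not None:
        wb = sps.sosfiltfilt(
            _bandpass_sos((0.05, 1.5), fs, 4), np.asarray(wideband_source, float)
        )
        phase_wb = np.unwrap(np.angle(sps.hilbert(wb)))

    valid = (
        (env > config.min_envelope_frac * float(np.median(env)))
        & (freq > config.valid_band[0])
        & (freq < config.valid_band[1])
        & (np.abs(freq_raw - freq) < config.max_freq_jitter_hz)
    )
    edge = int(2 * fs)
    valid[:edge] = False
    valid[-edge:] = False

    usable = bool(valid.mean() >= config.min_valid_fraction)
    if not usable:
        warnings.warn("respiration undetectable for >50% of the night", stacklevel=2)

    n_bins = int(len(x) / fs // config.bin_s)
    starts = np.arange(n_bins) * config.bin_s
    rates = np.full(n_bins, np.nan)
    bin_ok = np.zeros(n_bins, dtype=bool)
    per_bin = int(config.bin_s * fs)
    for b in range(n_bins):
        sl = slice(b * per_bin, (b + 1) * per_bin)
        v = valid[sl]
        if v.mean() >= 0.5:
            rates[b] = float(np.mean(freq[sl][v]) * 60.0)
            bin_ok[b] = True

    return RRRateSeries(
        freq_raw=freq_raw,
        freq=freq,
        valid=valid,
        sampling_rate=fs,
        phase_wideband=phase_wb,
        bin_starts_s=starts,
        binned_rate=rates,
        bin_valid=bin_ok,
        usable=usable,
    )
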