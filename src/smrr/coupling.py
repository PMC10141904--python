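"""SM-RR coupling: windowing, event detection, pairing and latency profiles.

Each night is cut into contiguous 10-min windows.  Within a window,
respiratory-frequency-change events are detected where the smoothed
instantaneous frequency exceeds the window baseline by one window SD,
sustained for a few seconds.  Event onsets are then re-estimated on the
unsmoothed frequency series with a hinge (flat-then-ramp) least-squares fit,
which localizes the start of the frequency ramp to sub-sample precision.
Bouts and events are paired one-to-one by onset proximity; the signed
latency is (event onset - bout onset), positive when movement leads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import EventDetectionConfig, HistogramConfig, PairingConfig
from .separation import RRRateSeries, SMBout, _bool_runs, _merge_runs


@dataclass
class AnalysisWindow:
    night_index: int
    window_index: int
    start_s: float
    end_s: float
    usable: bool = True

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("window end must follow start")


@dataclass(frozen=True)
class RREvent:
    onset_s: float
    magnitude_sd: float  # peak deviation in units of the window SD
    duration_s: float
    midpoint_s: Optional[float] = None  # fitted frequency-transition midpoint
    ramp_s: Optional[float] = None  # fitted transition duration

    def __post_init__(self) -> None:
        if self.magnitude_sd < 1.0:
            raise ValueError("event magnitude below the 1-SD detection floor")


@dataclass(frozen=True)
class LatencySample:
    night_index: int
    window_index: int
    bout: SMBout
    event: RREvent
    latency_ms: float


@dataclass
class CaseLatencyProfile:
    """Per-case distribution of window-maximum latencies across both nights."""

    case_id: str
    maxima_ms: List[float]
    bin_edges_ms: np.ndarray
    density: np.ndarray
    n_usable_windows: int
    low_coverage: bool

    def pdf_integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges_ms)))


# ---------------------------------------------------------------------------


def segment_windows(
    duration_s: float, night_index: int = 1, window_s: float = 600.0
) -> List[AnalysisWindow]:
    """Contiguous non-overlapping windows; the partial trailing one is dropped."""
    n = int(duration_s // window_s)
    if n < 1:
        warnings.warn(
            f"night of {duration_s:.0f}s shorter than one {window_s:.0f}s window; excluded",
            stacklevel=2,
        )
        return []
    return [
        AnalysisWindow(night_index, k, k * window_s, (k + 1) * window_s)
        for k in range(n)
    ]


def _ramp_integral_basis(u: np.ndarray, T: float) -> np.ndarray:
    """Integral of the unit frequency ramp clip(u,0,T)/T.

    0 before the ramp, u^2/2T during it, u - T/2 after; continuous in u.
    """
    c = np.clip(u, 0.0, T)
    return c * (u - 0.5 * c) / T


def fit_event_timing(
    phase: np.ndarray,
    fs: float,
    run_start: int,
    run_stop: int,
    *,
    tau_search_s: float = 1.5,
    ramp_grid: Tuple[float, float, float] = (0.75, 3.75, 0.25),
) -> Tuple[float, float, bool]:
    """Fit a three-piece phase model around a detected frequency excursion.

    The unwrapped wideband phase is modelled as linear (baseline breathing)
    + the integral of a linear frequency ramp of duration ``T`` starting at
    ``tau``; (tau, T) are grid-searched with the linear coefficients solved
    in closed form, then refined (fine grid + parabolic interpolation).

    Threshold landmarks on the frequency series are biased by the smearing
    every band-limited estimate suffers, and the ramp-corner region of the
    fit carries little information.  The transition *midpoint* tau + T/2,
    in contrast, is pinned by the accumulated phase offset between the
    pre-event and plateau segments, which symmetric smearing cannot move.

    Returns ``(midpoint_s, ramp_s, ok)``.  Onsets should be derived as
    ``midpoint - T_night/2`` with a per-night T estimate (see
    :func:`calibrate_event_onsets`) rather than from each event's own noisy
    ``ramp_s``.
    """
    n = len(phase)
    i0 = max(0, run_start - int(8 * fs))
    i1 = min(n, run_start + int(8 * fs))
    if i1 - i0 < int(6 * fs):
        return (run_start / fs, np.nan, False)
    ph = phase[i0:i1].astype(float)
    j_mid = run_start - i0
    j_lo = max(1, j_mid - int(tau_search_s * fs))
    j_hi = min(len(ph) - int(1 * fs), j_mid + int(tau_search_s * fs))
    fit = _fit_phase_model(ph, fs, j_lo, j_hi, ramp_grid)
    if fit is None:
        return (run_start / fs, np.nan, False)
    tau, t1 = fit
    return (i0 / fs + tau + 0.5 * t1, float(t1), True)


def _fit_phase_model(
    ph: np.ndarray,
    fs: float,
    j_lo: int,
    j_hi: int,
    ramp_grid: Tuple[float, float, float],
) -> Optional[Tuple[float, float]]:
    """Grid-fit the three-piece phase model; returns (tau_s_local, T_s)."""
    if j_hi <= j_lo:
        return None
    t = np.arange(len(ph)) / fs
    # project out the [1, t] subspace once; SSE of the full model follows
    # from the residualized ramp basis
    q_mat, _ = np.linalg.qr(np.stack([np.ones_like(t), t], axis=1))
    r0 = ph - q_mat @ (q_mat.T @ ph)
    r0r0 = float(r0 @ r0)

    def sse_at(j: int, T: float) -> float:
        basis = _ramp_integral_basis(t - t[j], T)
        rb = basis - q_mat @ (q_mat.T @ basis)
        den = float(rb @ rb)
        if den <= 0:
            return np.inf
        return r0r0 - float(r0 @ rb) ** 2 / den

    t_lo, t_hi, t_step = ramp_grid
    # coarse pass over T to bracket the optimum cheaply
    best: Optional[Tuple[float, int, float]] = None
    for T in np.arange(t_lo, t_hi + 0.5 * t_step, t_step):
        for j in range(j_lo, j_hi, 2):
            sse = sse_at(j, float(T))
            if best is None or sse < best[0]:
                best = (sse, j, float(T))
    if best is None or not np.isfinite(best[0]):
        return None
    _, j0, T0 = best
    for T in np.arange(max(t_lo, T0 - t_step), T0 + t_step + 1e-9, t_step / 4.0):
        for j in range(max(j_lo, j0 - 3), min(j_hi, j0 + 4)):
            sse = sse_at(j, float(T))
            if sse < best[0]:
                best = (sse, j, float(T))
    s0, j1, T1 = best
    tau = t[j1]
    if j_lo < j1 < j_hi - 1:
        s_m, s_p = sse_at(j1 - 1, T1), sse_at(j1 + 1, T1)
        den = s_m - 2 * s0 + s_p
        if np.isfinite(s_m) and np.isfinite(s_p) and den > 0:
            tau += 0.5 * (s_m - s_p) / den / fs
    # sub-grid T via parabolic interpolation of SSE(T) at the best break
    dt = t_step / 4.0
    s_tm, s_tp = sse_at(j1, T1 - dt), sse_at(j1, T1 + dt)
    den_t = s_tm - 2 * s0 + s_tp
    if np.isfinite(s_tm) and np.isfinite(s_tp) and den_t > 0:
        T1 = T1 + 0.5 * (s_tm - s_tp) / den_t * dt
    return float(tau), float(T1)


def calibrate_event_onsets(events: Sequence[RREvent]) -> List[RREvent]:
    """Re-derive event onsets as midpoint - T/2 with a shared per-night T.

    Each event's fitted ramp duration is noisy, but the transition shape is
    a property of the night, so the median over all fitted events is a far
    better estimate than any single fit.  Events without a fit pass through
    unchanged.
    """
    ramps = [e.ramp_s for e in events if e.ramp_s is not None and np.isfinite(e.ramp_s)]
    if not ramps:
        return list(events)
    t_night = float(np.median(ramps))
    out: List[RREvent] = []
    for e in events:
        if e.midpoint_s is None or e.ramp_s is None or not np.isfinite(e.ramp_s):
            out.append(e)
            continue
        out.append(
            RREvent(
                onset_s=e.midpoint_s - 0.5 * t_night,
                magnitude_sd=e.magnitude_sd,
                duration_s=e.duration_s,
                midpoint_s=e.midpoint_s,
                ramp_s=e.ramp_s,
            )
        )
    return out


def detect_rr_events(
    rate: RRRateSeries,
    window: AnalysisWindow,
    config: Optional[EventDetectionConfig] = None,
) -> List[RREvent]:
    """1-SD rule: sustained excursions of smoothed frequency above the
    window median + 1 window SD (upward only unless ``bidirectional``)."""
    config = config or EventDetectionConfig()
    fs = rate.sampling_rate
    lo = int(round(window.start_s * fs))
    hi = min(len(rate.freq), int(round(window.end_s * fs)))
    valid = rate.valid[lo:hi]
    if valid.mean() < 0.5:
        window.usable = False
        return []
    f = rate.freq[lo:hi]
    fv = f[valid]
    baseline = float(np.median(fv))
    sd = float(np.std(fv))
    if sd <= 0:
        return []
    above = valid & (f > baseline + config.threshold_sds * sd)
    if config.bidirectional:
        above |= valid & (f < baseline - config.threshold_sds * sd)
    runs = _merge_runs(_bool_runs(above), int(config.merge_gap_s * fs))
    sustain = int(config.sustain_s * fs)
    events: List[RREvent] = []
    for start, stop in runs:
        if stop - start < sustain:
            continue
        mag = float(np.max(np.abs(f[start:stop] - baseline)) / sd)
        midpoint: Optional[float] = None
        ramp: Optional[float] = None
        onset = (lo + start) / fs
        if rate.phase_wideband is not None:
            midpoint, ramp, ok = fit_event_timing(
                rate.phase_wideband, fs, lo + start, lo + stop
            )
            if ok:
                onset = midpoint - 0.5 * ramp
            else:
                midpoint, ramp = None, None
        events.append(
            RREvent(
                onset_s=onset,
                magnitude_sd=max(mag, 1.0),
                duration_s=(stop - start) / fs,
                midpoint_s=midpoint,
                ramp_s=ramp,
            )
        )
    events.sort(key=lambda e: e.onset_s)
    return events


def pair_and_latency(
    bouts: Sequence[SMBout],
    events: Sequence[RREvent],
    window: AnalysisWindow,
    config: Optional[PairingConfig] = None,
) -> List[LatencySample]:
    """Greedy nearest-in-time one-to-one pairing within the radius.

    Ties in |distance| are broken toward the earlier event.  Unpaired bouts
    and events are discarded.  Latency is signed: positive when the bout
    onset precedes the event onset.
    """
    config = config or PairingConfig()
    in_win = lambda t: window.start_s <= t < window.end_s  # noqa: E731
    bs = [b for b in bouts if in_win(b.onset_s)]
    es = [e for e in events if in_win(e.onset_s)]
    candidates = []
    for i, b in enumerate(bs):
        for j, e in enumerate(es):
            d = e.onset_s - b.onset_s
            if abs(d) <= config.radius_s:
                candidates.append((abs(d), e.onset_s, i, j))
    candidates.sort()
    used_b: set = set()
    used_e: set = set()
    samples: List[LatencySample] = []
    for _, _, i, j in candidates:
        if i in used_b or j in used_e:
            continue
        used_b.add(i)
        used_e.add(j)
        samples.append(
            LatencySample(
                night_index=window.night_index,
                window_index=window.window_index,
                bout=bs[i],
                event=es[j],
                latency_ms=(es[j].onset_s - bs[i].onset_s) * 1000.0,
            )
        )
    samples.sort(key=lambda s: s.bout.onset_s)
    return samples


def window_max_latency(
    samples: Sequence[LatencySample], mode: str = "absolute"
) -> Optional[float]:
    """Representative latency of a window: largest |latency| with sign kept
    (ties -> positive), or the signed maximum when ``mode='signed'``."""
    if not samples:
        return None
    vals = [s.latency_ms for s in samples]
    if mode == "signed":
        return float(max(vals))
    best = max(vals, key=lambda v: (abs(v), v > 0))
    return float(best)


def case_profile(
    case_id: str,
    window_maxima_ms: Sequence[float],
    config: Optional[HistogramConfig] = None,
) -> CaseLatencyProfile:
    """Fixed-bin density histogram of window-maximum latencies.

    Values outside the histogram range are clipped onto the edge bins so the
    PDF always integrates to one.  Fewer than ``min_windows`` usable windows
    raises the low-coverage flag (profile still produced).
    """
    config = config or HistogramConfig()
    maxima = [float(v) for v in window_maxima_ms]
    lo, hi = config.range_ms
    edges = np.arange(lo, hi + 0.5 * config.bin_width_ms, config.bin_width_ms)
    width = config.bin_width_ms
    clipped = np.clip(maxima, lo + 1e-9, hi - 1e-9) if maxima else np.empty(0)
    counts, _ = np.histogram(clipped, bins=edges)
    density = (
        counts / (len(maxima) * width) if maxima else np.zeros(len(edges) - 1)
    )
    return CaseLatencyProfile(
        case_id=case_id,
        maxima_ms=maxima,
        bin_edges_ms=edges,
        density=density,
        n_usable_windows=len(maxima),
        low_coverage=len(maxima) < config.min_windows,
    )
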