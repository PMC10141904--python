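"""Synthetic mattress-night generator with ground-truth coupling latencies.

Each night is a multi-channel pressure recording assembled from three
components: a respiration carrier whose instantaneous frequency transiently
ramps up at each coupled event, amplitude-modulated movement bouts in the
low-frequency band, and additive Gaussian noise.  Every bout and its signed
latency (ms, positive when the bout leads the respiratory event) is recorded
in the ground truth, with event onsets quantized to the sample grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .config import CohortConfig, GeneratorConfig, LatencyParams
from .separation import RawRecording

MCI = "MCI"
NC = "NC"


class GeneratorError(ValueError):
    """Raised when a generator configuration cannot produce a valid night."""


@dataclass(frozen=True)
class BoutTruth:
    """One injected movement bout and (if coupled) its respiratory event."""

    onset_s: float
    offset_s: float
    event_onset_s: Optional[float]
    latency_ms: Optional[float]
    coupled: bool

    def __post_init__(self) -> None:
        if self.onset_s >= self.offset_s:
            raise ValueError("bout onset must precede offset")


@dataclass(frozen=True)
class NightTruth:
    bouts: Tuple[BoutTruth, ...]

    @property
    def coupled_bouts(self) -> Tuple[BoutTruth, ...]:
        return tuple(b for b in self.bouts if b.coupled)

    @property
    def latencies_ms(self) -> np.ndarray:
        return np.array([b.latency_ms for b in self.coupled_bouts], dtype=float)


@dataclass(frozen=True)
class CaseRecord:
    case_id: str
    label: str
    nights: Tuple[RawRecording, ...]
    truths: Tuple[NightTruth, ...]


@dataclass
class CohortDataset:
    cases: List[CaseRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise ValueError("case_ids must be unique")
        for c in self.cases:
            if c.label not in (MCI, NC):
                raise ValueError(f"label must be {MCI!r} or {NC!r}, got {c.label!r}")

    @property
    def labels(self) -> List[str]:
        return [c.label for c in self.cases]


# ---------------------------------------------------------------------------
# bout / event planning


def _quantize(t: float, fs: float) -> float:
    return round(t * fs) / fs


def _plan_bouts(
    config: GeneratorConfig,
    latency: LatencyParams,
    rng: np.random.Generator,
) -> List[Tuple[float, float, Optional[float]]]:
    """Schedule (onset_s, duration_s, latency_ms-or-None) for one night."""
    margin = 60.0
    plan: List[Tuple[float, float, Optional[float]]] = []
    t = margin + rng.uniform(0.0, config.bout_recurrence_mean)
    while True:
        dur = rng.uniform(*config.bout_duration_range)
        if t + dur > config.night_duration - margin:
            break
        lat: Optional[float] = None
        if rng.random() >= config.uncoupled_fraction:
            lat = float(rng.normal(latency.mean_ms, latency.sd_ms))
        plan.append((t, dur, lat))
        step = rng.normal(config.bout_recurrence_mean, config.bout_recurrence_jitter_sd)
        t += max(step, dur + 10.0)
    return plan


def _build_truth(
    plan: Sequence[Tuple[float, float, Optional[float]]],
    config: GeneratorConfig,
) -> NightTruth:
    fs = config.sampling_rate
    onsets = [_quantize(o, fs) for o, _, _ in plan]
    bouts: List[BoutTruth] = []
    for i, (raw_onset, dur, lat_ms) in enumerate(plan):
        onset = onsets[i]
        offset = _quantize(onset + dur, fs)
        if lat_ms is None:
            bouts.append(BoutTruth(onset, offset, None, None, False))
            continue
        # snap latency onto the sample grid
        k = round(lat_ms * fs / 1000.0)
        true_lat = k * 1000.0 / fs
        event_onset = _quantize(onset + true_lat / 1000.0, fs)
        gaps = []
        if i > 0:
            gaps.append(onset - onsets[i - 1])
        if i + 1 < len(onsets):
            gaps.append(onsets[i + 1] - onset)
        if gaps and abs(true_lat) / 1000.0 > 0.5 * min(gaps):
            raise GeneratorError(
                f"latency {true_lat:.1f} ms at t={onset:.1f}s exceeds half the "
                "inter-bout gap; pairing would be ambiguous"
            )
        if not (0.0 <= event_onset <= config.night_duration):
            raise GeneratorError("coupled event falls outside the night")
        bouts.append(BoutTruth(onset, offset, event_onset, true_lat, True))
    return NightTruth(tuple(bouts))


# ---------------------------------------------------------------------------
# signal synthesis


def respiratory_frequency_series(
    truth: NightTruth, config: GeneratorConfig, n_samples: int
) -> np.ndarray:
    """Instantaneous respiration frequency (Hz): baseline plus trapezoidal
    upregulation (2-s linear ramps, hold, ramp back) at each coupled event."""
    fs = config.sampling_rate
    f = np.full(n_samples, config.resp_base_freq, dtype=float)
    ramp = config.upregulation_ramp
    dur = config.upregulation_duration
    dev = config.resp_base_freq * config.upregulation_magnitude
    t = np.arange(n_samples) / fs
    for b in truth.coupled_bouts:
        e0 = b.event_onset_s
        knots_t = [e0, e0 + ramp, e0 + dur - ramp, e0 + dur]
        i0 = max(0, int(np.floor(e0 * fs)))
        i1 = min(n_samples, int(np.ceil((e0 + dur) * fs)) + 1)
        if i0 >= i1:
            continue
        f[i0:i1] += np.interp(t[i0:i1], knots_t, [0.0, dev, dev, 0.0])
    return f


def _respiration_component(
    truth: NightTruth,
    config: GeneratorConfig,
    n_samples: int,
    phase0: float,
) -> np.ndarray:
    f = respiratory_frequency_series(truth, config, n_samples)
    # trapezoidal phase integration: the signal's instantaneous frequency at
    # sample i is then exactly f[i] (a plain cumsum shifts it half a sample)
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (f[1:] + f[:-1]))))
    phase = phase0 + 2.0 * np.pi * cum / config.sampling_rate
    return config.resp_amplitude * np.sin(phase)


def _bout_component(
    truth: NightTruth,
    config: GeneratorConfig,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    fs = config.sampling_rate
    out = np.zeros(n_samples, dtype=float)
    for b in truth.bouts:
        freq = rng.uniform(*config.bout_band_freq_range)
        amp = config.bout_amplitude * rng.uniform(0.8, 1.2)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        i0 = int(round(b.onset_s * fs))
        i1 = min(n_samples, int(round(b.offset_s * fs)))
        if i0 >= i1:
            continue
        tt = (np.arange(i0, i1) - i0) / fs
        dur = b.offset_s - b.onset_s
        # linear attack with cosine carrier phase: movement onsets are
        # abrupt, so force contribution ramps from the first sample
        attack = min(config.bout_attack_s, dur / 4.0)
        release = dur / 3.0
        up = np.clip(tt / attack, 0.0, 1.0)
        down = np.sin(0.5 * np.pi * np.clip((dur - tt) / release, 0.0, 1.0)) ** 2
        out[i0:i1] += sign * amp * up * down * np.cos(2.0 * np.pi * freq * tt)
    return out


def _mix_to_sensors(
    resp: np.ndarray,
    bout: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Respiration loads on every channel with slowly drifting gains; bouts
    load on one contiguous channel subset (body position proxy)."""
    n = resp.size
    c = config.n_sensors
    fs = config.sampling_rate
    t = np.arange(n) / fs
    sig = np.empty((n, c), dtype=np.float64)
    width = max(1, int(rng.integers(max(1, c // 5), max(2, c // 2) + 1)))
    start = int(rng.integers(0, c - width + 1))
    bout_gain = np.zeros(c)
    bout_gain[start : start + width] = rng.uniform(0.5, 1.0, size=width)
    for ch in range(c):
        g0 = rng.uniform(0.4, 1.0)
        fm = rng.uniform(0.0005, 0.002)
        ph = rng.uniform(0.0, 2.0 * np.pi)
        gain = g0 * (1.0 + 0.05 * np.sin(2.0 * np.pi * fm * t + ph))
        sig[:, ch] = gain * resp + bout_gain[ch] * bout
        if config.noise_sd > 0:
            sig[:, ch] += rng.normal(0.0, config.noise_sd, size=n)
    return sig


# ---------------------------------------------------------------------------
# public API


def generate_night(
    config: GeneratorConfig,
    latency: LatencyParams | Tuple[float, float],
    seed: int | np.random.SeedSequence,
    *,
    case_id: str = "case",
    night_index: int = 1,
    bout_plan: Optional[Sequence[Tuple[float, float, Optional[float]]]] = None,
    return_components: bool = False,
):
    """Generate one synthetic night.

    Parameters
    ----------
    latency
        Class latency distribution (mean_ms, sd_ms) for coupled bouts.
    bout_plan
        Optional explicit schedule of ``(onset_s, duration_s, latency_ms)``
        tuples (``latency_ms=None`` marks an uncoupled bout); overrides the
        random schedule.  Useful for recovery tests.

    Returns
    -------
    (RawRecording, NightTruth), plus ``(resp, bout)`` components when
    ``return_components`` is set.
    """
    if not isinstance(latency, LatencyParams):
        latency = LatencyParams(mean_ms=float(latency[0]), sd_ms=float(latency[1]))
    rng = np.random.default_rng(seed)
    n = int(round(config.night_duration * config.sampling_rate))
    plan = list(bout_plan) if bout_plan is not None else _plan_bouts(config, latency, rng)
    truth = _build_truth(plan, config)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    resp = _respiration_component(truth, config, n, phase0)
    bout = _bout_component(truth, config, n, rng)
    signal = _mix_to_sensors(resp, bout, config, rng)
    rec = RawRecording(
        signal=signal,
        sampling_rate=config.sampling_rate,
        case_id=case_id,
        night_index=night_index,
    )
    if return_components:
        return rec, truth, (resp, bout)
    return rec, truth


def _case_plan(
    n_per_class: int, seed: int
) -> List[Tuple[str, str, np.random.SeedSequence]]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(2 * n_per_class)
    plan = []
    for i in range(n_per_class):
        plan.append((f"mci{i + 1:03d}", MCI, children[i]))
    for i in range(n_per_class):
        plan.append((f"nc{i + 1:03d}", NC, children[n_per_class + i]))
    return plan


def generate_case(
    case_id: str,
    label: str,
    config: GeneratorConfig,
    latency: LatencyParams,
    seed: int | np.random.SeedSequence,
    nights_per_case: int = 2,
) -> CaseRecord:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    night_seeds = ss.spawn(nights_per_case)
    nights, truths = [], []
    for k in range(nights_per_case):
        rec, truth = generate_night(
            config, latency, night_seeds[k], case_id=case_id, night_index=k + 1
        )
        nights.append(rec)
        truths.append(truth)
    return CaseRecord(case_id, label, tuple(nights), tuple(truths))


def iter_cohort(
    cohort: CohortConfig,
    config: GeneratorConfig,
    seed: int,
) -> Iterator[CaseRecord]:
    """Lazily generate cohort cases one at a time (bounded memory).

    Deterministic given ``seed``: each case draws from its own spawned
    seed stream, so case k is identical no matter how many cases are taken.
    """
    for case_id, label, ss in _case_plan(cohort.n_per_class, seed):
        latency = cohort.mci_latency if label == MCI else cohort.nc_latency
        yield generate_case(case_id, label, config, latency, ss, cohort.nights_per_case)


def generate_cohort(
    n_per_class: int,
    mci_latency: LatencyParams | Tuple[float, float],
    nc_latency: LatencyParams | Tuple[float, float],
    config: GeneratorConfig,
    seed: int,
    nights_per_case: int = 2,
) -> CohortDataset:
    """Eagerly generate a balanced two-class cohort.

    For large cohorts prefer :func:`iter_cohort`, which yields case by case.
    """
    if n_per_class < 2:
        raise GeneratorError("n_per_class must be >= 2")
    if not isinstance(mci_latency, LatencyParams):
        mci_latency = LatencyParams(mean_ms=float(mci_latency[0]), sd_ms=float(mci_latency[1]))
    if not isinstance(nc_latency, LatencyParams):
        nc_latency = LatencyParams(mean_ms=float(nc_latency[0]), sd_ms=float(nc_latency[1]))
    cohort = CohortConfig(
        n_per_class=n_per_class,
        nights_per_case=nights_per_case,
        mci_latency=mci_latency,
        nc_latency=nc_latency,
    )
    return CohortDataset(cases=list(iter_cohort(cohort, config, seed)))
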