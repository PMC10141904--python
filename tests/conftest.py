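import numpy as np
import pytest

from smrr.config import GeneratorConfig, LatencyParams, PipelineConfig
from smrr.separation import RawRecording
from smrr.synthetic import generate_night

FS = 54.0
SAMPLE_MS = 1000.0 / FS  # 18.518... ms


@pytest.fixture(scope="session")
def short_config() -> GeneratorConfig:
    """Noise-free 30-min night: fast enough for unit tests."""
    return GeneratorConfig(night_duration=1800.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_night(short_config):
    """One noise-free night with a wide spread of injected latencies."""
    rec, truth = generate_night(
        short_config, LatencyParams(mean_ms=150.0, sd_ms=120.0), seed=7
    )
    return rec, truth


@pytest.fixture(scope="session")
def clean_processed(clean_night):
    """The clean night pushed through separation (expensive, share it)."""
    from smrr.separation import (
        BoutRefiner,
        aggregate_channels,
        band_streams_from_pair,
        detect_sm_bouts,
        instantaneous_rr,
    )

    rec, truth = clean_night
    pair = aggregate_channels(rec)
    streams = band_streams_from_pair(pair)
    rate = instantaneous_rr(streams.rr, FS, wideband_source=pair.rr)
    refiner = BoutRefiner.from_recording(rec, streams.rr)
    bouts = detect_sm_bouts(streams.sm, FS, refine_with=refiner)
    return rec, truth, pair, streams, rate, bouts


@pytest.fixture()
def sine_recording():
    """10-min pure 0.37 Hz single-channel recording."""
    t = np.arange(int(600 * FS)) / FS
    return RawRecording(signal=np.sin(2 * np.pi * 0.37 * t), sampling_rate=FS)


def make_recording(x: np.ndarray, fs: float = FS) -> RawRecording:
    return RawRecording(signal=x, sampling_rate=fs)
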