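"""End-to-end orchestration: recording -> streams -> latencies -> metrics.

The heavy per-night stages stream one night at a time so an 80-night cohort
never holds more than one raw recording in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .classify import (
    CaseScore,
    FeatureVector,
    ROCResult,
    confusion,
    evaluate_family,
    features_from_profile,
    latency_threshold_classify,
)
from .config import ClassifierSpec, PipelineConfig
from .coupling import (
    CaseLatencyProfile,
    LatencySample,
    calibrate_event_onsets,
    case_profile,
    detect_rr_events,
    pair_and_latency,
    segment_windows,
    window_max_latency,
)
from .separation import (
    BoutRefiner,
    RawRecording,
    aggregate_channels,
    band_streams_from_pair,
    detect_sm_bouts,
    instantaneous_rr,
)
from .synthetic import CaseRecord, iter_cohort

log = logging.getLogger("smrr")


@dataclass
class NightResult:
    case_id: str
    night_index: int
    usable: bool
    n_bouts: int
    n_events: int
    samples: List[LatencySample] = field(default_factory=list)
    window_maxima_ms: List[float] = field(default_factory=list)
    binned_rate: Optional[np.ndarray] = None


@dataclass
class CaseResult:
    case_id: str
    label: str
    profile: CaseLatencyProfile
    nights: List[NightResult]


@dataclass
class RunReport:
    seed: int
    config: PipelineConfig
    cases: List[CaseResult]
    metrics: Dict[str, Dict] = field(default_factory=dict)
    scores: Dict[str, List[CaseScore]] = field(default_factory=dict)
    version: str = __version__

    def metrics_payload(self) -> Dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "n_cases": len(self.cases),
            "per_case": {
                c.case_id: {
                    "label": c.label,
                    "n_usable_windows": c.profile.n_usable_windows,
                    "low_coverage": c.profile.low_coverage,
                    "median_max_latency_ms": (
                        float(np.median(c.profile.maxima_ms))
                        if c.profile.maxima_ms
                        else None
                    ),
                }
                for c in self.cases
            },
            "classifiers": self.metrics,
        }


def process_night(rec: RawRecording, config: PipelineConfig) -> NightResult:
    """One night through separation, detection, pairing and window maxima."""
    pair = aggregate_channels(rec)
    streams = band_streams_from_pair(pair, config.bands)
    rate = instantaneous_rr(streams.rr, rec.sampling_rate, config.rr_rate,
                            wideband_source=pair.rr)
    result = NightResult(
        case_id=rec.case_id,
        night_index=rec.night_index,
        usable=rate.usable,
        n_bouts=0,
        n_events=0,
        binned_rate=rate.binned_rate,
    )
    if not rate.usable:
        log.warning("%s night %d: respiration undetectable, night skipped",
                    rec.case_id, rec.night_index)
        return result

    refiner = BoutRefiner.from_recording(rec, streams.rr)
    bouts = detect_sm_bouts(streams.sm, rec.sampling_rate, config.bouts,
                            refine_with=refiner)
    windows = segment_windows(rec.duration_s, rec.night_index,
                              config.events.window_s)
    per_window = []
    events_all = []
    for w in windows:
        evs = detect_rr_events(rate, w, config.events)
        per_window.append((w, len(events_all), len(evs)))
        events_all.extend(evs)
    events_all = calibrate_event_onsets(events_all)

    result.n_bouts = len(bouts)
    result.n_events = len(events_all)
    for w, k0, n_ev in per_window:
        samples = pair_and_latency(bouts, events_all[k0 : k0 + n_ev], w,
                                   config.pairing)
        result.samples.extend(samples)
        wm = window_max_latency(samples, config.pairing.max_mode)
        if wm is not None:
            result.window_maxima_ms.append(wm)
    log.info("%s night %d: %d bouts, %d events, %d pairings, %d usable windows",
             rec.case_id, rec.night_index, len(bouts), len(events_all),
             len(result.samples), len(result.window_maxima_ms))
    return result


def process_case(case: CaseRecord, config: PipelineConfig) -> CaseResult:
    """Both nights of a case pooled into one latency profile."""
    nights = [process_night(rec, config) for rec in case.nights]
    maxima: List[float] = []
    for nr in nights:
        maxima.extend(nr.window_maxima_ms)
    profile = case_profile(case.case_id, maxima, config.histogram)
    return CaseResult(case.case_id, case.label, profile, nights)


def evaluate_cohort(
    cases: Sequence[CaseResult],
    specs: Sequence[ClassifierSpec],
) -> Tuple[Dict[str, Dict], Dict[str, List[CaseScore]]]:
    """Pooled-LOOCV metrics for every requested classifier family."""
    labels = [c.label for c in cases]
    feats: List[FeatureVector] = [features_from_profile(c.profile) for c in cases]
    metrics: Dict[str, Dict] = {}
    scores: Dict[str, List[CaseScore]] = {}
    for spec in specs:
        if spec.family == "latency_threshold":
            pred = [
                latency_threshold_classify(c.profile, spec.threshold_ms)
                for c in cases
            ]
            cm = confusion(pred, labels)
            cs, roc = evaluate_family(feats, labels, spec)
            metrics[spec.family] = {
                "auc": roc.auc,
                "threshold_rule": {
                    "threshold_ms": spec.threshold_ms,
                    **cm.as_dict(),
                },
                "operating_threshold": roc.operating_threshold,
                **roc.confusion.as_dict(),
            }
            scores[spec.family] = cs
            continue
        cs, roc = evaluate_family(feats, labels, spec)
        metrics[spec.family] = {
            "auc": roc.auc,
            "operating_threshold": roc.operating_threshold,
            "degenerate": roc.degenerate,
            **roc.confusion.as_dict(),
        }
        scores[spec.family] = cs
    return metrics, scores


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Simulate (or later: load) a cohort and push it through every stage."""
    config = config.with_classifier_seeds()
    case_results: List[CaseResult] = []
    for case in iter_cohort(config.cohort, config.generator, config.seed):
        case_results.append(process_case(case, config))
    report = RunReport(seed=config.seed, config=config, cases=case_results)
    if config.classifiers:
        report.metrics, report.scores = evaluate_cohort(
            case_results, config.classifiers
        )
    return report
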