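"""Readers and writers for recordings, ground truth, profiles and metrics.

Formats: HDF5 (``/signal`` dataset + ``sampling_rate``/``start_time``
attributes), long-format CSV (``time_s, channel, value`` with the sampling
rate in a comment header), and a minimal EDF reader/writer (16-bit,
identical per-channel rates).  Sampling metadata is always read, never
guessed; timestamp gaps in CSV input are repaired by linear interpolation
onto the uniform grid and logged.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .classify import CaseScore
from .coupling import CaseLatencyProfile, LatencySample
from .separation import RawRecording, SMBout
from .synthetic import CaseRecord, NightTruth

log = logging.getLogger("smrr")


class FormatError(ValueError):
    """Corrupt, truncated or metadata-less input file."""


# ---------------------------------------------------------------------------
# recordings: HDF5


def write_recording_hdf5(rec: RawRecording, path: Path | str,
                         start_time: float = 0.0) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("signal", data=rec.signal)
        ds.attrs["sampling_rate"] = rec.sampling_rate
        ds.attrs["start_time"] = start_time
        ds.attrs["case_id"] = rec.case_id
        ds.attrs["night_index"] = rec.night_index


def read_recording_hdf5(path: Path | str) -> RawRecording:
    try:
        with h5py.File(path, "r") as f:
            ds = f["signal"]
            if "sampling_rate" not in ds.attrs:
                raise FormatError(f"{path}: sampling_rate attribute missing")
            return RawRecording(
                signal=ds[()],
                sampling_rate=float(ds.attrs["sampling_rate"]),
                case_id=str(ds.attrs.get("case_id", "case")),
                night_index=int(ds.attrs.get("night_index", 1)),
            )
    except OSError as exc:
        raise FormatError(f"{path}: not a readable HDF5 file ({exc})") from exc


# ---------------------------------------------------------------------------
# recordings: long-format CSV


def write_recording_csv(rec: RawRecording, path: Path | str) -> None:
    n, c = rec.signal.shape
    t = np.arange(n) / rec.sampling_rate
    with open(path, "w", newline="") as f:
        f.write(f"# sampling_rate_hz={rec.sampling_rate}\n")
        f.write(f"# case_id={rec.case_id} night_index={rec.night_index}\n")
        w = csv.writer(f)
        w.writerow(["time_s", "channel", "value"])
        for ch in range(c):
            for i in range(n):
                w.writerow([f"{t[i]:.12g}", ch, f"{rec.signal[i, ch]:.9g}"])


def read_recording_csv(path: Path | str) -> RawRecording:
    meta: Dict[str, str] = {}
    with open(path) as f:
        pos = f.tell()
        line = f.readline()
        while line.startswith("#"):
            for token in line[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            pos = f.tell()
            line = f.readline()
        f.seek(pos)
        df = pd.read_csv(f)
    if "sampling_rate_hz" not in meta:
        raise FormatError(f"{path}: sampling_rate_hz header missing")
    fs = float(meta["sampling_rate_hz"])
    required = {"time_s", "channel", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: columns {sorted(required)} required")
    channels = sorted(df["channel"].unique())
    t_end = float(df["time_s"].max())
    n = int(round(t_end * fs)) + 1
    grid = np.arange(n) / fs
    sig = np.empty((n, len(channels)))
    n_gaps = 0
    for k, ch in enumerate(channels):
        sub = df[df["channel"] == ch].sort_values("time_s")
        t = sub["time_s"].to_numpy(float)
        v = sub["value"].to_numpy(float)
        gaps = np.diff(t) > 1.5 / fs
        n_gaps += int(gaps.sum())
        sig[:, k] = np.interp(grid, t, v)
    if n_gaps:
        log.info("%s: %d timestamp gap(s) repaired by linear interpolation",
                 path, n_gaps)
    return RawRecording(
        signal=sig,
        sampling_rate=fs,
        case_id=meta.get("case_id", "case"),
        night_index=int(meta.get("night_index", 1)),
    )


# ---------------------------------------------------------------------------
# recordings: minimal EDF (16-bit, one data record per second)


def write_recording_edf(rec: RawRecording, path: Path | str) -> None:
    """Minimal EDF writer (for tests and interchange; integer-second nights)."""
    n, c = rec.signal.shape
    spr = int(round(rec.sampling_rate))  # samples per 1-s record
    n_rec = n // spr
    phys_min = float(rec.signal.min())
    phys_max = float(max(rec.signal.max(), phys_min + 1e-6))
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)

    def pad(s: str, width: int) -> bytes:
        return s[:width].ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8),
        pad(f"{rec.case_id}", 80),
        pad("recording", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 + 256 * c), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),  # record duration, seconds
        pad(str(c), 4),
    ])
    fields = [
        ("label", 16, [f"ch{k}" for k in range(c)]),
        ("transducer", 80, [""] * c),
        ("dim", 8, ["au"] * c),
        ("phys_min", 8, [f"{phys_min:.6g}" for _ in range(c)]),
        ("phys_max", 8, [f"{phys_max:.6g}" for _ in range(c)]),
        ("dig_min", 8, [str(dig_min)] * c),
        ("dig_max", 8, [str(dig_max)] * c),
        ("prefilter", 80, [""] * c),
        ("spr", 8, [str(spr)] * c),
        ("reserved", 32, [""] * c),
    ]
    with open(path, "wb") as f:
        f.write(header)
        for _, width, values in fields:
            for v in values:
                f.write(pad(v, width))
        for r in range(n_rec):
            block = rec.signal[r * spr : (r + 1) * spr]
            dig = np.clip(
                np.round((block - phys_min) / scale) + dig_min, dig_min, dig_max
            ).astype("<i2")
            f.write(dig.T.tobytes())  # per-signal contiguity within a record


def read_recording_edf(path: Path | str) -> RawRecording:
    try:
        with open(path, "rb") as f:
            head = f.read(256)
            if len(head) < 256:
                raise FormatError(f"{path}: truncated EDF header")
            n_rec = int(head[236:244].decode("ascii").strip())
            rec_dur = float(head[244:252].decode("ascii").strip())
            c = int(head[252:256].decode("ascii").strip())
            sig_head = f.read(256 * c)
            if len(sig_head) < 256 * c:
                raise FormatError(f"{path}: truncated EDF signal header")

            def col(offset: int, width: int) -> List[str]:
                base = offset * c
                return [
                    sig_head[base + k * width : base + (k + 1) * width]
                    .decode("ascii")
                    .strip()
                    for k in range(c)
                ]

            phys_min = [float(v) for v in col(16 + 80 + 8, 8)]
            phys_max = [float(v) for v in col(16 + 80 + 8 + 8, 8)]
            dig_min = [int(v) for v in col(16 + 80 + 8 + 8 + 8, 8)]
            dig_max = [int(v) for v in col(16 + 80 + 8 + 8 + 8 + 8, 8)]
            # samples-per-record sits after label/transducer/dim, the four
            # 8-byte range fields, and the 80-byte prefilter field
            spr = [int(v) for v in col(16 + 80 + 8 + 8 * 4 + 80, 8)]
            if len(set(spr)) != 1:
                raise FormatError(f"{path}: per-channel sampling rates differ")
            if rec_dur <= 0:
                raise FormatError(f"{path}: record duration missing")
            fs = spr[0] / rec_dur
            n = n_rec * spr[0]
            sig = np.empty((n, c))
            for r in range(n_rec):
                raw = f.read(2 * spr[0] * c)
                if len(raw) < 2 * spr[0] * c:
                    raise FormatError(f"{path}: truncated EDF data record")
                block = np.frombuffer(raw, dtype="<i2").reshape(c, spr[0])
                for k in range(c):
                    scale = (phys_max[k] - phys_min[k]) / (dig_max[k] - dig_min[k])
                    sig[r * spr[0] : (r + 1) * spr[0], k] = (
                        (block[k].astype(float) - dig_min[k]) * scale + phys_min[k]
                    )
    except (ValueError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: malformed EDF ({exc})") from exc
    return RawRecording(signal=sig, sampling_rate=fs)


def read_recording(path: Path | str, fmt: Optional[str] = None) -> RawRecording:
    """Dispatch on explicit format or file suffix (h5/hdf5, csv, edf)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    fmt = fmt or p.suffix.lstrip(".").lower()
    if fmt in ("h5", "hdf5"):
        return read_recording_hdf5(p)
    if fmt == "csv":
        return read_recording_csv(p)
    if fmt == "edf":
        return read_recording_edf(p)
    raise FormatError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------------------
# ground truth / manifest / detections


def write_ground_truth_csv(truths: Sequence[NightTruth], path: Path | str) -> None:
    rows = []
    for night, truth in enumerate(truths, start=1):
        for b in truth.bouts:
            rows.append({
                "night": night,
                "bout_onset_s": b.onset_s,
                "bout_offset_s": b.offset_s,
                "event_onset_s": b.event_onset_s if b.coupled else "",
                "latency_ms": b.latency_ms if b.coupled else "",
                "coupled": int(b.coupled),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_manifest_csv(rows: Sequence[Dict], path: Path | str) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest_csv(path: Path | str) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"manifest not found: {p}")
    df = pd.read_csv(p)
    required = {"case_id", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{p}: manifest needs columns {sorted(required)}")
    return df


def write_bouts_csv(bouts: Sequence[SMBout], path: Path | str) -> None:
    pd.DataFrame(
        [
            {
                "onset_s": b.onset_s,
                "offset_s": b.offset_s,
                "peak_amplitude": b.peak_amplitude,
                "auc": b.auc,
            }
            for b in bouts
        ]
    ).to_csv(path, index=False)


def write_latency_samples_csv(
    samples: Sequence[LatencySample], path: Path | str, case_id: str = ""
) -> None:
    pd.DataFrame(
        [
            {
                "case_id": case_id,
                "night": s.night_index,
                "window": s.window_index,
                "bout_onset_s": s.bout.onset_s,
                "event_onset_s": s.event.onset_s,
                "latency_ms": s.latency_ms,
            }
            for s in samples
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# profiles / scores / metrics


def write_profile_json(profile: CaseLatencyProfile, path: Path | str) -> None:
    payload = {
        "case_id": profile.case_id,
        "maxima_ms": list(profile.maxima_ms),
        "bin_edges_ms": profile.bin_edges_ms.tolist(),
        "density": profile.density.tolist(),
        "n_usable_windows": profile.n_usable_windows,
        "low_coverage": profile.low_coverage,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_profile_json(path: Path | str) -> CaseLatencyProfile:
    d = json.loads(Path(path).read_text())
    return CaseLatencyProfile(
        case_id=d["case_id"],
        maxima_ms=[float(v) for v in d["maxima_ms"]],
        bin_edges_ms=np.asarray(d["bin_edges_ms"], dtype=float),
        density=np.asarray(d["density"], dtype=float),
        n_usable_windows=int(d["n_usable_windows"]),
        low_coverage=bool(d["low_coverage"]),
    )


def write_scores_csv(scores: Sequence[CaseScore], path: Path | str) -> None:
    pd.DataFrame(
        [
            {"case_id": s.case_id, "label": s.label, "score": s.score, "fold": s.fold}
            for s in scores
        ]
    ).to_csv(path, index=False)


def write_metrics_json(payload: Dict, path: Path | str) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_case_files(case: CaseRecord, out_dir: Path | str,
                     fmt: str = "hdf5") -> Dict[str, str]:
    """Persist one synthetic case; returns the manifest row."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    row: Dict[str, str] = {"case_id": case.case_id, "label": case.label}
    for k, rec in enumerate(case.nights, start=1):
        suffix = "h5" if fmt == "hdf5" else fmt
        p = out / f"{case.case_id}_night{k}.{suffix}"
        if fmt == "hdf5":
            write_recording_hdf5(rec, p)
        elif fmt == "csv":
            write_recording_csv(rec, p)
        elif fmt == "edf":
            write_recording_edf(rec, p)
        else:
            raise FormatError(f"unknown recording format {fmt!r}")
        row[f"night{k}_path"] = str(p)
    truth_path = out / f"{case.case_id}_truth.csv"
    write_ground_truth_csv(case.truths, truth_path)
    row["truth_path"] = str(truth_path)
    return row
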