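"""Reading and writing recordings: EDF+ and CSV, plus cohort manifests.

CSV recordings are two files: ``<stem>.csv`` with columns (time_s, eeg_uv)
and ``<stem>.events.csv`` with columns (event, time_s).

EDF+ files are written by a small built-in EDF+C writer (one EEG channel,
events as EDF+ annotations) and read back through :func:`mne.io.read_raw_edf`,
which doubles as an independent check on the writer in the test suite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthcohort import EEGRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_edf",
    "read_edf",
    "write_csv",
    "read_csv",
    "write_manifest",
    "read_manifest",
]

_EVENT_NAMES = ("LOR", "ROR", "emergence_start")


# ---------------------------------------------------------------------------
# CSV


def write_csv(rec: EEGRecording, path) -> Path:
    path = Path(path)
    t = np.arange(len(rec.samples)) / rec.sample_rate_hz
    pd.DataFrame({"time_s": t, "eeg_uv": rec.samples}).to_csv(path, index=False)
    ev = pd.DataFrame(
        {"event": list(rec.events), "time_s": list(rec.events.values())}
    )
    ev.to_csv(path.with_suffix(".events.csv"), index=False)
    return path


def read_csv(path, required_events: tuple[str, ...] = ()) -> EEGRecording:
    path = Path(path)
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("recording CSV must contain at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform timestamps in recording CSV")
    fs = 1.0 / dt[0]
    ev_path = path.with_suffix(".events.csv")
    events = {}
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        events = dict(zip(ev["event"], ev["time_s"].astype(float)))
    missing = [e for e in required_events if e not in events]
    if missing:
        raise ValueError(f"missing event annotation(s): {', '.join(missing)}")
    rec = EEGRecording(
        samples=df["eeg_uv"].to_numpy(float),
        sample_rate_hz=float(round(fs, 6)),
        events=events,
        subject_id=path.stem,
    )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# EDF+ writer (EDF+C, one EEG signal + one annotation signal)

_ANNOT_SAMPLES_PER_RECORD = 60  # 120 bytes of TAL space per 1 s record


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r}")
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path) -> Path:
    """Write a single-channel EDF+C file with events as EDF+ annotations.

    The record duration is 1 s; the recording is zero-padded to a whole
    number of seconds if needed.
    """
    path = Path(path)
    fs = rec.sample_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    fs = int(round(fs))
    x = np.asarray(rec.samples, float)
    n_rec = int(np.ceil(len(x) / fs))
    x = np.pad(x, (0, n_rec * fs - len(x)))

    phys_max = float(max(np.abs(x).max(), 1.0))
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((x - phys_min) * scale + dig_min).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad(rec.subject_id or "X X X X", 80),
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * 3), 8),
            _pad("EDF+C", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad("2", 4),
        ]
    )
    labels = [_pad("EEG Fpz-A1", 16), _pad("EDF Annotations", 16)]
    transducer = [_pad("AgAgCl electrode", 80), _pad("", 80)]
    phys_dim = [_pad("uV", 8), _pad("", 8)]
    pmin = [_pad(f"{phys_min:.6g}"[:8], 8), _pad("-1", 8)]
    pmax = [_pad(f"{phys_max:.6g}"[:8], 8), _pad("1", 8)]
    dmin = [_pad(str(dig_min), 8), _pad("-32768", 8)]
    dmax = [_pad(str(dig_max), 8), _pad("32767", 8)]
    prefilter = [_pad("HP:6Hz LP:42Hz", 80), _pad("", 80)]
    n_samp = [_pad(str(fs), 8), _pad(str(_ANNOT_SAMPLES_PER_RECORD), 8)]
    reserved = [_pad("", 32), _pad("", 32)]
    for fields in (labels, transducer, phys_dim, pmin, pmax, dmin, dmax,
                   prefilter, n_samp, reserved):
        header += b"".join(fields)

    ann_bytes = 2 * _ANNOT_SAMPLES_PER_RECORD
    with open(path, "wb") as fh:
        fh.write(header)
        for k in range(n_rec):
            fh.write(digital[k * fs : (k + 1) * fs].tobytes())
            tal = f"+{k}\x14\x14\x00".encode("ascii")
            if k == 0:
                for name, t in sorted(rec.events.items(), key=lambda kv: kv[1]):
                    tal += f"+{t:g}\x14{name}\x14\x00".encode("ascii")
            if len(tal) > ann_bytes:
                raise ValueError("too many annotations for the TAL record size")
            fh.write(tal + b"\x00" * (ann_bytes - len(tal)))
    return path


def read_edf(path, required_events: tuple[str, ...] = ()) -> EEGRecording:
    """Read a single-channel EDF/EDF+ recording via mne."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(picks=[0])[0] * 1e6  # mne returns volts
    events = {}
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc in _EVENT_NAMES:
            events[desc] = float(onset)
    missing = [e for e in required_events if e not in events]
    if missing:
        raise ValueError(f"missing event annotation(s): {', '.join(missing)}")
    rec = EEGRecording(
        samples=data,
        sample_rate_hz=float(raw.info["sfreq"]),
        events=events,
        subject_id=Path(path).stem,
    )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# dispatch and manifest


def write_recording(rec: EEGRecording, path, fmt: str | None = None) -> Path:
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        return write_edf(rec, path)
    if fmt == "csv":
        return write_csv(rec, path)
    raise ValueError(f"unknown recording format {fmt!r}")


def read_recording(
    path,
    fmt: str | None = None,
    required_events: tuple[str, ...] = (),
    expected_sample_rate_hz: float | None = None,
) -> EEGRecording:
    """Read an EDF or CSV recording with validation.

    A sample-rate mismatch with ``expected_sample_rate_hz`` fails loudly
    (no silent resampling).
    """
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        rec = read_edf(path, required_events)
    elif fmt == "csv":
        rec = read_csv(path, required_events)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")
    if expected_sample_rate_hz is not None and not np.isclose(
        rec.sample_rate_hz, expected_sample_rate_hz, rtol=1e-6
    ):
        raise ValueError(
            f"sample rate {rec.sample_rate_hz} Hz does not match configured "
            f"{expected_sample_rate_hz} Hz (resampling is not applied implicitly)"
        )
    return rec


def write_manifest(recs, path) -> Path:
    """Cohort manifest CSV: subject, group, event times, truth parameters."""
    rows = []
    for rec in recs:
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "duration_s": rec.duration_s,
            "sample_rate_hz": rec.sample_rate_hz,
        }
        for name in _EVENT_NAMES:
            row[f"event_{name}"] = rec.events.get(name, np.nan)
        if rec.truth:
            row["truth_json"] = json.dumps(rec.truth, sort_keys=True)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return Path(path)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)
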