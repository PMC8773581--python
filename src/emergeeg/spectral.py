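"""Windowed power spectral density and density spectral arrays (DSA).

PSDs are Welch estimates over 10 s episodes advanced in 1 s steps; stacking
episode PSDs over time yields the density spectral array used to visualize
and compare anesthesia emergence spectra.  Within each 10 s episode the Welch
estimator averages 2 s Hamming-tapered sub-windows at 50% overlap (0.5 Hz
resolution), a variance/resolution trade-off adequate to separate alpha from
beta activity.

A window [t, t+window) is indexed by its start time t, so the "value 15 s
before an event" is the window starting at event-15 s, which contains only
pre-event EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

__all__ = [
    "Spectrogram",
    "ParamTrend",
    "psd",
    "dsa",
    "band_power",
    "extract_window_at",
    "to_db",
]

WELCH_SUBWINDOW_S = 2.0
REPORTING_BAND = (6.0, 30.0)


@dataclass
class Spectrogram:
    """Time x frequency power grid in uV^2/Hz (or per-window relative power)."""

    times: np.ndarray  # window-start seconds
    freqs: np.ndarray  # Hz bin centers
    power: np.ndarray  # shape (len(times), len(freqs))
    window_s: float
    hop_s: float
    normalized: bool = False
    norm_band: tuple[float, float] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.freqs = np.asarray(self.freqs, float)
        self.power = np.asarray(self.power, float)
        if self.power.shape != (len(self.times), len(self.freqs)):
            raise ValueError("power grid shape does not match times x freqs")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        t, f = np.meshgrid(self.times, self.freqs, indexing="ij")
        return pd.DataFrame(
            {"time_s": t.ravel(), "freq_hz": f.ravel(), "power": self.power.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, window_s=10.0, hop_s=1.0, normalized=False) -> "Spectrogram":
        df = pd.read_csv(path)
        times = np.unique(df["time_s"].to_numpy())
        freqs = np.unique(df["freq_hz"].to_numpy())
        grid = (
            df.pivot(index="time_s", columns="freq_hz", values="power")
            .loc[times, freqs]
            .to_numpy()
        )
        return cls(times, freqs, grid, window_s, hop_s, normalized)


@dataclass
class ParamTrend:
    """A time-stamped scalar parameter series on the analysis window grid."""

    times: np.ndarray
    values: np.ndarray
    name: str = "value"
    band: tuple[float, float] | None = None
    window_s: float = 10.0
    hop_s: float = 1.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")

    def to_frame(self) -> pd.DataFrame:
        d = {"time_s": self.times, self.name: self.values}
        for k, v in self.extra.items():
            d[k] = v
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _as_samples(rec_or_samples):
    if hasattr(rec_or_samples, "samples"):
        return np.asarray(rec_or_samples.samples, float), float(
            rec_or_samples.sample_rate_hz
        )
    return None


def psd(segment: np.ndarray, sample_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD of a segment, density in uV^2/Hz.

    2 s Hamming sub-windows, 50% overlap, per-window mean removal.
    """
    x = np.asarray(segment, float)
    if x.ndim < 1 or x.shape[-1] < 2 * sample_rate_hz:
        raise ValueError("segment must be at least 2 s long")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite samples")
    nperseg = int(round(WELCH_SUBWINDOW_S * sample_rate_hz))
    freqs, density = signal.welch(
        x,
        fs=sample_rate_hz,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        axis=-1,
    )
    return freqs, density


def dsa(
    rec,
    window_s: float = 10.0,
    hop_s: float = 1.0,
    normalized: bool = False,
    norm_band: tuple[float, float] = REPORTING_BAND,
) -> Spectrogram:
    """Density spectral array: one Welch PSD per window start 0, hop, 2*hop...

    If ``normalized``, each row is divided by its own integral over
    ``norm_band`` so rows integrate to 1 over that band.
    """
    got = _as_samples(rec)
    if got is None:
        raise TypeError("dsa expects an EEGRecording-like object with .samples")
    x, fs = got
    wlen = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    if wlen > len(x):
        raise ValueError("window longer than record")
    windows = sliding_window_view(x, wlen)[::hop]
    freqs, rows = psd(windows, fs)
    times = np.arange(rows.shape[0]) * hop_s
    if normalized:
        rows = rows / _band_integral(freqs, rows, norm_band)[:, None]
    return Spectrogram(
        times, freqs, rows, window_s, hop_s, normalized, norm_band if normalized else None
    )


def _band_slice(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    low, high = band
    if low >= high:
        raise ValueError("band must satisfy low < high")
    if low < freqs[0] - 1e-9 or high > freqs[-1] + 1e-9:
        raise ValueError(
            f"band {band} outside frequency support [{freqs[0]}, {freqs[-1]}] Hz"
        )
    return (freqs >= low - 1e-9) & (freqs <= high + 1e-9)


def _band_integral(freqs, rows, band) -> np.ndarray:
    sel = _band_slice(freqs, band)
    return np.trapezoid(rows[..., sel], freqs[sel], axis=-1)


def band_power(spec: Spectrogram, band: tuple[float, float], name: str | None = None) -> ParamTrend:
    """Trapezoidal band-integrated power trend, uV^2 per window."""
    values = _band_integral(spec.freqs, spec.power, band)
    return ParamTrend(
        spec.times,
        values,
        name=name or f"power_{band[0]:g}_{band[1]:g}",
        band=band,
        window_s=spec.window_s,
        hop_s=spec.hop_s,
    )


def extract_window_at(obj, event_time_s: float, offset_s: float = 0.0):
    """Value (trend) or PSD row (spectrogram) at the window nearest event+offset.

    The window grid is indexed by window starts; the request must fall within
    half a hop of an existing window start, otherwise a ValueError is raised
    (out-of-coverage requests are never silently clamped).
    """
    target = event_time_s + offset_s
    times = obj.times
    hop = getattr(obj, "hop_s", None) or float(np.median(np.diff(times)))
    if target < times[0] - hop / 2 or target > times[-1] + hop / 2:
        raise ValueError(
            f"requested time {target:g} s outside window coverage "
            f"[{times[0]:g}, {times[-1]:g}] s"
        )
    idx = int(np.argmin(np.abs(times - target)))
    if isinstance(obj, Spectrogram):
        return obj.freqs, obj.power[idx]
    return obj.values[idx]


def to_db(power, ref: float = 1.0):
    """Display-only dB conversion, 10*log10(power/ref)."""
    return 10.0 * np.log10(np.maximum(np.asarray(power, float), 1e-300) / ref)
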