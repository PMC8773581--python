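"""Transparent depth-of-anesthesia index from spectral sub-parameters.

Commercial cerebral-state monitors combine a small set of spectral log-energy
ratios and the burst-suppression ratio into a dimensionless 0-100 index via a
proprietary adaptive neuro-fuzzy system.  This module computes the stated
inputs transparently and maps them through a fixed monotone logistic
combination instead -- a reproducible proxy, with no claim of numerical
equivalence to any commercial index.

Sub-parameters (energies E from trapezoid band integration of the PSD):

* ``alpha_ratio`` = ln(E[30-42] / E[6-12])
* ``beta_ratio``  = ln(E[30-42] / E[11-21])
* ``beta_over_alpha`` = beta_ratio - alpha_ratio (the log of the quotient of
  the two energy ratios; stored as a difference to avoid dividing signed logs)
* ``bsr_percent`` -- percentage of the window spent in near-isoelectric runs.

Band edges follow the published cerebral-state-index sub-parameter family;
the exact commercial bands are proprietary, so these are package design
choices, not vendor facts.

The index is ``100 * sigmoid(w . params) * (1 - BS%/100)``: monotone
nondecreasing in each spectral ratio, non-increasing in BS%, 0 under full
suppression.  The default weights were calibrated once on the synthetic
generator (awake-like segments map to >= 85, deep-anesthesia-like to <= 50)
and are frozen; they are never refit at analysis time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import ParamTrend, psd

__all__ = [
    "SubParams",
    "IndexTrend",
    "IndexMapping",
    "DEFAULT_INDEX_MAPPING",
    "burst_suppression_ratio",
    "sub_params",
    "composite_index",
    "index_trend",
]

HIGH_BAND = (30.0, 42.0)
ALPHA_BAND = (6.0, 12.0)
BETA_BAND = (11.0, 21.0)
ENERGY_FLOOR_UV2 = 1e-6  # prevents -inf log ratios on suppressed windows


@dataclass(frozen=True)
class SubParams:
    alpha_ratio: float
    beta_ratio: float
    beta_over_alpha: float
    bsr_percent: float
    window_time_s: float = float("nan")

    def __post_init__(self):
        if not 0.0 <= self.bsr_percent <= 100.0:
            raise ValueError("bsr_percent must lie in [0, 100]")


@dataclass(frozen=True)
class IndexMapping:
    """Frozen logistic combination of the spectral sub-parameters."""

    intercept: float
    w_alpha_ratio: float
    w_beta_ratio: float
    w_beta_over_alpha: float

    def score(self, p: SubParams) -> float:
        return (
            self.intercept
            + self.w_alpha_ratio * p.alpha_ratio
            + self.w_beta_ratio * p.beta_ratio
            + self.w_beta_over_alpha * p.beta_over_alpha
        )


# Calibrated once on the default synthetic generator (see docs/methods.md);
# versioned constants, never refit at analysis time.
DEFAULT_INDEX_MAPPING = IndexMapping(
    intercept=4.5,
    w_alpha_ratio=1.4,
    w_beta_ratio=1.4,
    w_beta_over_alpha=0.2,
)


@dataclass
class IndexTrend:
    """0-100 composite index trend with its sub-parameters per window."""

    times: np.ndarray
    csi_like: np.ndarray
    bsr_percent: np.ndarray
    alpha_ratio: np.ndarray
    beta_ratio: np.ndarray
    quality: np.ndarray
    window_s: float = 10.0
    hop_s: float = 1.0

    @property
    def values(self) -> np.ndarray:  # ParamTrend-compatible access
        return self.csi_like

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "csi_like": self.csi_like,
                "bsr_percent": self.bsr_percent,
                "alpha_ratio": self.alpha_ratio,
                "beta_ratio": self.beta_ratio,
                "quality": self.quality.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def as_param_trend(self) -> ParamTrend:
        return ParamTrend(
            self.times, self.csi_like, name="csi_like",
            window_s=self.window_s, hop_s=self.hop_s,
        )


def burst_suppression_ratio(
    segment,
    sample_rate_hz: float,
    amp_threshold_uv: float = 5.0,
    min_suppress_s: float = 0.5,
    smooth_s: float = 0.2,
) -> float:
    """Percent of the segment spent in suppression runs of >= min_suppress_s.

    The instantaneous amplitude is a moving RMS envelope over ``smooth_s``;
    samples where it stays below ``amp_threshold_uv`` for at least
    ``min_suppress_s`` contiguously count as suppressed.
    """
    x = np.asarray(segment, float)
    if amp_threshold_uv <= 0:
        raise ValueError("amp_threshold_uv must be positive")
    if len(x) < 5 * sample_rate_hz:
        raise ValueError("segment must be at least 5 s long")
    win = max(int(round(smooth_s * sample_rate_hz)), 1)
    kernel = np.ones(win) / win
    env = np.sqrt(np.convolve(x**2, kernel, mode="same"))
    below = env < amp_threshold_uv
    min_run = int(round(min_suppress_s * sample_rate_hz))
    edges = np.diff(np.concatenate(([0], below.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    lengths = ends - starts
    suppressed = int(lengths[lengths >= min_run].sum())
    return 100.0 * suppressed / len(x)


def _band_energy(freqs: np.ndarray, density: np.ndarray, band) -> float:
    low, high = band
    if low < freqs[0] - 1e-9 or high > freqs[-1] + 1e-9:
        raise ValueError(f"PSD does not cover the {band} Hz band")
    sel = (freqs >= low - 1e-9) & (freqs <= high + 1e-9)
    return float(np.trapezoid(density[sel], freqs[sel]))


def sub_params(
    freqs: np.ndarray,
    density: np.ndarray,
    bsr_percent: float = 0.0,
    window_time_s: float = float("nan"),
) -> SubParams:
    """Spectral log-energy ratios plus BS% from one PSD row.

    Requires PSD coverage of 6-42 Hz; band energies are floored at a small
    positive constant so fully suppressed windows give finite ratios.
    """
    freqs = np.asarray(freqs, float)
    density = np.asarray(density, float)
    e_high = max(_band_energy(freqs, density, HIGH_BAND), ENERGY_FLOOR_UV2)
    e_alpha = max(_band_energy(freqs, density, ALPHA_BAND), ENERGY_FLOOR_UV2)
    e_beta = max(_band_energy(freqs, density, BETA_BAND), ENERGY_FLOOR_UV2)
    ar = float(np.log(e_high / e_alpha))
    br = float(np.log(e_high / e_beta))
    return SubParams(
        alpha_ratio=ar,
        beta_ratio=br,
        beta_over_alpha=br - ar,
        bsr_percent=float(bsr_percent),
        window_time_s=window_time_s,
    )


def composite_index(params: SubParams, mapping: IndexMapping = DEFAULT_INDEX_MAPPING) -> float:
    """Monotone 0-100 index: logistic map of the ratios, pulled to 0 by BS%."""
    z = mapping.score(params)
    idx = 100.0 / (1.0 + np.exp(-z))
    idx *= 1.0 - params.bsr_percent / 100.0
    return float(np.clip(idx, 0.0, 100.0))


def index_trend(
    rec,
    mapping: IndexMapping = DEFAULT_INDEX_MAPPING,
    window_s: float = 10.0,
    hop_s: float = 1.0,
    amp_threshold_uv: float = 5.0,
    min_suppress_s: float = 0.5,
    smooth_len: int = 0,
) -> IndexTrend:
    """Windowed sub-parameters and composite index on the DSA grid.

    ``smooth_len`` > 1 applies a trailing moving average to the index,
    emulating the display smoothing (and its delay) of commercial monitors;
    default off.  Windows containing non-finite samples get quality=False and
    a NaN index.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    fs = float(rec.sample_rate_hz)
    x = np.asarray(rec.samples, float)
    wlen = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    if wlen > len(x):
        raise ValueError("window longer than record")
    windows = sliding_window_view(x, wlen)[::hop]
    n = windows.shape[0]
    times = np.arange(n) * hop_s
    csi = np.full(n, np.nan)
    bsr = np.full(n, np.nan)
    ar = np.full(n, np.nan)
    br = np.full(n, np.nan)
    quality = np.zeros(n, dtype=bool)
    for i, w in enumerate(windows):
        if not np.all(np.isfinite(w)):
            continue
        quality[i] = True
        bsr[i] = burst_suppression_ratio(
            w, fs, amp_threshold_uv=amp_threshold_uv, min_suppress_s=min_suppress_s
        )
    good = quality
    if good.any():
        freqs, rows = psd(windows[good], fs)
        idx_good = np.flatnonzero(good)
        for j, i in enumerate(idx_good):
            p = sub_params(freqs, rows[j], bsr_percent=bsr[i], window_time_s=times[i])
            csi[i] = composite_index(p, mapping)
            ar[i] = p.alpha_ratio
            br[i] = p.beta_ratio
    if smooth_len and smooth_len > 1:
        smoothed = csi.copy()
        for i in range(n):
            lo = max(0, i - smooth_len + 1)
            seg = csi[lo : i + 1]
            good = np.isfinite(seg)
            smoothed[i] = seg[good].mean() if good.any() else np.nan
        csi = smoothed
    return IndexTrend(times, csi, bsr, ar, br, quality, window_s, hop_s)
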