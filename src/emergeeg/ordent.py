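"""Ordinal-pattern (permutation) entropy trends.

Permutation entropy is the Shannon entropy, in bits, of the distribution of
rank-order patterns of ``m`` samples taken at lag ``tau`` from a time series.
With the defaults used throughout this package (m=3, tau=1) the entropy lies
in [0, log2 6 ~= 2.585] bits; reported anesthesia values around 2.2-2.5 bits
are only consistent with base-2 logarithms, which is why bits are the unit
here.  The EEG is low-pass filtered to 30 Hz once per recording (zero-phase
4th-order Butterworth) before windowing, limiting muscle-activity leakage and
avoiding per-window filter transients.

Ties between equal samples are broken by temporal order (the earlier sample
ranks lower), the original ordinal-pattern convention; on continuous EEG ties
are a measure-zero event but quantized or synthetic signals need the rule for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .spectral import ParamTrend

__all__ = [
    "OrdinalConfig",
    "ordinal_pattern",
    "permutation_entropy",
    "peen_trend",
]


@dataclass(frozen=True)
class OrdinalConfig:
    m: int = 3
    tau: int = 1
    lowpass_hz: float = 30.0
    tie_policy: str = "temporal"

    def validate(self, sample_rate_hz: float | None = None) -> None:
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if self.tau < 1:
            raise ValueError("time lag tau must be >= 1")
        if self.tie_policy != "temporal":
            raise ValueError(f"unknown tie policy {self.tie_policy!r}")
        if sample_rate_hz is not None and self.lowpass_hz > sample_rate_hz / 2:
            raise ValueError("lowpass_hz exceeds Nyquist frequency")


def _perm_ids(windows: np.ndarray, m: int) -> np.ndarray:
    """Lexicographic id of the stable-argsort permutation of each row."""
    perms = np.argsort(windows, axis=-1, kind="stable")
    base = np.array([factorial(m - 1 - k) for k in range(m)])
    # convert permutation to Lehmer code for a dense id in [0, m!)
    ids = np.zeros(perms.shape[:-1], dtype=np.int64)
    for k in range(m):
        smaller = (perms[..., k + 1 :] < perms[..., k : k + 1]).sum(axis=-1)
        ids += smaller * base[k]
    return ids


def ordinal_pattern(window, tie_policy: str = "temporal") -> int:
    """Id of the permutation sorting ``window`` ascending (ties: temporal order).

    Ids are the Lehmer (lexicographic) rank of the argsort permutation: the
    identity pattern (already ascending) has id 0, the descending pattern has
    id m!-1.
    """
    if tie_policy != "temporal":
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    w = np.asarray(window, float)
    if w.ndim != 1 or len(w) < 2:
        raise ValueError("window must be a 1-D array of m >= 2 samples")
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains non-finite samples")
    return int(_perm_ids(w[None, :], len(w))[0])


def permutation_entropy(segment, config: OrdinalConfig = OrdinalConfig()) -> float:
    """Permutation entropy of a segment in bits, H = -sum p_i log2 p_i.

    Probabilities are the relative frequencies of the m! ordinal patterns over
    all N-(m-1)*tau lag-tau windows; absent patterns contribute nothing and no
    normalization is applied, so H is in [0, log2 m!].
    """
    config.validate()
    x = np.asarray(segment, float)
    m, tau = config.m, config.tau
    if x.ndim != 1 or len(x) < (m - 1) * tau + 1:
        raise ValueError("segment too short for the requested embedding")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite samples")
    windows = sliding_window_view(x, (m - 1) * tau + 1)[:, ::tau]
    ids = _perm_ids(windows, m)
    counts = np.bincount(ids, minlength=factorial(m))
    p = counts[counts > 0] / len(ids)
    return float(-(p * np.log2(p)).sum())


def peen_trend(
    rec,
    config: OrdinalConfig = OrdinalConfig(),
    window_s: float = 10.0,
    hop_s: float = 1.0,
) -> ParamTrend:
    """Windowed permutation entropy on the DSA time grid.

    The recording is low-pass filtered once (zero-phase Butterworth at
    ``config.lowpass_hz``) before windowing.
    """
    fs = float(rec.sample_rate_hz)
    config.validate(fs)
    x = np.asarray(rec.samples, float)
    wlen = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    if wlen > len(x):
        raise ValueError("window longer than record")
    if config.lowpass_hz < fs / 2:
        sos = signal.butter(4, config.lowpass_hz, btype="low", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, x)
    windows = sliding_window_view(x, wlen)[::hop]
    values = np.array([permutation_entropy(w, config) for w in windows])
    times = np.arange(len(values)) * hop_s
    return ParamTrend(times, values, name="peen_bits", window_s=window_s, hop_s=hop_s)
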