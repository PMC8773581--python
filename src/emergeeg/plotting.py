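"""Figures: density spectral arrays, AUC maps with cluster contours, durations."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .groupcompare import AUCMap
from .spectral import Spectrogram, to_db

__all__ = ["plot_dsa", "plot_auc_map", "plot_duration_box"]


def plot_dsa(spec: Spectrogram, ax=None, db: bool = True, vmin=None, vmax=None):
    """Time x frequency heat map of a spectrogram (dB re 1 uV^2/Hz)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    z = to_db(spec.power) if db else spec.power
    mesh = ax.pcolormesh(spec.times, spec.freqs, z.T, shading="nearest", cmap="turbo")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    label = "power (dB re 1 $\\mu V^2$/Hz)" if db else "power ($\\mu V^2$/Hz)"
    plt.colorbar(mesh, ax=ax, label=label)
    return ax


def plot_auc_map(m: AUCMap, ax=None):
    """Pixel-wise AUC heat map; retained clusters outlined in black."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    mesh = ax.pcolormesh(
        m.times, m.freqs, m.auc.T, shading="nearest", cmap="RdBu_r", vmin=0, vmax=1
    )
    if m.cluster_mask.any():
        ax.contour(
            m.times, m.freqs, m.cluster_mask.T.astype(float),
            levels=[0.5], colors="k", linewidths=1.0,
        )
    ax.set_xlabel("time relative to event (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(f"AUC: {m.labels[1]} vs {m.labels[0]}")
    plt.colorbar(mesh, ax=ax, label="AUC")
    return ax


def plot_duration_box(durations: pd.DataFrame, ax=None, threshold: float = 80.0):
    """Box plot of per-group index-above-threshold durations before ROR."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    groups = list(durations["group"].unique())
    data = [durations.loc[durations["group"] == g, "duration_s"] for g in groups]
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel(f"duration index >= {threshold:g} before ROR (s)")
    for i, vals in enumerate(data, start=1):
        x = np.random.default_rng(0).normal(i, 0.04, len(vals))
        ax.plot(x, vals, "o", ms=3, alpha=0.5)
    return ax
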