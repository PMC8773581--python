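"""Synthetic single-channel EEG cohorts for anesthesia transition analyses.

The generator emulates the statistical structure of frontal EEG recorded by a
band-limited depth-of-anesthesia monitor (100 Hz sampling, ~6-42 Hz pass band)
around two behaviorally verified state transitions:

* **induction** -- an awake-like broadband signal (relatively high beta, weak
  alpha) transitions over ~1 min around loss of responsiveness (LOR) into an
  alpha-dominant, beta-poor anesthesia signal;
* **emergence** -- an alpha-dominant anesthesia signal in which a fast
  (beta-and-above) component ramps up some subject-specific lead time before
  return of responsiveness (ROR).  The lead time is Gamma-distributed with a
  group-specific mean, so anesthetic groups differ in how early the "fast"
  EEG activation occurs -- the phenomenon that drives every downstream group
  comparison in this package.

Each component is built from spectrally shaped Gaussian noise (1/f^gamma
background, ~2 Hz-wide alpha bump, flat fast band), modulated by slow
amplitude envelopes and optionally interrupted by near-isoelectric
(burst-suppression) epochs.  All randomness flows from per-subject
``numpy.random.SeedSequence`` substreams derived from the master seed, so a
cohort is a pure function of its configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "CohortConfig",
    "EEGRecording",
    "simulate_subject",
    "simulate_induction",
    "simulate_cohort",
    "simulate_stationary",
    "analytic_psd",
]

DEFAULT_GROUPS = ("propofol", "sevoflurane", "isoflurane")

# Group-specific mean lead (s) of fast-band activation before ROR.  Volatile
# maintenance shows "wake-like" fast activity minutes before ROR; intravenous
# maintenance only shortly before.  The two volatile groups share a mean so
# that their emergence trajectories are statistically exchangeable.
DEFAULT_BETA_ONSET_MEAN_S: Mapping[str, float] = {
    "propofol": 60.0,
    "sevoflurane": 270.0,
    "isoflurane": 270.0,
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Power parameters are stationary full-amplitude variances in uV^2; with the
    defaults the root-mean-square amplitude of a deep-anesthesia segment is
    roughly 15 uV and of an awake-like segment roughly 13 uV, in the range
    typical for frontal adult EEG.
    """

    n_per_group: int = 15
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    sample_rate_hz: float = 100.0
    band_limit_hz: tuple[float, float] = (6.0, 42.0)
    emergence_duration_s: float = 600.0
    post_ror_s: float = 60.0
    induction_duration_s: float = 300.0
    beta_onset_mean_s: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_BETA_ONSET_MEAN_S)
    )
    beta_onset_shape: float = 4.0
    alpha_power_uv2: float = 150.0
    beta_power_uv2: float = 60.0
    background_power_uv2: float = 100.0
    background_exponent: float = 1.5
    alpha_center_hz: float = 10.0
    alpha_bw_hz: float = 2.0
    beta_band_hz: tuple[float, float] = (13.0, 42.0)
    alpha_fade: float = 0.6
    awake_alpha_frac: float = 0.2
    deep_beta_frac: float = 0.05
    beta_ramp_s: float = 60.0
    subject_sd: float = 0.1
    bsr_prob: float = 0.2
    seed: int = 0

    def onset_mean(self, group: str) -> float:
        if isinstance(self.beta_onset_mean_s, Mapping):
            try:
                return float(self.beta_onset_mean_s[group])
            except KeyError:
                raise ValueError(f"no beta_onset_mean_s entry for group {group!r}")
        return float(self.beta_onset_mean_s)

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        low, high = self.band_limit_hz
        if not 0 < low < high:
            raise ValueError("band_limit_hz must satisfy 0 < low < high")
        if self.sample_rate_hz < 2 * high + 2:
            raise ValueError(
                "sample_rate_hz must be at least 2 * band upper edge + 2 Hz"
            )
        for name in ("alpha_power_uv2", "beta_power_uv2", "background_power_uv2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for g in self.group_labels:
            if self.onset_mean(g) >= self.emergence_duration_s:
                raise ValueError(
                    f"beta_onset_mean_s for {g!r} must be < emergence_duration_s"
                )
        if self.emergence_duration_s <= 0 or self.induction_duration_s <= 0:
            raise ValueError("durations must be positive")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["beta_onset_mean_s"], Mapping):
            d["beta_onset_mean_s"] = dict(d["beta_onset_mean_s"])
        for key in ("group_labels", "band_limit_hz", "beta_band_hz"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        for key in ("group_labels", "band_limit_hz", "beta_band_hz"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class EEGRecording:
    """A uniformly sampled single-channel EEG with event markers.

    ``events`` maps marker names (``LOR``, ``ROR``, ``emergence_start``) to
    seconds from record start.  ``truth`` optionally records the generating
    parameters of a synthetic subject for recovery experiments.
    """

    samples: np.ndarray
    sample_rate_hz: float
    events: dict[str, float]
    group: str | None = None
    subject_id: str | None = None
    truth: dict | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def validate(self) -> None:
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        dur = self.duration_s
        for name, t in self.events.items():
            if not 0 <= t <= dur:
                raise ValueError(f"event {name!r} at {t} s outside [0, {dur}] s")
        if "ROR" in self.events and "emergence_start" in self.events:
            if self.events["ROR"] <= self.events["emergence_start"]:
                raise ValueError("ROR must come after emergence_start")


# ---------------------------------------------------------------------------
# spectral building blocks


def _band_mask(freqs: np.ndarray, band: tuple[float, float], taper_hz: float = 1.0):
    """Unit pass-band with raised-cosine edges of width ``taper_hz``."""
    low, high = band
    m = np.zeros_like(freqs)
    inside = (freqs >= low) & (freqs <= high)
    m[inside] = 1.0
    rise = (freqs >= low - taper_hz) & (freqs < low)
    m[rise] = 0.5 * (1 + np.cos(np.pi * (low - freqs[rise]) / taper_hz))
    fall = (freqs > high) & (freqs <= high + taper_hz)
    m[fall] = 0.5 * (1 + np.cos(np.pi * (freqs[fall] - high) / taper_hz))
    return m


def _shaped_noise(
    n: int, fs: float, shape: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with amplitude spectrum ``shape`` and unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white) * shape
    x = np.fft.irfft(spec, n)
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _background(n, fs, config: CohortConfig, rng) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = freqs[nz] ** (-config.background_exponent / 2.0)
    amp *= _band_mask(freqs, config.band_limit_hz)
    return _shaped_noise(n, fs, amp, rng)


def _alpha(n, fs, config: CohortConfig, rng) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1 / fs)
    sigma = config.alpha_bw_hz / 2.355  # bandwidth read as FWHM
    amp = np.exp(-0.5 * ((freqs - config.alpha_center_hz) / sigma) ** 2)
    amp *= _band_mask(freqs, config.band_limit_hz)
    return _shaped_noise(n, fs, amp, rng)


def _fastband(n, fs, config: CohortConfig, rng) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1 / fs)
    low = max(config.beta_band_hz[0], config.band_limit_hz[0])
    high = min(config.beta_band_hz[1], config.band_limit_hz[1])
    amp = _band_mask(freqs, (low, high))
    return _shaped_noise(n, fs, amp, rng)


def _logistic(t: np.ndarray, center: float, rise_s: float) -> np.ndarray:
    # ~2% -> ~98% over rise_s
    return 1.0 / (1.0 + np.exp(-(t - center) / (rise_s / 8.0)))


def _suppression_envelope(
    t: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Near-isoelectric epochs early in emergence (amplitude x 0.05)."""
    env = np.ones_like(t)
    epochs: list[tuple[float, float]] = []
    if rng.random() >= config.bsr_prob:
        return env, epochs
    n_ep = int(rng.integers(3, 7))
    window_end = 0.3 * config.emergence_duration_s
    for _ in range(n_ep):
        dur = rng.uniform(2.0, 10.0)
        start = rng.uniform(0.0, max(window_end - dur, 1.0))
        edge = 0.5
        ramp_dn = 0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * np.clip((t - start) / edge, 0, 1)))
        ramp_up = 0.05 + 0.95 * 0.5 * (1 - np.cos(np.pi * np.clip((t - start - dur) / edge, 0, 1)))
        env = np.minimum(env, np.maximum(ramp_dn, ramp_up))
        epochs.append((start, dur))
    return env, epochs


def _subject_scales(config: CohortConfig, rng) -> dict[str, float]:
    # independent log-normal amplitude variability per component
    s = config.subject_sd
    return {
        name: float(np.exp(rng.normal(0.0, s)))
        for name in ("background", "alpha", "beta")
    }


# ---------------------------------------------------------------------------
# public simulators


def simulate_subject(
    config: CohortConfig,
    group: str,
    subject_id: str,
    rng: np.random.Generator,
) -> EEGRecording:
    """Simulate one emergence recording ending ``post_ror_s`` after ROR.

    The fast-band amplitude follows a logistic ramp that starts at
    ``ROR - lead`` with ``lead ~ Gamma(shape, mean/shape)`` for the subject's
    group; the alpha amplitude wanes linearly toward ROR and decays to its
    awake fraction afterwards.  Deterministic given ``rng``'s state.
    """
    config.validate()
    if group not in config.group_labels:
        raise ValueError(f"unknown group label {group!r}")
    fs = config.sample_rate_hz
    ror = config.emergence_duration_s
    dur = ror + config.post_ror_s
    n = int(round(dur * fs))
    t = np.arange(n) / fs

    mean = config.onset_mean(group)
    shape = config.beta_onset_shape
    lead = float(rng.gamma(shape, mean / shape))
    lead = float(np.clip(lead, 5.0, ror - 10.0))
    onset = ror - lead

    scales = _subject_scales(config, rng)

    env_alpha = np.interp(t, [0.0, ror], [1.0, config.alpha_fade])
    post = t > ror
    env_alpha[post] = np.interp(
        t[post], [ror, ror + 30.0], [config.alpha_fade, config.awake_alpha_frac]
    )
    eps = config.deep_beta_frac
    env_beta = eps + (1 - eps) * _logistic(t, onset + config.beta_ramp_s / 2, config.beta_ramp_s)

    x = np.sqrt(config.background_power_uv2 * scales["background"]) * _background(n, fs, config, rng)
    x += np.sqrt(config.alpha_power_uv2 * scales["alpha"]) * env_alpha * _alpha(n, fs, config, rng)
    x += np.sqrt(config.beta_power_uv2 * scales["beta"]) * env_beta * _fastband(n, fs, config, rng)

    sup, epochs = _suppression_envelope(t, config, rng)
    x *= sup

    truth = {
        "beta_onset_lead_s": lead,
        "beta_onset_time_s": onset,
        "scales": scales,
        "suppression_epochs": epochs,
    }
    rec = EEGRecording(
        samples=x,
        sample_rate_hz=fs,
        events={"emergence_start": 0.0, "ROR": ror},
        group=group,
        subject_id=subject_id,
        truth=truth,
    )
    rec.validate()
    return rec


def simulate_induction(
    config: CohortConfig,
    subject_id: str,
    rng: np.random.Generator,
    group: str | None = None,
) -> EEGRecording:
    """Simulate an induction recording with LOR at the record midpoint.

    The awake segment is broadband (full fast-band amplitude, weak alpha);
    over ~60 s around LOR the fast band fades to its deep fraction while the
    alpha oscillation rises to full amplitude.
    """
    config.validate()
    if config.induction_duration_s <= 60:
        raise ValueError("induction_duration_s must exceed 60 s")
    fs = config.sample_rate_hz
    dur = config.induction_duration_s
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    lor = dur / 2.0

    scales = _subject_scales(config, rng)
    ramp = _logistic(t, lor, 60.0)
    env_alpha = config.awake_alpha_frac + (1 - config.awake_alpha_frac) * ramp
    env_beta = 1.0 - (1.0 - config.deep_beta_frac) * ramp

    x = np.sqrt(config.background_power_uv2 * scales["background"]) * _background(n, fs, config, rng)
    x += np.sqrt(config.alpha_power_uv2 * scales["alpha"]) * env_alpha * _alpha(n, fs, config, rng)
    x += np.sqrt(config.beta_power_uv2 * scales["beta"]) * env_beta * _fastband(n, fs, config, rng)

    rec = EEGRecording(
        samples=x,
        sample_rate_hz=fs,
        events={"LOR": lor},
        group=group,
        subject_id=subject_id,
        truth={"scales": scales, "lor_s": lor},
    )
    rec.validate()
    return rec


def _subject_rng(config: CohortConfig, phase: str, group_idx: int, idx: int):
    phase_key = 0 if phase == "emergence" else 1
    ss = np.random.SeedSequence([int(config.seed), phase_key, group_idx, idx])
    return np.random.default_rng(ss)


def simulate_cohort(config: CohortConfig, phase: str = "emergence") -> list[EEGRecording]:
    """Simulate ``n_per_group`` recordings per group, reproducible from seed.

    ``phase`` selects emergence (default) or induction recordings.  Subject
    substreams are derived from ``(seed, phase, group index, subject index)``
    so each subject is independent of cohort size.
    """
    config.validate()
    if phase not in ("emergence", "induction"):
        raise ValueError(f"unknown phase {phase!r}")
    recs = []
    for gi, group in enumerate(config.group_labels):
        for i in range(config.n_per_group):
            rng = _subject_rng(config, phase, gi, i)
            sid = f"{group[:4]}-{i:02d}"
            if phase == "emergence":
                recs.append(simulate_subject(config, group, sid, rng))
            else:
                recs.append(simulate_induction(config, sid, rng, group=group))
    return recs


def simulate_stationary(
    config: CohortConfig,
    duration_s: float,
    rng: np.random.Generator,
    alpha_level: float = 1.0,
    beta_level: float = 1.0,
    background_level: float = 1.0,
) -> np.ndarray:
    """A stationary mixture segment at fixed component amplitudes.

    ``*_level`` are amplitude factors on the configured full-power components
    (e.g. ``alpha_level=1, beta_level=config.deep_beta_frac`` is
    deep-anesthesia-like; ``alpha_level=config.awake_alpha_frac,
    beta_level=1`` is awake-like).  Used for spectral-fidelity oracles and for
    the one-off calibration of the depth-index mapping.
    """
    config.validate()
    fs = config.sample_rate_hz
    n = int(round(duration_s * fs))
    x = background_level * np.sqrt(config.background_power_uv2) * _background(n, fs, config, rng)
    x += alpha_level * np.sqrt(config.alpha_power_uv2) * _alpha(n, fs, config, rng)
    x += beta_level * np.sqrt(config.beta_power_uv2) * _fastband(n, fs, config, rng)
    return x


def analytic_psd(
    config: CohortConfig,
    freqs: np.ndarray,
    alpha_level: float = 1.0,
    beta_level: float = 1.0,
    background_level: float = 1.0,
) -> np.ndarray:
    """Closed-form one-sided PSD (uV^2/Hz) of the stationary mixture.

    Each component's spectral shape is normalized to unit total power and
    scaled by its configured variance, mirroring the time-domain construction.
    """
    freqs = np.asarray(freqs, float)
    lowb = max(config.beta_band_hz[0], config.band_limit_hz[0])
    highb = min(config.beta_band_hz[1], config.band_limit_hz[1])
    sigma = config.alpha_bw_hz / 2.355

    def _bg(f):
        out = np.zeros_like(f)
        nz = f > 0
        out[nz] = f[nz] ** (-config.background_exponent)
        return out * _band_mask(f, config.band_limit_hz) ** 2

    def _al(f):
        shape = np.exp(-(((f - config.alpha_center_hz) / sigma) ** 2))
        return shape * _band_mask(f, config.band_limit_hz) ** 2

    def _be(f):
        return _band_mask(f, (lowb, highb)) ** 2

    dense = np.linspace(0.0, config.sample_rate_hz / 2, 8193)
    psd = np.zeros_like(freqs)
    for shape_fn, level, power in (
        (_bg, background_level, config.background_power_uv2),
        (_al, alpha_level, config.alpha_power_uv2),
        (_be, beta_level, config.beta_power_uv2),
    ):
        total = np.trapezoid(shape_fn(dense), dense)
        if total > 0:
            psd = psd + level**2 * power * shape_fn(freqs) / total
    return psd
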