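"""Paired pre/post statistics at anesthesia state transitions.

Parameter values are extracted 15 s before and 30 s after a transition marker
(LOR or ROR); the post offset accommodates the calculation delay of monitor
indices.  The layer provides the Wilcoxon signed-rank test (exact null
enumeration for small n, tie/continuity-corrected normal approximation
above), Hedges' g for dependent data with a bias-corrected bootstrap CI, the
Mann-Whitney AUC (equivalent to the prediction probability used to grade
anesthesia monitors), and seeded bootstrap confidence intervals whose
resampling unit is the subject.

Sign convention: g is computed on d = pre - post, so a parameter *decrease*
across the transition yields positive g.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import extract_window_at

__all__ = [
    "PairedTransitionSet",
    "PairedTestResult",
    "build_paired_set",
    "wilcoxon_signed_rank",
    "hedges_g_dependent",
    "auc_two_sample",
    "bootstrap_ci",
    "significant_by_ci",
    "paired_test",
    "results_table",
]

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 15


@dataclass
class PairedTransitionSet:
    """Per-subject (pre, post) parameter values around one event."""

    subject_ids: list[str]
    pre_values: np.ndarray
    post_values: np.ndarray
    parameter_name: str
    event_name: str
    group: str | None = None
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.pre_values = np.asarray(self.pre_values, float)
        self.post_values = np.asarray(self.post_values, float)
        if not (
            len(self.subject_ids) == len(self.pre_values) == len(self.post_values)
        ):
            raise ValueError("pre and post values must align by subject")
        if np.any(~np.isfinite(self.pre_values)) or np.any(
            ~np.isfinite(self.post_values)
        ):
            raise ValueError("NaN pairs must be excluded before constructing the set")

    @property
    def n(self) -> int:
        return len(self.subject_ids)


@dataclass
class PairedTestResult:
    parameter_name: str
    event_name: str
    group: str | None
    n_effective: int
    p_value: float
    hedges_g: float
    g_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    pre_median: float
    pre_iqr: tuple[float, float]
    post_median: float
    post_iqr: tuple[float, float]

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")
        for lo, hi in (self.g_ci, self.auc_ci):
            if lo > hi:
                raise ValueError("CI bounds must be ordered")


def build_paired_set(
    trends: Mapping[str, object],
    event_times: Mapping[str, float],
    event_name: str,
    parameter_name: str,
    pre_offset_s: float = -15.0,
    post_offset_s: float = 30.0,
    group: str | None = None,
) -> PairedTransitionSet:
    """One (pre, post) pair per subject whose trend covers both offsets.

    Subjects lacking coverage (or with non-finite extracted values) are
    dropped with a logged reason; an empty retained set raises.
    """
    ids, pre, post, dropped = [], [], [], {}
    for sid, trend in trends.items():
        if sid not in event_times:
            dropped[sid] = "no event time"
            continue
        t0 = event_times[sid]
        try:
            a = extract_window_at(trend, t0, pre_offset_s)
            b = extract_window_at(trend, t0, post_offset_s)
        except ValueError as exc:
            dropped[sid] = str(exc)
            continue
        if not (np.isfinite(a) and np.isfinite(b)):
            dropped[sid] = "non-finite parameter value"
            continue
        ids.append(sid)
        pre.append(float(a))
        post.append(float(b))
    for sid, why in dropped.items():
        logger.info("dropped subject %s from %s/%s pairs: %s",
                    sid, event_name, parameter_name, why)
    if not ids:
        raise ValueError(
            f"no subjects retained for {parameter_name} at {event_name}"
        )
    return PairedTransitionSet(
        ids, np.array(pre), np.array(post), parameter_name, event_name, group, dropped
    )


def _wilcoxon_exact(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumerating all sign assignments (midranks kept)."""
    n = len(ranks)
    signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    w_all = signs @ ranks
    n_tot = len(w_all)
    p_le = np.count_nonzero(w_all <= w_plus + 1e-9) / n_tot
    p_ge = np.count_nonzero(w_all >= w_plus - 1e-9) / n_tot
    return min(1.0, 2.0 * min(p_le, p_ge))


def _wilcoxon_approx(ranks: np.ndarray, w_plus: float) -> float:
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        return 1.0
    d = w_plus - mean
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var)  # continuity correction
    return float(2.0 * stats.norm.sf(abs(z)))


def wilcoxon_signed_rank(pre, post=None) -> float:
    """Two-sided Wilcoxon signed-rank p for paired values (or differences).

    Zero differences are dropped (classic Wilcoxon convention, logged); with
    at most 15 nonzero differences the null is enumerated exactly (midranks
    for tied magnitudes), above that a tie- and continuity-corrected normal
    approximation is used.  All-zero differences give p = 1 with a warning.
    """
    d = np.asarray(pre, float) if post is None else np.asarray(pre, float) - np.asarray(post, float)
    if not np.all(np.isfinite(d)):
        raise ValueError("differences contain non-finite values")
    nonzero = d[d != 0]
    n_zero = len(d) - len(nonzero)
    if n_zero:
        logger.info("wilcoxon: dropped %d zero difference(s)", n_zero)
    if len(nonzero) == 0:
        warnings.warn("all differences are zero; Wilcoxon p defined as 1")
        return 1.0
    ranks = stats.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    if len(nonzero) <= EXACT_WILCOXON_MAX_N:
        return _wilcoxon_exact(ranks, w_plus)
    return _wilcoxon_approx(ranks, w_plus)


def hedges_correction(n: int) -> float:
    return 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)


def hedges_g_dependent(
    pre,
    post,
    n_boot: int = 10000,
    seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Hedges' g for dependent data with a bias-corrected bootstrap CI.

    g = J * mean(d) / sd(d) with d = pre - post, sd using the n-1 denominator
    and small-sample correction J = 1 - 3/(4(n-1) - 1).  The CI resamples
    subjects with replacement (seeded) and applies the bias-corrected (BC)
    percentile adjustment.
    """
    d = np.asarray(pre, float) - np.asarray(post, float)
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences; Hedges' g undefined")
    j = hedges_correction(n)
    g = j * d.mean() / sd
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = d[idx]
    sds = samples.std(ddof=1, axis=1)
    ok = sds > 0
    boots = j * samples.mean(axis=1)[ok] / sds[ok]
    if len(boots) == 0:
        warnings.warn("all bootstrap resamples degenerate; collapsed CI")
        return float(g), (float(g), float(g))
    alpha = 1 - ci_level
    z0 = stats.norm.ppf(
        np.clip((boots < g).mean() + 0.5 * (boots == g).mean(), 1e-6, 1 - 1e-6)
    )
    zlo, zhi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
    plo = stats.norm.cdf(2 * z0 + zlo)
    phi = stats.norm.cdf(2 * z0 + zhi)
    lo, hi = np.quantile(boots, [plo, phi])
    return float(g), (float(lo), float(hi))


def auc_two_sample(x, y) -> float:
    """Mann-Whitney AUC: P(Y > X) + 0.5 P(Y = X), via the rank formula."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    r_y = ranks[len(x):].sum()
    u_y = r_y - len(y) * (len(y) + 1) / 2.0
    return float(u_y / (len(x) * len(y)))


def bootstrap_ci(
    statistic: Callable,
    data,
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI.

    ``data`` is one array (resampled as a whole -- the paired-subject case) or
    a tuple of arrays resampled independently (the two-group case, subjects
    resampled within group).  ``statistic`` receives the resampled array(s).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    single = not isinstance(data, (tuple, list))
    arrays = (np.asarray(data),) if single else tuple(np.asarray(a) for a in data)
    if min(len(a) for a in arrays) < 3:
        raise ValueError("need at least 3 resampling units")
    vals = np.empty(n_boot)
    for b in range(n_boot):
        res = tuple(a[rng.integers(0, len(a), len(a))] for a in arrays)
        vals[b] = statistic(res[0]) if single else statistic(*res)
    if np.allclose(vals, vals[0]):
        warnings.warn("degenerate statistic on all resamples; collapsed CI")
        return float(vals[0]), float(vals[0])
    alpha = 1 - level
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def significant_by_ci(ci: tuple[float, float], null_value: float = 0.5) -> bool:
    """True iff the CI excludes the no-effect value (closed-interval rule)."""
    lo, hi = ci
    if lo > hi:
        raise ValueError("CI bounds must be ordered")
    return bool(null_value < lo or null_value > hi)


def paired_test(
    pairs: PairedTransitionSet,
    n_boot: int = 10000,
    seed: int | np.random.Generator = 0,
) -> PairedTestResult:
    """Full paired analysis of one transition set (p, g with CI, AUC with CI).

    The AUC grades how well the parameter separates the responsive from the
    unresponsive state: it is P(responsive-state value > unresponsive-state
    value), where the responsive side is pre at LOR and post at ROR.  Its
    bootstrap resamples subjects, carrying each subject's (pre, post) pair
    together.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pre, post = pairs.pre_values, pairs.post_values
    p = wilcoxon_signed_rank(pre, post)
    g, g_ci = hedges_g_dependent(pre, post, n_boot=n_boot, seed=rng)
    responsive, unresponsive = (
        (pre, post) if pairs.event_name.upper() == "LOR" else (post, pre)
    )
    auc = auc_two_sample(unresponsive, responsive)
    n = pairs.n
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.array(
        [auc_two_sample(unresponsive[i], responsive[i]) for i in idx]
    )
    if np.allclose(boots, boots[0]):
        auc_ci = (float(boots[0]), float(boots[0]))
    else:
        auc_ci = tuple(np.quantile(boots, [0.025, 0.975]))
    q_pre = np.quantile(pre, [0.25, 0.5, 0.75])
    q_post = np.quantile(post, [0.25, 0.5, 0.75])
    return PairedTestResult(
        parameter_name=pairs.parameter_name,
        event_name=pairs.event_name,
        group=pairs.group,
        n_effective=n,
        p_value=p,
        hedges_g=g,
        g_ci=(float(g_ci[0]), float(g_ci[1])),
        auc=auc,
        auc_ci=(float(auc_ci[0]), float(auc_ci[1])),
        pre_median=float(q_pre[1]),
        pre_iqr=(float(q_pre[0]), float(q_pre[2])),
        post_median=float(q_post[1]),
        post_iqr=(float(q_post[0]), float(q_post[2])),
    )


def results_table(results: Sequence[PairedTestResult]) -> pd.DataFrame:
    """Tabulate paired-test results, one row per event/parameter/group."""
    rows = []
    for r in results:
        rows.append(
            {
                "event": r.event_name,
                "parameter": r.parameter_name,
                "group": r.group or "all",
                "n": r.n_effective,
                "pre_median": r.pre_median,
                "pre_q1": r.pre_iqr[0],
                "pre_q3": r.pre_iqr[1],
                "post_median": r.post_median,
                "post_q1": r.post_iqr[0],
                "post_q3": r.post_iqr[1],
                "p_value": r.p_value,
                "hedges_g": r.hedges_g,
                "g_ci_lo": r.g_ci[0],
                "g_ci_hi": r.g_ci[1],
                "auc": r.auc,
                "auc_ci_lo": r.auc_ci[0],
                "auc_ci_hi": r.auc_ci[1],
            }
        )
    return pd.DataFrame(rows)
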