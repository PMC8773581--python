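"""Between-group emergence comparisons.

Group differences in spectra are assessed with the Mann-Whitney AUC per
frequency bin (or per time-frequency pixel of ROR-aligned spectrograms),
with seeded subject-level bootstrap confidence intervals; a comparison is
significant where the 95% CI excludes 0.5.  To suppress isolated false
positives, per-bin PSD findings are retained only where at least two
neighboring bins are jointly significant, and 2-D map findings only inside
4-connected significant clusters of a minimum pixel count (default 200,
calibrated on the null generator for a <=10% family-wise false-cluster
rate: overlapping 10 s windows at 1 s hops and between-subject amplitude
variability correlate neighboring pixels strongly, so chance significant
patches of tens of pixels are routine under the null).

Also provided: the duration a depth index stayed at or above a wakefulness
threshold contiguously up to ROR (subjects below threshold at ROR enter as
0 s), Kruskal-Wallis with Dunn's post-hoc z tests (Holm-adjusted), and the
exact Freeman-Halton test for r x c contingency tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .spectral import ParamTrend, Spectrogram

__all__ = [
    "AUCMap",
    "BinComparison",
    "DurationRecord",
    "KruskalDunnResult",
    "psd_compare",
    "auc_map",
    "align_to_event",
    "duration_above",
    "kruskal_dunn",
    "freeman_halton",
    "auc_grid_bootstrap",
]

# Calibrated once on 24 null cohorts (identical group parameters, n=15/group,
# full 591 x 49 ROR-aligned grid): largest null 4-connected significant
# component had median 36 px, 90th percentile ~58 px, maximum 174 px.
DEFAULT_CLUSTER_MIN = 200
DEFAULT_NEIGHBOR_MIN = 2


# ---------------------------------------------------------------------------
# vectorized AUC with subject-level bootstrap


def _auc_grid(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """AUC = P(b > a) + 0.5 P(b = a) per column; a, b are (subjects, cells)."""
    gt = (b[:, None, :] > a[None, :, :]).sum(axis=(0, 1))
    eq = (b[:, None, :] == a[None, :, :]).sum(axis=(0, 1))
    return (gt + 0.5 * eq) / (a.shape[0] * b.shape[0])


def auc_grid_bootstrap(
    a: np.ndarray,
    b: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
    chunk_cells: int = 40000,
):
    """Per-cell AUC with bootstrap CI, resampling subjects within each group.

    ``a`` and ``b`` have shape (n_subjects, n_cells); returns (auc, lo, hi).
    The same subject resamples are used across cells within one replicate,
    which is the correct subject-level resampling scheme and keeps the
    computation vectorized.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the same cell grid")
    na, nb = a.shape[0], b.shape[0]
    if min(na, nb) < 3:
        raise ValueError("need at least 3 subjects per group")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    point = _auc_grid(a, b)
    n_cells = a.shape[1]
    alpha = 1 - level
    ia = rng.integers(0, na, size=(n_boot, na))
    ib = rng.integers(0, nb, size=(n_boot, nb))
    lo = np.empty(n_cells)
    hi = np.empty(n_cells)
    for start in range(0, n_cells, chunk_cells):
        sl = slice(start, min(start + chunk_cells, n_cells))
        ac, bc = a[:, sl], b[:, sl]
        boots = np.empty((n_boot, ac.shape[1]), dtype=np.float32)
        for r in range(n_boot):
            boots[r] = _auc_grid(ac[ia[r]], bc[ib[r]])
        lo[sl], hi[sl] = np.quantile(boots, [alpha / 2, 1 - alpha / 2], axis=0)
    return point, lo, hi


# ---------------------------------------------------------------------------
# per-bin PSD comparison with the neighboring-bin rule


@dataclass
class BinComparison:
    freqs: np.ndarray
    auc: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    sig: np.ndarray        # CI excludes 0.5
    retained: np.ndarray   # sig AND in a run of >= neighbor_min adjacent bins

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq_hz": self.freqs,
                "auc": self.auc,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "sig": self.sig.astype(int),
                "retained": self.retained.astype(int),
            }
        )


def _runs_of_true(mask: np.ndarray, min_len: int) -> np.ndarray:
    out = np.zeros_like(mask)
    edges = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            out[s:e] = True
    return out


def psd_compare(
    freqs: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    neighbor_min: int = DEFAULT_NEIGHBOR_MIN,
) -> BinComparison:
    """Per-frequency-bin subject-level AUC between two groups of PSDs.

    ``group_a``/``group_b`` are (n_subjects, n_bins) PSD value arrays on the
    same frequency grid.  Findings are retained only where at least
    ``neighbor_min`` adjacent bins are jointly significant.
    """
    group_a = np.asarray(group_a, float)
    group_b = np.asarray(group_b, float)
    freqs = np.asarray(freqs, float)
    if group_a.shape[1] != len(freqs) or group_b.shape[1] != len(freqs):
        raise ValueError("frequency grids of the two groups do not match")
    auc, lo, hi = auc_grid_bootstrap(group_a, group_b, n_boot=n_boot, seed=seed)
    sig = (lo > 0.5) | (hi < 0.5)
    retained = _runs_of_true(sig, neighbor_min)
    return BinComparison(freqs, auc, lo, hi, sig, retained)


# ---------------------------------------------------------------------------
# 2-D AUC maps on ROR-aligned spectrograms


@dataclass
class AUCMap:
    times: np.ndarray   # seconds relative to the event (negative before)
    freqs: np.ndarray
    auc: np.ndarray     # (time, freq)
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    sig_mask: np.ndarray
    cluster_mask: np.ndarray
    cluster_min: int
    labels: tuple[str, str] = ("A", "B")

    def __post_init__(self):
        if np.any((self.auc < 0) | (self.auc > 1)):
            raise ValueError("AUC values must lie in [0, 1]")
        if np.any(self.cluster_mask & ~self.sig_mask):
            raise ValueError("cluster_mask must be a subset of sig_mask")

    def to_frame(self) -> pd.DataFrame:
        t, f = np.meshgrid(self.times, self.freqs, indexing="ij")
        return pd.DataFrame(
            {
                "rel_time_s": t.ravel(),
                "freq_hz": f.ravel(),
                "auc": self.auc.ravel(),
                "ci_lo": self.ci_lo.ravel(),
                "ci_hi": self.ci_hi.ravel(),
                "sig": self.sig_mask.ravel().astype(int),
                "cluster": self.cluster_mask.ravel().astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def n_clusters(self) -> int:
        _, n = ndimage.label(self.cluster_mask, structure=_FOUR_CONNECTED)
        return int(n)


_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def align_to_event(spec: Spectrogram, event_time_s: float, span_s: float = 600.0) -> Spectrogram:
    """Re-timestamp spectrogram rows relative to an event, keeping the rows
    whose windows lie fully inside the ``span_s`` seconds before the event.

    Retained window starts run from event-span to event-window (the last
    window ending by the event); with a 600 s span and 10 s / 1 s windows
    that is 591 rows.  Insufficient coverage raises (subject to be dropped
    with a log by the caller).
    """
    t0 = event_time_s - span_s
    t1 = event_time_s - spec.window_s
    eps = 1e-9
    if spec.times[0] > t0 + eps or spec.times[-1] < t1 - eps:
        raise ValueError(
            f"record does not cover [{t0:g}, {event_time_s:g}] s for alignment"
        )
    sel = (spec.times >= t0 - eps) & (spec.times <= t1 + eps)
    return Spectrogram(
        spec.times[sel] - event_time_s,
        spec.freqs,
        spec.power[sel],
        spec.window_s,
        spec.hop_s,
        spec.normalized,
        spec.norm_band,
    )


def auc_map(
    specs_a: Sequence[Spectrogram],
    specs_b: Sequence[Spectrogram],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    cluster_min: int = DEFAULT_CLUSTER_MIN,
    labels: tuple[str, str] = ("A", "B"),
) -> AUCMap:
    """Pixel-wise AUC map between two groups of event-aligned spectrograms.

    All spectrograms must share the same time-frequency grid.  Pixels whose
    bootstrap CI excludes 0.5 are significant; the cluster mask keeps only
    pixels inside 4-connected significant components of >= cluster_min
    pixels.
    """
    ref = specs_a[0]
    for s in list(specs_a) + list(specs_b):
        if not (
            np.allclose(s.times, ref.times) and np.allclose(s.freqs, ref.freqs)
        ):
            raise ValueError("spectrograms are not on a common aligned grid")
    shape = ref.power.shape
    a = np.stack([s.power.ravel() for s in specs_a])
    b = np.stack([s.power.ravel() for s in specs_b])
    auc, lo, hi = auc_grid_bootstrap(a, b, n_boot=n_boot, seed=seed)
    auc, lo, hi = (x.reshape(shape) for x in (auc, lo, hi))
    sig = (lo > 0.5) | (hi < 0.5)
    labeled, n_comp = ndimage.label(sig, structure=_FOUR_CONNECTED)
    cluster = np.zeros_like(sig)
    if n_comp:
        sizes = ndimage.sum_labels(sig, labeled, index=np.arange(1, n_comp + 1))
        for lab, size in enumerate(sizes, start=1):
            if size >= cluster_min:
                cluster |= labeled == lab
    return AUCMap(ref.times, ref.freqs, auc, lo, hi, sig, cluster, cluster_min, labels)


# ---------------------------------------------------------------------------
# index-above-threshold duration before ROR


@dataclass(frozen=True)
class DurationRecord:
    subject_id: str
    group: str | None
    duration_s: float
    at_ror_below: bool

    def __post_init__(self):
        if self.duration_s < 0:
            raise ValueError("duration_s must be >= 0")
        if self.at_ror_below and self.duration_s != 0:
            raise ValueError("below-threshold-at-ROR implies duration 0")


def duration_above(
    trend,
    ror_time_s: float,
    threshold: float = 80.0,
    mode: str = "contiguous",
    subject_id: str = "",
    group: str | None = None,
) -> DurationRecord:
    """Time the index stayed >= threshold up to ROR.

    ``contiguous`` (default): length of the maximal run of >= threshold
    windows ending at the last window before ROR, measured from the run's
    first window start to ROR; 0 s (with ``at_ror_below``) if that last
    window is below threshold.  ``total``: summed window hops >= threshold
    before ROR, regardless of contiguity (the alternative reading, behind
    this flag).
    """
    times = np.asarray(trend.times, float)
    values = np.asarray(trend.values, float)
    window_s = getattr(trend, "window_s", 10.0)
    hop_s = getattr(trend, "hop_s", 1.0)
    pre = times <= ror_time_s - window_s + 1e-9
    if not pre.any() or times[pre][-1] < ror_time_s - window_s - hop_s:
        raise ValueError("trend does not reach ROR")
    t_pre = times[pre]
    v_pre = values[pre]
    above = v_pre >= threshold
    if mode == "total":
        return DurationRecord(subject_id, group, float(above.sum() * hop_s), False)
    if mode != "contiguous":
        raise ValueError(f"unknown mode {mode!r}")
    if not above[-1]:
        return DurationRecord(subject_id, group, 0.0, True)
    i = len(above) - 1
    while i > 0 and above[i - 1]:
        i -= 1
    return DurationRecord(subject_id, group, float(ror_time_s - t_pre[i]), False)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn


@dataclass
class KruskalDunnResult:
    kw_chi2: float
    kw_p: float
    dunn: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_adj

    def to_frame(self) -> pd.DataFrame:
        df = self.dunn.copy()
        df["kw_chi2"] = self.kw_chi2
        df["kw_p"] = self.kw_p
        return df


def kruskal_dunn(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
) -> KruskalDunnResult:
    """Tie-corrected Kruskal-Wallis plus Dunn's pairwise z tests.

    Dunn p-values are Holm-adjusted across the pairwise comparisons.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(groups))]
    kw_chi2, kw_p = stats.kruskal(*groups)
    pooled = np.concatenate(groups)
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for m in sizes:
        mean_ranks.append(ranks[start : start + m].mean())
        start += m
    rows = []
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term / (12.0 * (n_tot - 1))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p_raw = 2.0 * stats.norm.sf(abs(z))
            rows.append([labels[i], labels[j], z, p_raw])
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    # Holm step-down adjustment
    order = np.argsort(df["p_raw"].to_numpy())
    m = len(df)
    adj = np.empty(m)
    running = 0.0
    for rank, k in enumerate(order):
        running = max(running, (m - rank) * df["p_raw"].iloc[k])
        adj[k] = min(1.0, running)
    df["p_adj"] = adj
    return KruskalDunnResult(float(kw_chi2), float(kw_p), df)


# ---------------------------------------------------------------------------
# Freeman-Halton exact test


def _table_logprob(cells: np.ndarray, log_const: float) -> float:
    return log_const - sum(math.lgamma(c + 1) for c in cells)


def table_distribution(table, budget: int = 10_000_000) -> np.ndarray:
    """Log-probabilities of every r x c table sharing the observed margins.

    The multivariate hypergeometric probabilities over this lattice sum to 1;
    the Freeman-Halton tail is the sum of entries no larger than the observed
    table's.  Raises when the lattice exceeds ``budget`` tables.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2-D array of nonnegative counts")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        raise ValueError("all row and column margins must be positive")
    n_tot = int(obs.sum())
    log_const = (
        sum(math.lgamma(r + 1) for r in row_sums)
        + sum(math.lgamma(c + 1) for c in col_sums)
        - math.lgamma(n_tot + 1)
    )
    r, c = obs.shape
    out: list[float] = []

    def recurse(row: int, col: int, rem_row: int, rem_cols: np.ndarray, lp: float):
        if row == r - 1:
            lp_final = lp - sum(math.lgamma(x + 1) for x in rem_cols)
            if len(out) >= budget:
                raise ValueError(
                    f"enumeration budget of {budget} tables exceeded; "
                    "re-run with monte_carlo=True for a seeded estimate"
                )
            out.append(lp_final)
            return
        if col == c - 1:
            x = rem_row
            if x > rem_cols[col]:
                return
            nxt = rem_cols.copy()
            nxt[col] -= x
            recurse(row + 1, 0, int(row_sums[row + 1]), nxt, lp - math.lgamma(x + 1))
            return
        hi = min(rem_row, int(rem_cols[col]))
        for x in range(hi + 1):
            nxt = rem_cols.copy()
            nxt[col] -= x
            recurse(row, col + 1, rem_row - x, nxt, lp - math.lgamma(x + 1))

    recurse(0, 0, int(row_sums[0]), col_sums.astype(np.int64).copy(), log_const)
    return np.array(out)


def freeman_halton(
    table,
    budget: int = 10_000_000,
    monte_carlo: bool = False,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Exact Freeman-Halton p for an r x c table of nonnegative counts.

    Enumerates every table with the observed margins and sums the
    multivariate hypergeometric probabilities of all tables no more probable
    than the observed one (the probability-ordering two-sided convention; for
    2 x 2 tables this reduces to Fisher's two-sided exact test).  When the
    lattice exceeds ``budget`` tables, a seeded conditional Monte-Carlo
    fallback is available via ``monte_carlo=True``.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2-D array of nonnegative counts")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        raise ValueError("all row and column margins must be positive")
    n_tot = int(obs.sum())
    log_const = (
        sum(math.lgamma(r + 1) for r in row_sums)
        + sum(math.lgamma(c + 1) for c in col_sums)
        - math.lgamma(n_tot + 1)
    )
    lp_obs = _table_logprob(obs.ravel(), log_const)

    if monte_carlo:
        return _freeman_halton_mc(obs, lp_obs, log_const, n_mc, seed)

    lps = table_distribution(obs, budget=budget)
    tail = float(np.exp(lps[lps <= lp_obs + 1e-9]).sum())
    return float(min(tail, 1.0))


def _freeman_halton_mc(obs, lp_obs, log_const, n_mc, seed) -> float:
    """Conditional Monte Carlo: permute individual column labels against rows."""
    rng = np.random.default_rng(seed)
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    row_codes = np.repeat(np.arange(len(row_sums)), row_sums)
    col_codes = np.repeat(np.arange(len(col_sums)), col_sums)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_codes)
        t = np.zeros_like(obs)
        np.add.at(t, (row_codes, perm), 1)
        if _table_logprob(t.ravel(), log_const) <= lp_obs + 1e-9:
            hits += 1
    return (hits + 1) / (n_mc + 1)
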