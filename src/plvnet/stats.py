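"""Baseline-referenced nonparametric statistics and motor-score correlation.

Every subject's metric series is first expressed relative to their own
baseline window (-1..0 s by default; subtraction, so the baseline cell is 0
by construction).  Per (channel, window) cell a nonparametric test across
subjects compares the window against baseline:

* ``signed_rank`` (default): exact paired Wilcoxon signed-rank of the
  baseline-normalized values against zero, p by exhaustive enumeration of
  all 2^n sign assignments (midranks under ties) for n <= 12, normal
  approximation with tie correction beyond;
* ``rank_sum``: unpaired Wilcoxon rank-sum (Mann-Whitney) of raw window
  values against raw baseline values.

Sample normality is screened with a one-sample Kolmogorov-Smirnov test of
the standardized sample against N(0, 1).  Metric-motor-function association
is a rank (Spearman) correlation across subjects by default, Pearson
selectable.  No multiple-comparison correction is applied by default (cells
are reported at per-cell alpha = 0.05 / 0.01); Benjamini-Hochberg FDR is
available as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .connectivity import TimeWindow
from .netmetrics import GraphMetricSeries

ALPHAS = (0.05, 0.01)
EXACT_ENUMERATION_MAX_N = 12


# ---------------------------------------------------------------------------
# baseline normalization


@dataclass
class NormalizedSeries:
    """Metric series expressed relative to the subject's baseline window."""

    values: np.ndarray  # windows x channels
    window_starts: np.ndarray
    baseline_index: int
    mode: str
    metric: str = ""
    band: str = ""
    task: str = ""
    subject: str = ""


def baseline_normalize(series: GraphMetricSeries, baseline: TimeWindow,
                       mode: str = "difference") -> NormalizedSeries:
    """Reference each window to the baseline window, per channel.

    ``difference`` (default): value - baseline value; the quantities of
    interest are small signed changes, which a difference preserves on the
    metric's own scale.  ``ratio``: value / baseline value (zero baselines
    give NaN).
    """
    if mode not in ("difference", "ratio"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    match = np.isclose(series.window_starts, baseline.start, atol=1e-9)
    if not match.any():
        raise ValueError(
            f"baseline start {baseline.start} s is not on the window grid "
            f"{series.window_starts.tolist()}")
    b = int(np.flatnonzero(match)[0])
    base = series.values[b]
    if mode == "difference":
        vals = series.values - base
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(base != 0, series.values / base, np.nan)
    return NormalizedSeries(values=vals, window_starts=series.window_starts,
                           baseline_index=b, mode=mode, metric=series.metric,
                           band=series.band, task=series.task,
                           subject=series.subject)


# ---------------------------------------------------------------------------
# normality screen


def ks_normality(sample: np.ndarray, alpha: float = 0.05) -> tuple[float, str]:
    """One-sample KS test of the standardized sample against N(0, 1).

    Returns ``(p, verdict)`` with verdict in {"normal", "non_normal",
    "degenerate"}.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("KS normality screen needs at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        return 1.0, "degenerate"
    z = (x - x.mean()) / sd
    p = float(sps.kstest(z, "norm").pvalue)
    return p, ("non_normal" if p < alpha else "normal")


# ---------------------------------------------------------------------------
# exact signed-rank


_signed_rank_cache: dict[tuple, np.ndarray] = {}


def _sign_flip_distribution(ranks: tuple[float, ...]) -> np.ndarray:
    """All 2^n values of W+ over sign assignments of the given ranks."""
    dist = _signed_rank_cache.get(ranks)
    if dist is None:
        n = len(ranks)
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        dist = bits @ np.asarray(ranks)
        if len(_signed_rank_cache) < 4096:
            _signed_rank_cache[ranks] = dist
    return dist


def signed_rank_exact(diffs: np.ndarray) -> tuple[float, float, int]:
    """Two-sided one-sample Wilcoxon signed-rank test against zero.

    Zero differences are discarded (Wilcoxon's rule); ties get midranks.
    For n <= 12 non-zero differences the p-value is
    ``P(|W - mu| >= |w_obs - mu|)`` under uniform sign flips, computed by
    full enumeration; beyond that a normal approximation with tie
    correction and continuity correction is used.

    Returns ``(w_plus, p, n_nonzero)``; an all-zero sample gives p = 1.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    dev = abs(w_plus - mu)
    if n <= EXACT_ENUMERATION_MAX_N:
        dist = _sign_flip_distribution(tuple(np.sort(ranks)))
        p = float(np.mean(np.abs(dist - mu) >= dev - 1e-9))
    else:
        # sign-flip variance with midranks: Var(W+) = sum(r_i^2) / 4
        var = float(np.sum(ranks**2)) / 4.0
        if var == 0:
            return w_plus, 1.0, n
        z = (dev - 0.5) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(max(z, 0.0)))
    return w_plus, min(p, 1.0), n


# ---------------------------------------------------------------------------
# grid tests


@dataclass
class StatResult:
    """Per-(window, channel) test grid across subjects."""

    test: str
    statistic: np.ndarray  # windows x channels
    p: np.ndarray
    direction: np.ndarray  # +1 increase, -1 decrease, 0 flat
    window_starts: np.ndarray
    channel_names: tuple[str, ...]
    alphas: tuple[float, ...] = ALPHAS
    baseline_index: int = 0
    fdr: bool = False

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p < alpha


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((flat[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0).reshape(p.shape)


def window_vs_baseline_test(
    stack: np.ndarray,
    window_starts: np.ndarray,
    baseline_index: int,
    channel_names: tuple[str, ...],
    mode: str = "signed_rank",
    fdr: bool = False,
) -> StatResult:
    """Test every (window, channel) cell against the baseline window.

    ``stack`` is subjects x windows x channels of *raw* metric values; the
    paired mode subtracts each subject's baseline internally (equivalent to
    testing the baseline-normalized values against zero).
    """
    stack = np.asarray(stack, dtype=float)
    S, W, N = stack.shape
    if S < 5:
        raise ValueError("need at least 5 subjects for a meaningful exact test")
    statistic = np.zeros((W, N))
    p = np.ones((W, N))
    direction = np.zeros((W, N), dtype=np.int64)
    base = stack[:, baseline_index, :]  # subjects x channels
    for wdx in range(W):
        if wdx == baseline_index:
            continue
        for c in range(N):
            x = stack[:, wdx, c]
            d = x - base[:, c]
            if mode == "signed_rank":
                stat, pv, n_nz = signed_rank_exact(d)
            elif mode == "rank_sum":
                res = sps.mannwhitneyu(x, base[:, c], alternative="two-sided",
                                       method="auto")
                stat, pv = float(res.statistic), float(res.pvalue)
            else:
                raise ValueError(f"unknown test mode {mode!r}")
            statistic[wdx, c] = stat
            p[wdx, c] = pv
            mean_d = d.mean()
            direction[wdx, c] = 0 if mean_d == 0 else (1 if mean_d > 0 else -1)
    if fdr:
        mask = np.ones((W, N), bool)
        mask[baseline_index] = False
        p_adj = p.copy()
        p_adj[mask] = _bh_adjust(p[mask])
        p = p_adj
    return StatResult(test=mode, statistic=statistic, p=p, direction=direction,
                      window_starts=np.asarray(window_starts),
                      channel_names=tuple(channel_names),
                      baseline_index=baseline_index, fdr=fdr)


# ---------------------------------------------------------------------------
# correlation with motor function


@dataclass
class CorrelationResult:
    coefficient: np.ndarray  # windows x channels
    p: np.ndarray
    method: str
    window_starts: np.ndarray
    channel_names: tuple[str, ...]
    degenerate: bool = False


def correlate_with_motor(
    stack: np.ndarray,
    fma: np.ndarray,
    window_starts: np.ndarray,
    channel_names: tuple[str, ...],
    method: str = "spearman",
) -> CorrelationResult:
    """Correlate each (window, channel) cell with FMA-UL across subjects."""
    stack = np.asarray(stack, dtype=float)
    fma = np.asarray(fma, dtype=float)
    S, W, N = stack.shape
    if fma.shape != (S,):
        raise ValueError("one FMA score per subject required")
    if S < 4:
        raise ValueError("need at least 4 subjects for correlation")
    degenerate = bool(np.all(fma == fma[0]))
    coef = np.full((W, N), np.nan)
    p = np.full((W, N), np.nan)
    if degenerate:
        return CorrelationResult(coef, p, method, np.asarray(window_starts),
                                 tuple(channel_names), degenerate=True)
    # vectorized over the whole grid; Spearman = Pearson on midranks with the
    # usual t approximation for the p-value (matches scipy cell-by-cell)
    if method == "spearman":
        x = sps.rankdata(stack, axis=0)
        y = sps.rankdata(fma)
    elif method == "pearson":
        x, y = stack, fma
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    xc = x - x.mean(axis=0)
    yc = (y - y.mean())[:, None, None]
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = float(np.sqrt((yc**2).sum()))
    valid = sx > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc).sum(axis=0) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    dof = S - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / (1.0 - r**2))
    pv = 2.0 * sps.t.sf(np.abs(t), dof)
    pv[np.abs(r) == 1.0] = 0.0
    coef[valid] = r[valid]
    p[valid] = pv[valid]
    return CorrelationResult(coef, p, method, np.asarray(window_starts),
                             tuple(channel_names))
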