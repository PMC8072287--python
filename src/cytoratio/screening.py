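"""Volcano-style per-feature screening.

Each candidate feature is compared between the two endpoint groups with a
two-sided Wilcoxon rank-sum test and an anti-log fold change; a feature is
called significant when |log2 fold change| > 1.0 and −log10(p) > 1.3, with
no multiple-testing correction (a Benjamini-Hochberg column is emitted for
reference but never alters the significance flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rank_sum_test", "volcano", "VolcanoRow"]


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p via the subset-sum count distribution.

    Pools the samples, assigns midranks (doubled to integers so ties are
    exact), and counts the number of size-``len(x)`` subsets attaining each
    possible rank sum with a dynamic program.  The two-sided p-value is
    ``min(1, 2 * min(P(W <= w), P(W >= w)))``.
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2.0 * stats.rankdata(pooled)).astype(np.int64)
    w_obs = int(ranks2[:nx].sum())

    total = int(ranks2.sum())
    # counts[k, s] = number of k-subsets of the pooled doubled-ranks with sum s
    counts = np.zeros((nx + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in ranks2:
        kmax = nx  # iterate k downward so each value is used at most once
        for k in range(min(kmax, nx), 0, -1):
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    dist = counts[nx]
    n_total = dist.sum()
    p_le = dist[: w_obs + 1].sum() / n_total
    p_ge = dist[w_obs:].sum() / n_total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    nx, ny = len(x), len(y)
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1.0))
    var = nx * ny / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        return 1.0
    diff = w - mu
    # continuity correction shrinks |W - E[W]| by 1/2 toward the null
    z = (abs(diff) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def rank_sum_test(x, y, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value for two independent samples.

    Parameters
    ----------
    x, y
        The two samples; each must contain at least one observation.
    mode
        ``'exact'`` enumerates the full rank-sum distribution (ties handled
        through doubled midranks); ``'approximate'`` uses the normal
        approximation with tie and continuity corrections; ``'auto'``
        (default) uses the exact distribution when ``len(x)+len(y) <= 12``
        and the pooled data are tie-free, the approximation otherwise.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must contain at least one observation")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("samples must not contain NaN")
    if mode == "auto":
        pooled = np.concatenate([x, y])
        no_ties = len(np.unique(pooled)) == len(pooled)
        mode = "exact" if (len(pooled) <= 12 and no_ties) else "approximate"
    if mode == "exact":
        return _exact_rank_sum_p(x, y)
    if mode == "approximate":
        return _approx_rank_sum_p(x, y)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class VolcanoRow:
    feature_id: str
    log2_fc: float
    p_value: float
    neg_log10_p: float
    significant: bool
    evaluable: bool


def volcano(
    features: pd.DataFrame,
    labels,
    lfc_threshold: float = 1.0,
    nlp_threshold: float = 1.3,
    center: str = "median",
    mode: str = "auto",
) -> pd.DataFrame:
    """Two-group volcano screen over a log2-scale feature matrix.

    Parameters
    ----------
    features
        Patients x features, log2 scale, NaN for missing.
    labels
        Binary vector aligned to ``features`` rows; group 1 is the
        positive class (R or CB) and fold changes are group-1 over group-0.
    lfc_threshold, nlp_threshold
        Significance gates: |log2 FC| > 1.0 and −log10 p > 1.3 by default.
    center
        ``'median'`` (default, consistent with the rank-based test) or
        ``'mean'`` — the per-group central value, taken on the anti-log
        scale, from which the fold change is computed.

    Returns a DataFrame with one row per feature: ``log2_fc``, ``p_value``,
    ``neg_log10_p``, ``significant``, ``evaluable`` and a reference
    Benjamini-Hochberg ``q_value`` that never affects ``significant``.
    """
    labels = np.asarray(labels).ravel().astype(int)
    if len(labels) != len(features):
        raise ValueError("labels must align with feature matrix rows")
    rows = []
    for fid in features.columns:
        col = features[fid].to_numpy(dtype=float)
        g1 = col[(labels == 1) & ~np.isnan(col)]
        g0 = col[(labels == 0) & ~np.isnan(col)]
        if len(g1) < 2 or len(g0) < 2:
            rows.append((fid, np.nan, np.nan, np.nan, False, False))
            continue
        if center == "median":
            # median commutes with the monotone anti-log, so the log2 fold
            # change of medians is just the difference of log2 medians
            lfc = float(np.median(g1) - np.median(g0))
        elif center == "mean":
            lfc = float(np.log2(np.mean(2.0**g1)) - np.log2(np.mean(2.0**g0)))
        else:
            raise ValueError(f"unknown center {center!r}")
        p = rank_sum_test(g1, g0, mode=mode)
        nlp = float(-np.log10(p))
        sig = bool(abs(lfc) > lfc_threshold and nlp > nlp_threshold)
        rows.append((fid, lfc, p, nlp, sig, True))

    out = pd.DataFrame(
        rows,
        columns=["feature_id", "log2_fc", "p_value", "neg_log10_p", "significant", "evaluable"],
    ).set_index("feature_id")
    out["q_value"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values; NaNs propagate."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return q
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q
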