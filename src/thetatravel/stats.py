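"""Nonparametric summaries: bootstrap medians, exact rank tests, report
assembly.

Summary statistics follow the convention of reporting medians with 95 %
bootstrap confidence intervals over 500 resamples.  Rank tests use exact
small-sample null distributions (for n = 6 paired data the signed-rank
statistic attains its maximum of 21 with two-sided probability
2/2⁶ = 0.03125).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass

import numpy as np
from scipy import stats as sstats

log = logging.getLogger(__name__)


def bootstrap_median_ci(values, n_boot: int = 500, level: float = 0.95,
                        seed: int = 0):
    """Median with percentile bootstrap CI over ``n_boot`` resamples."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("bootstrap_median_ci: empty input")
    if x.size == 1:
        return float(x[0]), float(x[0]), float(x[0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    meds = np.median(x[idx], axis=1)
    alpha = 100 * (1 - level) / 2
    lo, hi = np.percentile(meds, [alpha, 100 - alpha])
    return float(np.median(x)), float(lo), float(hi)


def bootstrap_within_subject_ci(values_by_subject: np.ndarray,
                                n_boot: int = 500, level: float = 0.95,
                                seed: int = 0):
    """Bootstrap CI on the within-subject effect.

    ``values_by_subject`` is subjects × conditions; subject means are
    subtracted before resampling subjects, so the CI reflects the
    within-subject condition effect.  Returns (condition_medians, lo, hi)
    arrays over conditions.
    """
    v = np.asarray(values_by_subject, dtype=float)
    centered = v - np.nanmean(v, axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    n_subj = v.shape[0]
    idx = rng.integers(0, n_subj, size=(n_boot, n_subj))
    meds = np.nanmedian(centered[idx], axis=1)  # (n_boot, conditions)
    alpha = 100 * (1 - level) / 2
    lo, hi = np.percentile(meds, [alpha, 100 - alpha], axis=0)
    return np.nanmedian(v, axis=0), lo, hi


def signed_rank_test(x, y=None):
    """Wilcoxon signed-rank test (paired / one-sample), exact null for
    small n without ties.

    Returns (W, W_max, p_two_sided) where W is the positive-rank sum and
    ``W_max = n(n+1)/2`` its maximum.  Ties are handled by mid-ranks (with
    a normal approximation in that case, as exact enumeration no longer
    applies).
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 0.0, 1.0
    ranks = sstats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_max = n * (n + 1) / 2.0
    has_ties = np.unique(np.abs(d)).size < n
    mode = "approx" if (has_ties or n > 25) else "exact"
    res = sstats.wilcoxon(d, alternative="two-sided", mode=mode)
    return w_pos, w_max, float(min(res.pvalue, 1.0))


def rank_sum_test(x, y):
    """Wilcoxon rank-sum (Mann–Whitney) test, exact for small samples.

    Returns (rank_sum, rank_sum_max, p_two_sided) for the first sample,
    with mid-ranks on ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    n, m = x.size, y.size
    ranks = sstats.rankdata(np.concatenate([x, y]))
    rank_sum = float(ranks[:n].sum())
    rank_sum_max = float(sum(range(m + 1, n + m + 1)))
    has_ties = np.unique(np.concatenate([x, y])).size < n + m
    method = "asymptotic" if has_ties else "exact"
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return rank_sum, rank_sum_max, float(res.pvalue)


def signed_rank_exact_p(w: int, n: int) -> float:
    """Closed-form two-sided exact p for the signed-rank statistic by full
    enumeration of the 2^n sign assignments (no ties).  Used as the
    independent check of the exact test path."""
    sums = np.zeros(1, dtype=np.int64)
    for r in range(1, n + 1):
        sums = np.concatenate([sums, sums + r])
    w_max = n * (n + 1) // 2
    dist = np.bincount(sums, minlength=w_max + 1) / 2.0 ** n
    # two-sided: double the smaller tail (statistic symmetric around w_max/2)
    lo = dist[: w + 1].sum()
    hi = dist[w:].sum()
    return float(min(1.0, 2 * min(lo, hi)))


def _to_jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def report(session_results, path=None) -> dict:
    """Aggregate per-session headline quantities into one report.

    ``session_results`` is an iterable of
    :class:`~thetatravel.model.TravelingWaveResults`.  Returns (and
    optionally writes) a JSON-ready dict with across-session medians of
    the gradient, metric-vs-distance slopes, asymmetry endpoints, delay
    profile, corrected delay and mechanism classifications.
    """
    sessions = [r.headline() for r in session_results]
    out = {"n_sessions": len(sessions), "sessions": sessions}
    if sessions:
        keys = [k for k, v in sessions[0].items()
                if isinstance(v, (int, float)) and v is not None]
        for key in keys:
            vals = np.array([s.get(key, np.nan) for s in sessions], dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                med, lo, hi = bootstrap_median_ci(vals)
                out[f"median_{key}"] = {"median": med, "ci": [lo, hi]}
        cls = [s.get("mechanism") for s in sessions if s.get("mechanism")]
        if cls:
            out["mechanism_classifications"] = cls
    out = _to_jsonable(out)
    if path is not None:
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)
    return out
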