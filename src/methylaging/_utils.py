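"""Shared numerical helpers: seeded substreams, vectorized rank correlations, FDR."""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def substream(seed: int, *path: str) -> np.random.Generator:
    """Derive a named, reproducible random substream from one integer seed.

    Every source of randomness in the package flows through here so that a
    single seed fixes the whole study.
    """
    # Stable string->int hashing: SeedSequence accepts a sequence of ints.
    tokens = [seed] + [abs(hash_str(p)) for p in path]
    return np.random.default_rng(np.random.SeedSequence(tokens))


def hash_str(s: str) -> int:
    """Deterministic 31-bit hash of a string (``hash()`` is salted per process)."""
    h = 0
    for ch in s:
        h = (h * 1000003 + ord(ch)) & 0x7FFFFFFF
    return h


def rankdata_rows(x: np.ndarray) -> np.ndarray:
    """Midrank each row of a 2-D array (NaN-free input)."""
    return stats.rankdata(x, axis=1)


def pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``x`` (sites x samples) with vector ``y``.

    Rows with zero variance yield NaN.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = xc @ yc
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0, out=r) if r.size else r


def spearman_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho (midranks for ties) of each row of ``x`` with vector ``y``."""
    rx = rankdata_rows(x)
    ry = stats.rankdata(y)
    return pearson_rows(rx, ry)


def corr_pvalues_t(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for correlation coefficients via the t approximation."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return np.clip(p, 0.0, 1.0)


def spearman_exact_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Exact permutation p-value for Spearman rho (two-sided), small n only.

    Enumerates all orderings of ``y`` against fixed ``x``; intended for n < 10.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = _rank_corr(rx, ry)
    if np.isnan(obs):
        return 1.0
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = _rank_corr(rx, ry[list(perm)])
        total += 1
        if abs(rho) >= abs(obs) - 1e-12:
            count += 1
    return count / total


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs pass through)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        from statsmodels.stats.multitest import multipletests

        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def interval_distance(pos0: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """bp distance from 0-based positions to the nearest [start, end) interval.

    0 means containment. ``starts`` must be sorted; intervals non-overlapping.
    Returns +inf where no interval exists.
    """
    pos0 = np.asarray(pos0)
    if len(starts) == 0:
        return np.full(pos0.shape, np.inf)
    idx = np.searchsorted(starts, pos0, side="right")
    dist = np.full(pos0.shape, np.inf)
    has_prev = idx > 0
    pi = np.clip(idx - 1, 0, None)
    inside = has_prev & (pos0 < ends[pi])
    d_prev = np.where(has_prev, pos0 - (ends[pi] - 1), np.inf)
    has_next = idx < len(starts)
    ni = np.clip(idx, None, len(starts) - 1)
    d_next = np.where(has_next, starts[ni] - pos0, np.inf)
    dist = np.minimum(np.where(d_prev < 0, np.inf, d_prev), np.where(d_next < 0, np.inf, d_next))
    dist[inside] = 0
    return dist
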