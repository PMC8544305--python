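"""RRBS preprocessing chain: coverage filter, coverage normalization, uniting
across samples, k-nearest-neighbour imputation, near-zero-variance removal.

The chain is order-fixed — filter -> normalize -> unite -> impute ->
variance-drop — and each step returns a new dataset. Coverage bounds are
inclusive at both ends (a 5x or 100x cell survives a 5-100x filter).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import MethylationDataset, merge_single_sample


def filter_by_coverage(
    ds: MethylationDataset, min_cov: int = 5, max_cov: int = 100
) -> MethylationDataset:
    """Mask cells with total coverage outside [min_cov, max_cov]; drop empty sites."""
    if min_cov > max_cov:
        raise ValueError(f"min_cov ({min_cov}) > max_cov ({max_cov})")
    cov = ds.coverage
    bad = np.isfinite(cov) & ((cov < min_cov) | (cov > max_cov))
    meth = ds.meth.copy()
    unmeth = ds.unmeth.copy()
    meth[bad] = np.nan
    unmeth[bad] = np.nan
    keep = np.isfinite(meth + unmeth).any(axis=1)
    return MethylationDataset(ds.sites, ds.samples, meth, unmeth).subset_sites(keep)


def normalize_coverage(ds: MethylationDataset) -> MethylationDataset:
    """Scale each sample's counts so per-sample median coverages match.

    The reference is the median of the per-sample median coverages. Totals are
    scaled and rounded; methylated counts are re-derived from each cell's
    pre-scaling methylation fraction so the fraction is preserved within
    rounding (at most 1/(2*coverage)).
    """
    if ds.n_samples < 2:
        raise ValueError("normalization needs at least 2 samples")
    cov = ds.coverage
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(cov, axis=0)
    if np.any(~np.isfinite(medians)) or np.any(medians <= 0):
        raise ValueError("a sample has zero median coverage")
    reference = float(np.median(medians))
    factors = reference / medians
    frac = ds.meth / cov  # NaN-safe: NaN cells stay NaN
    new_total = np.round(cov * factors[None, :])
    new_meth = np.round(frac * new_total)
    new_unmeth = new_total - new_meth
    return MethylationDataset(ds.sites, ds.samples, new_meth, new_unmeth)


def unite_sites(
    datasets: "MethylationDataset | Iterable[MethylationDataset]",
    min_per_group: int = 5,
) -> MethylationDataset:
    """Keep sites observed in at least ``min_per_group`` samples of every group.

    Accepts either one multi-sample dataset or an iterable of single-sample
    datasets (which are outer-joined first). Unobserved cells stay missing.
    """
    if not isinstance(datasets, MethylationDataset):
        datasets = merge_single_sample(datasets)
    ds = datasets
    groups = ds.groups()
    labels = pd.unique(groups)
    counts = {g: int((groups == g).sum()) for g in labels}
    for g, n in counts.items():
        if n < min_per_group:
            raise ValueError(
                f"group {g!r} has {n} samples < min_per_group={min_per_group}: "
                "criterion unsatisfiable"
            )
    observed = np.isfinite(ds.meth + ds.unmeth)
    keep = np.ones(ds.n_sites, dtype=bool)
    for g in labels:
        keep &= observed[:, groups == g].sum(axis=1) >= min_per_group
    return ds.subset_sites(keep)


def impute_knn(ds: MethylationDataset, k: int = 4) -> MethylationDataset:
    """Fill missing percent values from the k nearest sites.

    Distance between two sites is the Euclidean distance of their percent
    profiles over samples where both are observed (unscaled); ties are broken
    by site order. A missing cell (site i, sample s) is imputed as the mean
    percent at s over the k nearest sites that are observed at s. Counts are
    left untouched — everything downstream of imputation works on percent.
    """
    if ds.n_sites < k + 1:
        raise ValueError(f"need at least k+1={k + 1} sites for k={k} imputation")
    pct = ds.percent.copy()
    obs = np.isfinite(pct)
    if (~obs).all(axis=1).any():
        raise ValueError("a site is missing in all samples; unite/filter first")
    if obs.all():
        return MethylationDataset(ds.sites, ds.samples, ds.meth, ds.unmeth, pct)

    X0 = np.where(obs, pct, 0.0)
    M = obs.astype(float)
    X0sq = X0**2
    n = ds.n_sites
    need = np.flatnonzero(~obs.all(axis=1))
    filled = pct
    chunk = max(1, int(2e7 // max(n, 1)))
    for lo in range(0, len(need), chunk):
        rows = need[lo : lo + chunk]
        # squared distance over common mask: x2.m' + m.x2' - 2 x.x'
        d2 = X0sq[rows] @ M.T + M[rows] @ X0sq.T - 2.0 * X0[rows] @ X0.T
        common = M[rows] @ M.T
        d2[common == 0] = np.inf
        np.clip(d2, 0.0, None, out=d2)
        for r_local, i in enumerate(rows):
            d = d2[r_local].copy()
            d[i] = np.inf
            # cheap preselection of candidates; fall back to a full scan if the
            # nearest observed neighbours are not among them
            m_cand = min(n, max(50, 16 * k))
            if m_cand < n:
                cand = np.argpartition(d, m_cand - 1)[:m_cand]
                order = cand[np.lexsort((cand, d[cand]))]  # distance, then site order
            else:
                order = np.lexsort((np.arange(n), d))
            missing_samples = np.flatnonzero(~obs[i])
            for s in missing_samples:
                vals = _nearest_observed(order, d, obs, X0, s, k)
                if vals is None and m_cand < n:
                    full = np.lexsort((np.arange(n), d))
                    vals = _nearest_observed(full, d, obs, X0, s, k)
                if vals is None or not vals:
                    raise ValueError(
                        f"no observed neighbour for site {i} sample {s}; cannot impute"
                    )
                filled[i, s] = float(np.mean(vals))
    return MethylationDataset(ds.sites, ds.samples, ds.meth, ds.unmeth, filled)


def _nearest_observed(order, d, obs, X0, s, k):
    """Values of the k nearest sites observed at sample ``s``; None if the
    candidate list is exhausted before k are found while closer sites remain."""
    vals = []
    for j in order:
        if not np.isfinite(d[j]):
            break
        if obs[j, s]:
            vals.append(X0[j, s])
            if len(vals) == k:
                return vals
    # ran out of candidates: only trustworthy if the scan covered everything
    return vals if len(order) == len(d) else None


def drop_near_zero_variance(ds: MethylationDataset) -> MethylationDataset:
    """Remove near-invariant sites from an imputed dataset.

    A site is dropped when (most common value count / second most common value
    count) > 19 and (number of distinct values / number of samples) <= 0.10 —
    the frequency-ratio and unique-percent rule used for near-zero-variance
    screening. A fully constant site is always dropped.
    """
    pct = ds.percent
    keep = np.ones(ds.n_sites, dtype=bool)
    nsamp = ds.n_samples
    for i in range(ds.n_sites):
        vals = pct[i][np.isfinite(pct[i])]
        if len(vals) == 0:
            keep[i] = False
            continue
        uniq, counts = np.unique(vals, return_counts=True)
        if len(uniq) == 1:
            keep[i] = False
            continue
        counts = np.sort(counts)[::-1]
        freq_ratio = counts[0] / counts[1]
        unique_frac = len(uniq) / nsamp
        if freq_ratio > 19 and unique_frac <= 0.10:
            keep[i] = False
    return ds.subset_sites(keep)


def preprocess_chain(
    datasets,
    min_cov: int = 5,
    max_cov: int = 100,
    min_per_group: int = 5,
    knn_k: int = 4,
    normalize: bool = True,
) -> MethylationDataset:
    """Run the full preprocessing chain on raw single- or multi-sample data.

    An already-imputed dataset is returned unchanged: counts stop being the
    authoritative signal once percent values have been imputed, so the chain
    is idempotent from the second application onward.
    """
    if not isinstance(datasets, MethylationDataset):
        datasets = merge_single_sample(datasets)
    if datasets.is_imputed:
        return datasets
    ds = filter_by_coverage(datasets, min_cov=min_cov, max_cov=max_cov)
    if normalize and ds.n_samples >= 2:
        ds = normalize_coverage(ds)
    ds = unite_sites(ds, min_per_group=min_per_group)
    ds = impute_knn(ds, k=knn_k)
    ds = drop_near_zero_variance(ds)
    return ds
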