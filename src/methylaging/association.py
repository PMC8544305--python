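"""Per-site age association: rank correlations, FDR control, correlation
binning, differential-methylation calls, and early- vs late-life rates.

A site is *age-associated* when its Spearman correlation with age (in days)
exceeds 0.5 in magnitude. Sites are also sorted into seven correlation bins
spanning the aging continuum; boundary coefficients (+/-0.25, +/-0.5) go to
the bin farther from zero, and exactly-zero coefficients form their own bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import (
    bh_qvalues,
    corr_pvalues_t,
    pearson_rows,
    spearman_exact_pvalue,
    spearman_rows,
)
from .dataset import MethylationDataset

BIN_LABELS = [
    "-1.0 to -0.5",
    "-0.5 to -0.25",
    "-0.25 to 0",
    "0",
    "0 to 0.25",
    "0.25 to 0.5",
    "0.5 to 1.0",
]

RHO_THRESHOLD = 0.5


def assign_bin(rho: float) -> str:
    """Correlation-continuum bin; boundaries go to the bin farther from zero."""
    if np.isnan(rho):
        return "0"
    if rho == 0:
        return "0"
    if rho <= -0.5:
        return "-1.0 to -0.5"
    if rho <= -0.25:
        return "-0.5 to -0.25"
    if rho < 0:
        return "-0.25 to 0"
    if rho < 0.25:
        return "0 to 0.25"
    if rho < 0.5:
        return "0.25 to 0.5"
    return "0.5 to 1.0"


def site_age_correlation(
    ds: MethylationDataset,
    method: str = "spearman",
    age_transform: str = "identity",
) -> pd.DataFrame:
    """Correlate each site's percent methylation with sample age.

    Returns a table with Spearman rho, Pearson r, the p-value of the requested
    ``method`` coefficient, Benjamini-Hochberg q across all tested sites, the
    correlation bin of rho, and the age-associated flag (|rho| > 0.5).
    Constant sites get rho = 0, p = 1 and ``degenerate=True``.

    p-values use the t approximation for n >= 10 samples and an exact
    permutation enumeration below that (Spearman only).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    ages = ds.ages()
    if age_transform == "log10":
        ages = np.log10(ages)
    elif age_transform != "identity":
        raise ValueError(f"unknown age_transform {age_transform!r}")
    if len(np.unique(ages)) < 3:
        raise ValueError("need >= 3 samples with distinct ages")
    pct = ds.percent
    if np.isnan(pct).any():
        raise ValueError("correlation requires a complete (imputed) percent matrix")
    n = ds.n_samples

    degenerate = pct.std(axis=1) == 0
    rho = spearman_rows(pct, ages)
    r = pearson_rows(pct, ages)
    rho[degenerate] = 0.0
    r[degenerate] = 0.0
    coef = rho if method == "spearman" else r
    if n >= 10 or method == "pearson":
        p = corr_pvalues_t(coef, n)
    else:
        p = np.array(
            [
                1.0 if degenerate[i] else spearman_exact_pvalue(pct[i], ages)
                for i in range(ds.n_sites)
            ]
        )
    p[degenerate] = 1.0
    q = bh_qvalues(p)
    out = ds.sites.copy()
    out["rho"] = rho
    out["r"] = r
    out["p"] = p
    out["q"] = q
    out["bin"] = [assign_bin(v) for v in rho]
    out["age_associated"] = np.abs(rho) > RHO_THRESHOLD
    out["degenerate"] = degenerate
    return out


def classify_and_bin(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """(Re)assign bins from rho and tabulate bin occupancy (a partition of sites)."""
    records = records.copy()
    records["bin"] = [assign_bin(v) for v in records["rho"]]
    records["age_associated"] = np.abs(records["rho"]) > RHO_THRESHOLD
    occupancy = records["bin"].value_counts().reindex(BIN_LABELS, fill_value=0)
    return records, occupancy


@dataclass
class DmcOptions:
    diff_threshold: float = 25.0
    q_threshold: float = 0.01
    test: str = "lrt"  # or "fisher"


def call_dmcs(
    ds: MethylationDataset,
    group_a: str,
    group_b: str,
    diff_threshold: float = 25.0,
    q_threshold: float = 0.01,
    test: str = "lrt",
) -> pd.DataFrame:
    """Differentially methylated cytosines between two sample groups.

    Counts are pooled within each group per site; the default p-value is a
    two-proportion likelihood-ratio (G) test — the binomial logistic model of
    methylation state on group with no covariates — with Fisher's exact test
    available via ``test="fisher"``. q is Benjamini-Hochberg across tested
    sites. A DMC has |meth_diff| >= diff_threshold (percent, group_b - group_a)
    and q <= q_threshold. Sites with zero pooled coverage in either group are
    skipped.
    """
    groups = ds.groups()
    for g in (group_a, group_b):
        if (groups == g).sum() < 1:
            raise ValueError(f"group {g!r} has no samples")
    a_cols = groups == group_a
    b_cols = groups == group_b
    meth = np.nan_to_num(ds.meth)
    unmeth = np.nan_to_num(ds.unmeth)
    ma = meth[:, a_cols].sum(axis=1)
    ua = unmeth[:, a_cols].sum(axis=1)
    mb = meth[:, b_cols].sum(axis=1)
    ub = unmeth[:, b_cols].sum(axis=1)
    na = ma + ua
    nb = mb + ub
    ok = (na > 0) & (nb > 0)

    pa = np.divide(ma, na, out=np.zeros_like(ma), where=na > 0)
    pb = np.divide(mb, nb, out=np.zeros_like(mb), where=nb > 0)
    meth_diff = 100.0 * (pb - pa)

    if test == "lrt":
        p = _lrt_two_proportions(ma, na, mb, nb)
    elif test == "fisher":
        p = np.array(
            [
                stats.fisher_exact([[ma[i], ua[i]], [mb[i], ub[i]]])[1] if ok[i] else np.nan
                for i in range(len(ma))
            ]
        )
    else:
        raise ValueError(f"unknown test {test!r}")
    p[~ok] = np.nan
    q = bh_qvalues(p)
    out = ds.sites.copy()
    out["group_a"] = group_a
    out["group_b"] = group_b
    out["meth_a"] = 100.0 * pa
    out["meth_b"] = 100.0 * pb
    out["meth_diff"] = meth_diff
    out["p"] = p
    out["q"] = q
    out["is_dmc"] = (np.abs(meth_diff) >= diff_threshold) & (q <= q_threshold)
    out["direction"] = np.where(meth_diff > 0, "hyper", np.where(meth_diff < 0, "hypo", "none"))
    out["tested"] = ok
    out.loc[~ok, "is_dmc"] = False
    return out


def _lrt_two_proportions(ma, na, mb, nb) -> np.ndarray:
    """G-statistic p-values for pooled two-group binomial counts (df=1)."""

    def loglik(m, n, p):
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(m > 0, m * np.log(np.clip(p, 1e-300, None)), 0.0)
            t2 = np.where(n - m > 0, (n - m) * np.log(np.clip(1 - p, 1e-300, None)), 0.0)
        return t1 + t2

    with np.errstate(invalid="ignore"):
        p0 = (ma + mb) / np.clip(na + nb, 1, None)
        pa = np.divide(ma, na, out=np.zeros_like(ma, dtype=float), where=na > 0)
        pb = np.divide(mb, nb, out=np.zeros_like(mb, dtype=float), where=nb > 0)
    g = 2.0 * (
        loglik(ma, na, pa) + loglik(mb, nb, pb) - loglik(ma, na, p0) - loglik(mb, nb, p0)
    )
    g = np.clip(g, 0.0, None)
    return stats.chi2.sf(g, df=1)


def early_late_rates(
    ds: MethylationDataset,
    age_sites: np.ndarray,
    early: tuple[str, str],
    late: tuple[str, str],
) -> dict:
    """Per-day absolute rate of methylation change in early vs late life.

    For each age-associated site, the absolute change in group-mean percent
    methylation across the early interval (group early[0] -> early[1]) and the
    late interval, each divided by the actual days elapsed between the groups'
    mean ages. The two per-day rate vectors are compared with a paired t-test
    (df = n_sites - 1).
    """
    idx = np.asarray(age_sites)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if len(idx) == 0:
        raise ValueError("age_sites is empty")
    pct = ds.percent[idx]
    groups = ds.groups()
    ages = ds.ages()

    def group_stats(g):
        cols = groups == g
        if cols.sum() == 0:
            raise ValueError(f"group {g!r} has no samples")
        return np.nanmean(pct[:, cols], axis=1), float(np.mean(ages[cols]))

    e0, t_e0 = group_stats(early[0])
    e1, t_e1 = group_stats(early[1])
    l0, t_l0 = group_stats(late[0])
    l1, t_l1 = group_stats(late[1])
    days_early = t_e1 - t_e0
    days_late = t_l1 - t_l0
    if days_early <= 0 or days_late <= 0:
        raise ValueError("zero or negative days elapsed in an interval")
    abs_early = np.abs(e1 - e0)
    abs_late = np.abs(l1 - l0)
    rate_early = abs_early / days_early
    rate_late = abs_late / days_late
    diffs = rate_early - rate_late
    if np.allclose(diffs, diffs[0]) and np.isclose(diffs[0], 0.0):
        t_stat, p = 0.0, 1.0  # identical rates: no evidence either way
    else:
        t_stat, p = stats.ttest_rel(rate_early, rate_late)
    return {
        "per_site": pd.DataFrame(
            {
                "abs_change_early": abs_early,
                "abs_change_late": abs_late,
                "rate_early_per_day": rate_early,
                "rate_late_per_day": rate_late,
            }
        ),
        "mean_abs_change_early": float(abs_early.mean()),
        "mean_abs_change_late": float(abs_late.mean()),
        "mean_rate_early_per_day": float(rate_early.mean()),
        "mean_rate_late_per_day": float(rate_late.mean()),
        "days_early": days_early,
        "days_late": days_late,
        "t": float(t_stat),
        "df": len(idx) - 1,
        "p": float(p),
    }
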