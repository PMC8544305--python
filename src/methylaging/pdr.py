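"""Percent of discordant reads (PDR) and its trend with log age.

A read is *eligible* when it carries at least two CpG calls. Its within-read
methylation level m = 100 * mean(calls) classifies it as discordant when
10 <= m <= 90 and concordant otherwise (the thresholds act on the exact
fraction, no rounding; levels falling in the unreachable-for-small-reads gaps
(9, 10) and (90, 91) count as concordant). PDR is the percentage of
discordant reads among eligible reads.

The age trend is a linear mixed model PDR ~ ln(age_days) with a random
intercept per library batch (REML); with a single batch it falls back to OLS
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ReadPatternSet


def classify_read(calls) -> str:
    """'ineligible' (< 2 CpGs), 'discordant' (10% <= mean <= 90%) or 'concordant'."""
    calls = np.asarray(calls)
    if not np.isin(calls, (0, 1)).all():
        raise ValueError("calls must be binary 0/1")
    if calls.size < 2:
        return "ineligible"
    m = 100.0 * calls.mean()
    return "discordant" if 10.0 <= m <= 90.0 else "concordant"


@dataclass
class PdrResult:
    sample_id: str
    n_eligible: int
    n_discordant: int

    @property
    def pdr(self) -> float:
        return 100.0 * self.n_discordant / self.n_eligible


def compute_pdr(patterns: ReadPatternSet, sample_id: str) -> PdrResult:
    """PDR for one sample: discordant reads over reads with >= 2 CpGs."""
    sub = patterns.df[patterns.df["sample_id"] == sample_id]
    calls = sub["calls"].astype(str)
    if calls.str.contains(r"[^01]").any():
        raise ValueError("calls must be binary 0/1 strings")
    length = calls.str.len()
    m = 100.0 * calls.str.count("1") / length
    eligible = length >= 2
    discordant = eligible & (m >= 10.0) & (m <= 90.0)
    n_elig = int(eligible.sum())
    if n_elig == 0:
        raise ValueError(f"sample {sample_id!r} has no eligible reads (>= 2 CpGs)")
    return PdrResult(sample_id=sample_id, n_eligible=n_elig, n_discordant=int(discordant.sum()))


def pdr_table(patterns: ReadPatternSet) -> pd.DataFrame:
    """PDR per sample for every sample in the pattern set."""
    rows = []
    for sid in patterns.sample_ids():
        res = compute_pdr(patterns, sid)
        rows.append(
            {
                "sample_id": sid,
                "n_eligible": res.n_eligible,
                "n_discordant": res.n_discordant,
                "pdr": res.pdr,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PdrTrendResult:
    """Fitted PDR ~ log(age) trend: slope in PDR percentage points per unit log-age."""

    slope: float
    se: float
    p: float
    intercept: float
    batch_variance: float
    n: int
    model: str  # "lmm" or "ols"

    def summary(self) -> str:
        lines = [
            "PDR ~ log(age) trend" + (" (mixed model, random batch intercept)"
                                      if self.model == "lmm" else " (OLS, single batch)"),
            f"  n observations : {self.n}",
            f"  slope          : {self.slope:.4g} (SE {self.se:.4g}, p {self.p:.3g})",
            f"  intercept      : {self.intercept:.4g}",
            f"  batch variance : {self.batch_variance:.4g}",
        ]
        return "\n".join(lines)


def pdr_age_trend(
    pdr: pd.DataFrame, metadata: pd.DataFrame, log_base: str = "e"
) -> PdrTrendResult:
    """Fit the PDR-vs-log(age) trend with a random intercept per library batch.

    ``pdr`` needs columns sample_id, pdr; ``metadata`` needs sample_id,
    age_days, batch. Natural-log age by default (``log_base="10"`` for log10).
    The slope p-value uses a t statistic on residual degrees of freedom
    (n - 2).
    """
    df = pdr.merge(metadata[["sample_id", "age_days", "batch"]], on="sample_id")
    ages = df["age_days"].to_numpy(dtype=float)
    if (ages <= 0).any():
        raise ValueError("non-positive ages")
    x = np.log(ages) if log_base == "e" else np.log10(ages)
    y = df["pdr"].to_numpy(dtype=float)
    n = len(df)
    batches = df["batch"].astype(str)
    from scipy import stats as sps

    if batches.nunique() >= 2:
        import statsmodels.api as sm

        exog = sm.add_constant(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=batches.to_numpy())
            fit = model.fit(reml=True)
            slope = float(np.asarray(fit.fe_params)[1])
            se = float(np.asarray(fit.bse_fe)[1])
            intercept = float(np.asarray(fit.fe_params)[0])
            batch_var = float(np.asarray(fit.cov_re)[0, 0])
        dfree = n - 2
        if not np.isfinite(se) or se <= 0:
            # boundary fit (zero batch variance): SE from the OLS information
            X = np.column_stack([np.ones(n), x])
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            sigma2 = float(resid @ resid) / dfree
            se = float(np.sqrt((sigma2 * np.linalg.inv(X.T @ X))[1, 1]))
        p = 2.0 * sps.t.sf(abs(slope / se), df=dfree)
        return PdrTrendResult(slope, se, float(p), intercept, batch_var, n, "lmm")
    warnings.warn("single batch: falling back to ordinary least squares")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dfree = n - 2
    sigma2 = float(resid @ resid) / dfree
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[1, 1]))
    slope = float(beta[1])
    p = 2.0 * sps.t.sf(abs(slope / se), df=dfree)
    return PdrTrendResult(slope, se, float(p), float(beta[0]), 0.0, n, "ols")
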