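"""Epigenetic age predictors ("clocks") built from percent methylation.

Three model families are provided, each as a small model class whose
``fit()`` returns a :class:`ClockFit` results object:

``LinearTopKClock``
    Ordinary least squares of age (days) on the k sites with the largest
    training-set |Pearson r| vs untransformed age, greedily skipping sites
    within 100 bp of an already-chosen site on the same chromosome.
``ElasticNetClock``
    Elastic-net penalized regression (alpha = 0.5 mixing, gaussian family) of
    log10(age days) on standardized predictors; the penalty weight lambda is
    chosen by leave-one-out cross-validation over a 100-point log-spaced grid
    spanning four decades below lambda_max.
``PCAClock``
    PC1 of the training-set age-associated sites (|Spearman rho| > 0.5),
    centred and scaled, oriented to correlate positively with age, then an
    OLS line from PC1 to age.

All fits flatten to one prediction interface — a weighted sum of raw percent
methylation plus an intercept, back-transformed to days — so a site missing
from a new dataset simply contributes zero, mirroring how prediction degrades
when a clock is applied to a cohort with incomplete coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import pearson_rows, spearman_rows
from .dataset import MethylationDataset


# ------------------------------------------------------------------ splits

def split_train_test(
    ds: MethylationDataset, test_size: int = 10, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified random train/test split: 1-2 test samples per age group.

    Deterministic under ``seed``; raises if the requested test size cannot be
    met with 1-2 samples per group or if any group has fewer than 3 samples.
    """
    rng = np.random.default_rng(seed)
    groups = ds.groups()
    labels = list(pd.unique(groups))
    sizes = {g: int((groups == g).sum()) for g in labels}
    if min(sizes.values()) < 3:
        raise ValueError("every group needs >= 3 samples to split")
    if not len(labels) <= test_size <= 2 * len(labels):
        raise ValueError(
            f"test_size={test_size} infeasible with {len(labels)} groups at 1-2 per group"
        )
    n_extra = test_size - len(labels)
    extra_groups = rng.choice(labels, size=n_extra, replace=False) if n_extra else []
    take = {g: 1 + int(g in list(extra_groups)) for g in labels}
    ids = np.array(ds.sample_ids)
    test: list[str] = []
    for g in labels:
        members = ids[groups == g]
        chosen = rng.choice(members, size=take[g], replace=False)
        test.extend(chosen)
    train = [s for s in ids if s not in set(test)]
    return train, list(test)


# ------------------------------------------------------------------ results

@dataclass
class EvaluationResult:
    """Predicted vs true ages for one split, with MAE (days) and R^2.

    R^2 is the coefficient of determination on the day scale,
    1 - SSres/SStot, not a squared correlation.
    """

    predicted: np.ndarray
    truth: np.ndarray
    split: str = "train"

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.truth = np.asarray(self.truth, dtype=float)
        if self.predicted.shape != self.truth.shape or self.predicted.size == 0:
            raise ValueError("prediction/truth vectors must align and be nonempty")

    @property
    def mae(self) -> float:
        return float(np.mean(np.abs(self.predicted - self.truth)))

    @property
    def r2(self) -> float:
        ss_res = float(np.sum((self.truth - self.predicted) ** 2))
        ss_tot = float(np.sum((self.truth - self.truth.mean()) ** 2))
        return 1.0 - ss_res / ss_tot

    @property
    def abs_errors(self) -> np.ndarray:
        return np.abs(self.predicted - self.truth)


def evaluate(predicted, truth, split: str = "train") -> EvaluationResult:
    return EvaluationResult(np.asarray(predicted), np.asarray(truth), split)


def compare_overfit(train_eval: EvaluationResult, test_eval: EvaluationResult) -> dict:
    """Two-sample t-test on absolute errors of the train vs test split."""
    t, p = stats.ttest_ind(train_eval.abs_errors, test_eval.abs_errors, equal_var=False)
    return {
        "t": float(t),
        "p": float(p),
        "train_mae": train_eval.mae,
        "test_mae": test_eval.mae,
    }


def compare_groups(predictions: np.ndarray, groups: np.ndarray) -> dict:
    """One-way ANOVA of predicted age across exposure groups."""
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    arrays = [np.asarray(predictions)[groups == g] for g in labels]
    f, p = stats.f_oneway(*arrays)
    return {"F": float(f), "p": float(p), "groups": [str(g) for g in labels]}


@dataclass
class ClockFit:
    """A fitted epigenetic clock: sites, weights and the age transform.

    Prediction is ``transform_inverse(intercept + sum_j w_j * percent_j)``
    with absent sites contributing zero. ``extras`` holds family-specific
    detail (PCA loadings and scalers, the elastic-net lambda path, ...);
    ``training_meta`` records n_train, seed and selection parameters.
    JSON serialization round-trips bit-exactly.
    """

    family: str
    site_keys: list[str]
    weights: np.ndarray
    intercept: float
    age_transform: str = "identity"  # or "log10"
    extras: dict = field(default_factory=dict)
    training_meta: dict = field(default_factory=dict)
    train_predictions: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.site_keys) != len(self.weights):
            raise ValueError("weights must align 1:1 with sites")

    # ------------------------------------------------------------- predict
    def design_matrix(self, ds: MethylationDataset) -> np.ndarray:
        """Percent methylation at the model sites (samples x sites); absent
        sites and unobserved cells contribute zero."""
        key_to_row = {k: i for i, k in enumerate(ds.site_keys())}
        pct = ds.percent
        X = np.zeros((ds.n_samples, len(self.site_keys)))
        for j, key in enumerate(self.site_keys):
            i = key_to_row.get(key)
            if i is not None:
                col = pct[i]
                X[:, j] = np.where(np.isfinite(col), col, 0.0)
        return X

    def predict(self, ds: MethylationDataset) -> np.ndarray:
        """Predicted age in days for each sample of ``ds``."""
        yhat = self.intercept + self.design_matrix(ds) @ self.weights
        return self._inverse_transform(yhat)

    def _inverse_transform(self, y: np.ndarray) -> np.ndarray:
        if self.age_transform == "identity":
            return y
        if self.age_transform == "log10":
            return np.power(10.0, y)
        raise ValueError(f"unknown transform {self.age_transform!r}")

    def evaluate(self, ds: MethylationDataset, split: str = "test") -> EvaluationResult:
        return EvaluationResult(self.predict(ds), ds.ages(), split)

    # ------------------------------------------------------------- summary
    def summary(self) -> str:
        nz = int(np.sum(self.weights != 0))
        lines = [
            f"Epigenetic clock ({self.family})",
            f"  sites          : {len(self.site_keys)} ({nz} nonzero weights)",
            f"  age transform  : {self.age_transform}",
            f"  intercept      : {self.intercept:.6g}",
        ]
        for k, v in self.training_meta.items():
            lines.append(f"  {k:<15}: {v}")
        if "pc1_variance_explained" in self.extras:
            lines.append(
                f"  PC1 variance   : {self.extras['pc1_variance_explained'] * 100:.2f}%"
            )
        if "lambda" in self.extras:
            lines.append(f"  lambda         : {self.extras['lambda']:.6g}")
        head = sorted(
            zip(self.site_keys, self.weights), key=lambda t: -abs(t[1])
        )[:10]
        lines.append("  top sites      :")
        for key, w in head:
            lines.append(f"    {key:<24} {w:+.6g}")
        return "\n".join(lines)

    # ------------------------------------------------------------ serialize
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "family": self.family,
            "sites": list(self.site_keys),
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
            "age_transform": self.age_transform,
            "extras": _jsonify(self.extras),
            "training_meta": _jsonify(self.training_meta),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClockFit":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(s).read_text()
        payload = json.loads(text)
        return cls(
            family=payload["family"],
            site_keys=payload["sites"],
            weights=np.array(payload["weights"], dtype=float),
            intercept=payload["intercept"],
            age_transform=payload["age_transform"],
            extras=payload.get("extras", {}),
            training_meta=payload.get("training_meta", {}),
        )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [float(v) for v in obj.ravel()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ------------------------------------------------------------------- models

class LinearTopKClock:
    """OLS clock on the top-k age-correlated sites with a 100 bp spacing rule."""

    def __init__(self, ds: MethylationDataset, k: int = 10, min_spacing_bp: int = 100):
        self.ds = ds
        self.k = k
        self.min_spacing_bp = min_spacing_bp

    def fit(self) -> ClockFit:
        ds = self.ds
        ages = ds.ages()
        pct = np.nan_to_num(ds.percent)
        r = pearson_rows(pct, ages)
        r = np.where(np.isfinite(r), r, 0.0)
        # rank by |r| descending, ties by (chrom, pos, strand) order
        order = np.lexsort(
            (np.arange(len(r)), -np.abs(r))
        )
        chrom = ds.sites["chrom"].to_numpy()
        pos = ds.sites["pos"].to_numpy()
        chosen: list[int] = []
        for i in order:
            if len(chosen) == self.k:
                break
            too_close = any(
                chrom[i] == chrom[j] and abs(int(pos[i]) - int(pos[j])) <= self.min_spacing_bp
                for j in chosen
            )
            if not too_close:
                chosen.append(int(i))
        if len(chosen) < self.k:
            raise ValueError(
                f"only {len(chosen)} sites available after {self.min_spacing_bp} bp spacing"
            )
        X = pct[chosen].T  # samples x k
        A = np.column_stack([np.ones(len(ages)), X])
        beta, *_ = np.linalg.lstsq(A, ages, rcond=None)
        keys = ds.site_keys()[chosen]
        fitobj = ClockFit(
            family="linear_topk",
            site_keys=list(keys),
            weights=beta[1:],
            intercept=float(beta[0]),
            age_transform="identity",
            extras={"pearson_r": [float(r[i]) for i in chosen]},
            training_meta={
                "n_train": ds.n_samples,
                "k": self.k,
                "min_spacing_bp": self.min_spacing_bp,
            },
        )
        fitobj.train_predictions = fitobj.predict(ds)
        return fitobj


class ElasticNetClock:
    """Elastic-net clock of log10(age) with LOO-CV lambda selection.

    The objective is (1/2n) * ||y - b0 - Xb||^2 + lambda * (alpha*||b||_1 +
    (1-alpha)/2 * ||b||^2) on standardized predictors. ``lambda_`` fixes the
    penalty directly and skips cross-validation (0 gives the OLS limit).
    """

    def __init__(
        self,
        ds: MethylationDataset,
        alpha: float = 0.5,
        lambda_: float | None = None,
        n_lambda: int = 100,
        lambda_decades: float = 4.0,
    ):
        if ds.n_samples < 3:
            raise ValueError("need >= 3 training samples")
        self.ds = ds
        self.alpha = alpha
        self.lambda_ = lambda_
        self.n_lambda = n_lambda
        self.lambda_decades = lambda_decades

    # --------------------------------------------------------------- helpers
    @staticmethod
    def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)  # population sd, glmnet-style
        sd_safe = np.where(sd > 0, sd, 1.0)
        return (X - mean) / sd_safe, mean, sd_safe

    def _solve(self, Xs: np.ndarray, yc: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
        """Coefficients (p x n_lambda) for centred/standardized data."""
        from sklearn.linear_model import enet_path

        _, coefs, _ = enet_path(
            Xs, yc, l1_ratio=self.alpha, alphas=np.sort(lambdas)[::-1], max_iter=5000
        )
        # enet_path returns in decreasing-lambda order matching our sorted grid
        return coefs

    def _lambda_grid(self, Xs: np.ndarray, yc: np.ndarray) -> np.ndarray:
        n = len(yc)
        lam_max = np.max(np.abs(Xs.T @ yc)) / (n * max(self.alpha, 1e-3))
        lam_max = max(lam_max, 1e-12)
        return np.logspace(
            np.log10(lam_max), np.log10(lam_max) - self.lambda_decades, self.n_lambda
        )

    def fit(self) -> ClockFit:
        ds = self.ds
        ages = ds.ages()
        if np.allclose(ages, ages[0]):
            raise ValueError("degenerate (constant) response")
        y = np.log10(ages)
        X = np.nan_to_num(ds.percent).T  # samples x sites
        n = len(y)

        if self.lambda_ is not None and self.lambda_ == 0:
            Xs, mean, sd = self._standardize(X)
            A = np.column_stack([np.ones(n), Xs])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            w_std = beta[1:]
            b0 = float(beta[0])
            lam = 0.0
            cv_curve = None
        else:
            Xs, mean, sd = self._standardize(X)
            yc = y - y.mean()
            grid = self._lambda_grid(Xs, yc)
            if self.lambda_ is None:
                lam, cv_curve = self._loo_cv(X, y, grid)
            else:
                lam, cv_curve = float(self.lambda_), None
            coefs = self._solve(Xs, yc, np.array([lam]))
            w_std = coefs[:, -1]
            b0 = float(y.mean())
        # flatten to the raw percent scale
        w_raw = w_std / sd
        intercept = b0 - float(w_raw @ mean)
        nz = np.flatnonzero(w_raw != 0)
        keys = ds.site_keys()
        fitobj = ClockFit(
            family="elastic_net",
            site_keys=[keys[i] for i in nz],
            weights=w_raw[nz],
            intercept=intercept,
            age_transform="log10",
            extras={
                "lambda": float(lam),
                "alpha": self.alpha,
                "cv_mse": None if cv_curve is None else [float(v) for v in cv_curve[1]],
                "cv_lambdas": None if cv_curve is None else [float(v) for v in cv_curve[0]],
            },
            training_meta={"n_train": n, "alpha": self.alpha},
        )
        fitobj.train_predictions = fitobj.predict(ds)
        return fitobj

    def _loo_cv(self, X: np.ndarray, y: np.ndarray, grid: np.ndarray):
        """Leave-one-out CV MSE over the lambda grid (deterministic)."""
        n = len(y)
        sq_err = np.zeros((n, len(grid)))
        for i in range(n):
            mask = np.arange(n) != i
            Xt, yt = X[mask], y[mask]
            Xs, mean, sd = self._standardize(Xt)
            yc = yt - yt.mean()
            coefs = self._solve(Xs, yc, grid)  # p x n_lambda, decreasing lambda
            xi = (X[i] - mean) / sd
            preds = yt.mean() + xi @ coefs
            sq_err[i] = (y[i] - preds) ** 2
        mse = sq_err.mean(axis=0)
        grid_sorted = np.sort(grid)[::-1]
        best = int(np.argmin(mse))
        return float(grid_sorted[best]), (grid_sorted, mse)


class PCAClock:
    """PC1-based clock on training-set age-associated sites."""

    def __init__(self, ds: MethylationDataset, rho_threshold: float = 0.5, scale: bool = True):
        self.ds = ds
        self.rho_threshold = rho_threshold
        self.scale = scale

    def fit(self) -> ClockFit:
        ds = self.ds
        ages = ds.ages()
        pct = np.nan_to_num(ds.percent)
        rho = spearman_rows(pct, ages)
        rho = np.where(np.isfinite(rho), rho, 0.0)
        sel = np.flatnonzero(np.abs(rho) > self.rho_threshold)
        if len(sel) < 2:
            raise ValueError(
                f"fewer than 2 sites with |Spearman rho| > {self.rho_threshold}"
            )
        X = pct[sel].T  # samples x sites
        center = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if self.scale else np.ones(X.shape[1])
        sd = np.where(sd > 0, sd, 1.0)
        Z = (X - center) / sd
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        loadings = Vt[0]
        scores = Z @ loadings
        if np.corrcoef(scores, ages)[0, 1] < 0:  # orient PC1 with age
            loadings = -loadings
            scores = -scores
        var_explained = float(S[0] ** 2 / np.sum(S**2))
        A = np.column_stack([np.ones(len(ages)), scores])
        (b, a), *_ = np.linalg.lstsq(A, ages, rcond=None)
        w_raw = a * loadings / sd
        intercept = float(b - np.sum(a * loadings * center / sd))
        keys = ds.site_keys()
        fitobj = ClockFit(
            family="pca",
            site_keys=[keys[i] for i in sel],
            weights=w_raw,
            intercept=intercept,
            age_transform="identity",
            extras={
                "loadings": [float(v) for v in loadings],
                "center": [float(v) for v in center],
                "scale": [float(v) for v in sd],
                "pc1_slope": float(a),
                "pc1_intercept": float(b),
                "pc1_variance_explained": var_explained,
            },
            training_meta={
                "n_train": ds.n_samples,
                "rho_threshold": self.rho_threshold,
                "n_selected": int(len(sel)),
                "scaled": self.scale,
            },
        )
        fitobj.train_predictions = fitobj.predict(ds)
        return fitobj


FAMILIES = {
    "linear": LinearTopKClock,
    "linear_topk": LinearTopKClock,
    "enet": ElasticNetClock,
    "elastic_net": ElasticNetClock,
    "pca": PCAClock,
}


def fit_clock(ds: MethylationDataset, family: str, **kwargs) -> ClockFit:
    """Fit one clock family by name ('linear', 'enet' or 'pca')."""
    try:
        cls = FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown clock family {family!r}") from None
    return cls(ds, **kwargs).fit()
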