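"""Linear modeling of a target gene on its selected regulators.

All variables (response included) are z-scored across samples before fitting,
so coefficients are directly comparable within and across models.  Fitting is
ordinary least squares with an intercept; a regulator is called significant
when the t-based 95% confidence interval of its coefficient excludes zero.
Model quality is reported as R², adjusted R² and a Gaussian-likelihood BIC
(n·ln(RSS/n) + p·ln(n) with p = k + 1; additive constants dropped, so only
BIC differences are meaningful).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from ._util import logger


def zscore(data, ddof: int = 1):
    """Z-score each column to mean 0, variance 1 (denominator n-ddof).

    Accepts a DataFrame or Series; raises on constant columns, naming them.
    """
    if isinstance(data, pd.Series):
        sd = data.std(ddof=ddof)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {data.name!r} is constant; z-score undefined")
        return (data - data.mean()) / sd
    df = pd.DataFrame(data)
    sd = df.std(ddof=ddof)
    bad = sd.index[(sd == 0) | ~np.isfinite(sd)].tolist()
    if bad:
        raise ValueError(f"constant columns {bad}; z-score undefined")
    return (df - df.mean()) / sd


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Adjusted R² = 1 − (1 − R²)(n − 1)/(n − k − 1); requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"adjusted R2 undefined for n={n}, k={k}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def bic(n: int, rss: float, k: int) -> float:
    """Gaussian BIC, constants dropped: n·ln(RSS/n) + (k+1)·ln(n).

    A perfect fit (RSS = 0) is reported as −inf with a warning.
    """
    if rss <= 0:
        warnings.warn("BIC of a zero-residual model reported as -inf", stacklevel=2)
        return float("-inf")
    return n * np.log(rss / n) + (k + 1) * np.log(n)


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; carries the collinear column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; collinear columns: {self.columns}")


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    from scipy.linalg import qr

    A = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    _, R, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    names = ["<intercept>"] + list(X.columns)
    return sorted(names[i] for i in piv[rank:] if i > 0)


class InterpretableOLS(BaseEstimator, RegressorMixin):
    """OLS regression with confidence-interval significance calls.

    scikit-learn style estimator.  ``fit`` expects z-scored features and
    response; the intercept is still estimated (it is ≈0 on z-scored data
    but guards against imputation-induced mean shifts) and is never tested
    for significance.  Fitted attributes: ``coef_``, ``intercept_``,
    ``ci_low_``/``ci_high_``, ``significant_``, ``r2_``, ``adj_r2_``,
    ``bic_``, ``rss_``, ``n_``, ``k_``, ``feature_names_in_``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        n, k = X.shape
        if n <= k + 1:
            raise ValueError(f"need n > k + 1 samples; got n={n}, k={k}")
        design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(design) < k + 1:
            raise RankDeficientError(_collinear_columns(X))
        res = sm.OLS(y, design).fit()
        ci = res.conf_int(alpha=self.alpha)
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.ci_low_ = np.asarray(ci[1:, 0], dtype=float)
        self.ci_high_ = np.asarray(ci[1:, 1], dtype=float)
        self.significant_ = (self.ci_low_ > 0) | (self.ci_high_ < 0)
        self.rss_ = float(res.ssr)
        tss = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = float(res.rsquared) if tss > 0 else 0.0
        self.adj_r2_ = adjusted_r2(self.r2_, n, k) if k >= 0 else self.r2_
        rel_rss = self.rss_ / tss if tss > 0 else self.rss_
        self.bic_ = bic(n, 0.0 if rel_rss < 1e-14 else self.rss_, k)
        self.n_, self.k_ = n, k
        self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
        self.n_features_in_ = k
        return self

    def predict(self, X):
        X = pd.DataFrame(X)
        return self.intercept_ + X[list(self.feature_names_in_)].to_numpy(dtype=float) @ self.coef_


@dataclass
class RegressionModel:
    """Serializable record of one fitted target-gene model."""

    target_gene: str
    level: str
    features: tuple[str, ...]
    coefficients: tuple[float, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]
    significant: tuple[bool, ...]
    intercept: float
    r2: float
    adj_r2: float
    bic: float
    n: int
    k: int

    def predict(self, data: pd.DataFrame) -> pd.Series:
        """Apply the fitted linear map to new (z-scored) feature values."""
        vals = data[list(self.features)].to_numpy(dtype=float)
        return pd.Series(
            self.intercept + vals @ np.asarray(self.coefficients), index=data.index
        )

    def significant_features(self) -> dict[str, float]:
        return {
            f: c for f, c, s in zip(self.features, self.coefficients, self.significant) if s
        }

    def to_dict(self) -> dict:
        return {
            "target_gene": self.target_gene, "level": self.level,
            "features": list(self.features),
            "coefficients": list(self.coefficients),
            "ci_low": list(self.ci_low), "ci_high": list(self.ci_high),
            "significant": [bool(s) for s in self.significant],
            "intercept": self.intercept, "r2": self.r2, "adj_r2": self.adj_r2,
            "bic": self.bic, "n": self.n, "k": self.k,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegressionModel":
        return cls(
            target_gene=d["target_gene"], level=d["level"],
            features=tuple(d["features"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            ci_low=tuple(float(c) for c in d["ci_low"]),
            ci_high=tuple(float(c) for c in d["ci_high"]),
            significant=tuple(bool(s) for s in d["significant"]),
            intercept=float(d["intercept"]), r2=float(d["r2"]),
            adj_r2=float(d["adj_r2"]), bic=float(d["bic"]),
            n=int(d["n"]), k=int(d["k"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RegressionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_ols(
    X: pd.DataFrame,
    y: pd.Series,
    target_gene: str | None = None,
    level: str = "",
) -> RegressionModel:
    """Fit OLS of ``y`` on the columns of ``X`` (both z-scored) and package the result."""
    est = InterpretableOLS().fit(X, y)
    return RegressionModel(
        target_gene=target_gene if target_gene is not None else str(y.name or ""),
        level=level,
        features=tuple(str(c) for c in X.columns),
        coefficients=tuple(float(c) for c in est.coef_),
        ci_low=tuple(float(c) for c in est.ci_low_),
        ci_high=tuple(float(c) for c in est.ci_high_),
        significant=tuple(bool(s) for s in est.significant_),
        intercept=est.intercept_,
        r2=est.r2_, adj_r2=est.adj_r2_, bic=est.bic_, n=est.n_, k=est.k_,
    )


def summarize_models(
    models: Iterable[RegressionModel | None],
    adj_r2_threshold: float = 0.6,
) -> pd.DataFrame:
    """Per (gene, level) table of fit quality with a good-fit flag.

    Genes whose consensus was empty at a level appear as "no model" rows
    (models passed as None must be accompanied by target/level via tuples).
    """
    rows = []
    for m in models:
        if m is None:
            continue
        rows.append({
            "target_gene": m.target_gene, "level": m.level, "k": m.k,
            "r2": m.r2, "adj_r2": m.adj_r2, "bic": m.bic,
            "good_fit": m.adj_r2 > adj_r2_threshold,
            "n_significant": int(sum(m.significant)),
        })
    return pd.DataFrame(
        rows,
        columns=["target_gene", "level", "k", "r2", "adj_r2", "bic",
                 "good_fit", "n_significant"],
    )


def strategy_summary(per_strategy: Mapping[str, tuple[int, int, float]]) -> pd.DataFrame:
    """Assemble the strategy-benchmark table: models computed, features selected, mean BIC."""
    rows = [
        {"strategy": s, "n_models": nm, "n_features": nf, "mean_bic": mb}
        for s, (nm, nf, mb) in per_strategy.items()
    ]
    return pd.DataFrame(rows, columns=["strategy", "n_models", "n_features", "mean_bic"])
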