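"""Shared statistical machinery: rank correlation, covariate adjustment,
Bonferroni correction and leave-one-out cross-validation.

Effect sizes throughout the package are Spearman rho; LOOCV significance is
reported one-sided by default (a predictive map is expected to predict in
the stated direction), with two-sided available everywhere.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def pooled_t(a, b) -> tuple[float, float]:
    """Two-sample pooled-variance (Student) t-test; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two observations")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def spearman(
    x,
    y,
    *,
    alternative: str = "two-sided",
    exact_max_n: int = 10,
) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with an exact small-sample P.

    For n <= ``exact_max_n`` the P-value is computed by enumerating all n!
    permutations of one variable; for larger n the t-distribution
    approximation is used.  Constant input yields (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("Spearman undefined for constant input; returning nan")
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r_obs = float(np.corrcoef(rx, ry)[0, 1])
    if n > exact_max_n:
        res = stats.spearmanr(x, y, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    # exact permutation distribution of rho
    rx_c = (rx - rx.mean()) / np.sqrt(np.sum((rx - rx.mean()) ** 2))
    ry_c = (ry - ry.mean()) / np.sqrt(np.sum((ry - ry.mean()) ** 2))
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    rhos = ry_c[perms] @ rx_c
    eps = 1e-12
    if alternative == "two-sided":
        p = float(np.mean(np.abs(rhos) >= abs(r_obs) - eps))
    elif alternative == "greater":
        p = float(np.mean(rhos >= r_obs - eps))
    elif alternative == "less":
        p = float(np.mean(rhos <= r_obs + eps))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return r_obs, p


def bonferroni(p_values, family_size: int | None = None):
    """Bonferroni-adjusted P-values: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    m = len(np.atleast_1d(p)) if family_size is None else int(family_size)
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.minimum(1.0, m * p)


def residualize(values, covariates) -> np.ndarray:
    """Least-squares residuals of ``values`` on covariates plus intercept."""
    y = np.asarray(values, dtype=float)
    X = _design_matrix(covariates, n=len(y))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _design_matrix(covariates, n: int) -> np.ndarray:
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        names = [f"covariate_{i}" for i in range(C.shape[1])]
    if C.shape[0] != n:
        raise ValueError("covariate rows do not match the number of observations")
    if not np.all(np.isfinite(C)):
        raise ValueError("covariates must be finite")
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    return X


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns (beyond the intercept) that do not increase the design rank."""
    bad = []
    kept = X[:, :1]
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j + 1]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            bad.append(name)
        else:
            kept = cand
    return bad


def covariate_adjusted_correlation(
    pred,
    obs,
    covariates,
    *,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Spearman correlation after residualizing both variables on covariates.

    Both ``pred`` and ``obs`` are regressed on the covariates (with
    intercept) by least squares; the rank correlation of the residuals is
    returned.  Requires n > number of covariates + 3.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    ncov = covariates.shape[1] if hasattr(covariates, "shape") else len(covariates[0])
    if len(pred) <= ncov + 3:
        raise ValueError("too few observations for the covariate design")
    rp = residualize(pred, covariates)
    ro = residualize(obs, covariates)
    return spearman(rp, ro, alternative=alternative)


@dataclass
class CVResult:
    """Leave-one-out cross-validation record."""

    observed: np.ndarray
    predicted: np.ndarray
    spearman_r: float
    p_value: float
    adjusted_spearman_r: float | None = None
    adjusted_p: float | None = None
    model_tag: str = ""
    alternative: str = "greater"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"observed": self.observed, "predicted": self.predicted})

    def summary(self) -> dict:
        return {
            "model": self.model_tag,
            "n": int(len(self.observed)),
            "spearman_r": self.spearman_r,
            "p_value": self.p_value,
            "adjusted_spearman_r": self.adjusted_spearman_r,
            "adjusted_p": self.adjusted_p,
            "alternative": self.alternative,
        }


def loocv(
    observed,
    fit,
    predict,
    *,
    covariates=None,
    alternative: str = "greater",
    model_tag: str = "",
) -> CVResult:
    """Leave-one-out cross-validation of a map-based predictor.

    ``fit(train_indices)`` builds a model from the named patients only;
    ``predict(model, i)`` scores the held-out patient ``i``.  Held-out
    predictions are correlated with observed outcomes by Spearman rho
    (one-sided positive by default).  A constant predictor yields nan
    correlation with a warning.
    """
    y = np.asarray(observed, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("LOOCV needs at least 5 patients")
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        train = idx[idx != i]
        try:
            model = fit(train)
        except Exception as exc:
            raise RuntimeError(f"model fit failed on fold {i}: {exc}") from exc
        preds[i] = predict(model, i)
    r, p = spearman(preds, y, alternative=alternative)
    adj_r = adj_p = None
    if covariates is not None:
        adj_r, adj_p = covariate_adjusted_correlation(
            preds, y, covariates, alternative=alternative
        )
    return CVResult(
        observed=y, predicted=preds, spearman_r=r, p_value=p,
        adjusted_spearman_r=adj_r, adjusted_p=adj_p,
        model_tag=model_tag, alternative=alternative,
    )
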