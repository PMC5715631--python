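"""Statistical inference over genometric-space rows and columns.

Rows and columns of a space often hold hypothesis-testing results (e.g.
DNA-protein binding significance), so the basic toolkit here covers
t-statistics with one- and two-sample tests (pooled or Welch), covariance
and Pearson correlation matrices, and principal component analysis.

All p-values are two-sided by default; one-sided alternatives are
available as options.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InferenceError
from .space import GenometricSpace, _check_axis

_ALTERNATIVES = ("two-sided", "less", "greater")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a t-test."""

    statistic: float
    df: float
    p_value: float
    alpha: float
    reject_null: bool
    homoscedastic: bool | None = None
    alternative: str = "two-sided"


def _p_from_t(t: float, df: float, alternative: str) -> float:
    if alternative == "two-sided":
        return float(2.0 * stats.t.sf(abs(t), df))
    if alternative == "less":
        return float(stats.t.cdf(t, df))
    return float(stats.t.sf(t, df))


def t_one_sample(x, mu0: float, alpha: float = 0.05,
                 alternative: str = "two-sided") -> TestResult:
    """One-sample t-test of H0: mean(x) == mu0.

    t = (mean - mu0) / (s / sqrt(n)) on n-1 degrees of freedom, with s
    the sample standard deviation.
    """
    if alternative not in _ALTERNATIVES:
        raise InferenceError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InferenceError("need a 1-D sample of size >= 2")
    n = x.size
    s2 = float(x.var(ddof=1))
    if s2 == 0.0:
        raise InferenceError("zero sample variance: t undefined")
    t = (float(x.mean()) - mu0) / math.sqrt(s2 / n)
    df = float(n - 1)
    p = _p_from_t(t, df, alternative)
    return TestResult(statistic=t, df=df, p_value=p, alpha=alpha,
                      reject_null=p < alpha, alternative=alternative)


def t_two_sample(x, y, alpha: float = 0.05, homoscedastic: bool = False,
                 alternative: str = "two-sided") -> TestResult:
    """Two-sample t-test of H0: mean(x) == mean(y).

    With ``homoscedastic=True`` the pooled-variance statistic on
    n_x + n_y - 2 degrees of freedom is used; otherwise the Welch
    statistic with the Welch-Satterthwaite approximate (fractional)
    degrees of freedom.
    """
    if alternative not in _ALTERNATIVES:
        raise InferenceError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size < 2 or y.size < 2:
        raise InferenceError("need two 1-D samples of size >= 2")
    nx, ny = x.size, y.size
    vx, vy = float(x.var(ddof=1)), float(y.var(ddof=1))
    if vx == 0.0 and vy == 0.0:
        raise InferenceError("both samples have zero variance: t undefined")
    delta = float(x.mean()) - float(y.mean())
    if homoscedastic:
        df = float(nx + ny - 2)
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = math.sqrt(pooled * (1.0 / nx + 1.0 / ny))
    else:
        ax, ay = vx / nx, vy / ny
        se = math.sqrt(ax + ay)
        df = (ax + ay) ** 2 / (ax ** 2 / (nx - 1) + ay ** 2 / (ny - 1))
    t = delta / se
    p = _p_from_t(t, df, alternative)
    return TestResult(statistic=t, df=df, p_value=p, alpha=alpha,
                      reject_null=p < alpha, homoscedastic=homoscedastic,
                      alternative=alternative)


def _vectors_frame(space: GenometricSpace, axis: str) -> pd.DataFrame:
    """Observations in rows, variables (the chosen axis's elements) in
    columns."""
    axis = _check_axis(axis)
    if axis == "columns":
        return pd.DataFrame(space.values, columns=list(space.col_ids))
    return pd.DataFrame(space.values.T, columns=list(space.row_ids))


def covariance_matrix(space: GenometricSpace, axis: str = "columns"
                      ) -> pd.DataFrame:
    """Sample covariance (n-1 normalization) between the elements of one
    axis; missing cells are handled by pairwise-complete deletion."""
    frame = _vectors_frame(space, axis)
    if frame.shape[0] < 2:
        raise InferenceError("need at least 2 observations per vector")
    return frame.cov(min_periods=2)


def correlation_matrix(space: GenometricSpace, axis: str = "columns"
                       ) -> pd.DataFrame:
    """Pearson correlation between the elements of one axis with
    pairwise-complete deletion; zero-variance vectors yield missing
    entries and a warning."""
    frame = _vectors_frame(space, axis)
    if frame.shape[0] < 2:
        raise InferenceError("need at least 2 observations per vector")
    degenerate = [c for c in frame.columns
                  if float(frame[c].var(ddof=1)) == 0.0]
    if degenerate:
        warnings.warn(
            f"zero-variance vector(s) {degenerate}: correlation entries "
            "set to missing", stacklevel=2)
    corr = frame.corr(min_periods=2)
    for c in degenerate:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return corr


def pca(space: GenometricSpace, axis: str = "columns",
        n_components: int | None = None):
    """Principal component analysis of one axis's vectors.

    The elements of *axis* are the variables; the other axis provides the
    observations.  Data are centered internally; observations with any
    missing value are dropped (with a warning).  Components are the
    eigenvectors of the covariance matrix ordered by descending
    eigenvalue, with the sign convention that each component's
    largest-magnitude loading is positive.

    Returns ``(loadings, scores, explained)`` where loadings has shape
    (n_variables, n_components), scores (n_observations, n_components)
    and ``explained`` the fractions of total variance, which sum to 1
    when all components are kept.
    """
    frame = _vectors_frame(space, axis)
    X = frame.to_numpy(dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} observation(s) with missing "
                      "values before PCA", stacklevel=2)
    X = X[complete]
    if X.shape[0] < 2:
        raise InferenceError("need at least 2 complete observations for PCA")
    max_components = min(X.shape)
    if n_components is None:
        n_components = max_components
    if not (1 <= n_components <= max_components):
        raise InferenceError(
            f"n_components={n_components} out of range 1..{max_components}")
    centered = X - X.mean(axis=0)
    cov = np.cov(centered, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    total = float(np.trace(cov))
    if total <= 0.0:
        raise InferenceError("constant data: PCA undefined")
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        pivot = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[pivot, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    loadings = eigvecs[:, :n_components]
    scores = centered @ loadings
    explained = eigvals[:n_components] / total
    return loadings, scores, explained


def test_result_table(results: dict) -> pd.DataFrame:
    """Arrange named :class:`TestResult` objects as an exportable table."""
    rows = []
    for name, res in results.items():
        rows.append({"name": name, "statistic": res.statistic, "df": res.df,
                     "p_value": res.p_value, "alpha": res.alpha,
                     "reject_null": res.reject_null})
    return pd.DataFrame(rows).set_index("name")
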