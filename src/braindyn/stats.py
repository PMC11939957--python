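"""Covariate-adjusted group statistics for state-occupancy analyses.

MANCOVA (Wilks' lambda with the exact-F transform for a single-df group
factor) on the K-1 free state probabilities, univariate ANCOVA post hocs,
Benjamini-Hochberg FDR, Fisher-z confidence intervals for Pearson r,
Spearman partial correlation with percentile-bootstrap CIs, and paired
t-tests.  Covariates default to age, sex, education and mean framewise
displacement.  All tests are two-sided at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignSpec",
    "mancova_wilks",
    "ancova_univariate",
    "fdr_bh",
    "pearson_fisher_ci",
    "spearman_partial_bootstrap",
    "paired_t",
    "state_probability_table",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "mean_fd")


@dataclass
class DesignSpec:
    """Group factor, covariate matrix and per-subject K-vector responses."""

    group: np.ndarray
    covariates: np.ndarray
    responses: np.ndarray

    def __post_init__(self):
        self.group = np.asarray(self.group)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        n = self.group.shape[0]
        if self.covariates.shape[0] != n or self.responses.shape[0] != n:
            raise ValueError("group, covariates and responses disagree on n")
        if np.any(~np.isfinite(self.covariates)) or np.any(~np.isfinite(self.responses)):
            raise ValueError("missing values are not supported")


def _design_matrix(design: DesignSpec) -> np.ndarray:
    g = pd.Categorical(design.group).codes.astype(float)
    n = g.shape[0]
    return np.column_stack([np.ones(n), g, design.covariates])


def _check_rank(x: np.ndarray) -> int:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return rank


def mancova_wilks(design: DesignSpec, drop_state: int | None = None,
                  statistic: str = "wilks"):
    """MANCOVA of the group factor on the state probabilities.

    One response column is dropped (sum-to-one constraint; which one is
    immaterial for the statistic), leaving p = K-1 dependent variables in
    the model intercept + group + covariates.  For the single-df group
    hypothesis the exact-F transform of Wilks' lambda applies:

        F = ((1 - L)/L) * ((ve - p + 1)/p),   df = (p, ve - p + 1),

    with ve = n - rank(X).  ``statistic`` may be "wilks" (default) or
    "pillai"; with a single hypothesis degree of freedom the two exact-F
    transforms coincide.  Returns ``(F, df1, df2, p_value)``.
    """
    if statistic not in ("wilks", "pillai"):
        raise ValueError(f"unknown statistic {statistic!r}")
    y = design.responses
    k = y.shape[1]
    drop = k - 1 if drop_state is None else drop_state
    y = np.delete(y, drop, axis=1)
    p = y.shape[1]
    x = _design_matrix(design)
    n = x.shape[0]
    rank = _check_rank(x)
    if n <= x.shape[1] + p:
        raise ValueError("too few subjects for the design")

    def residual_sscp(xm):
        beta, *_ = np.linalg.lstsq(xm, y, rcond=None)
        resid = y - xm @ beta
        return resid.T @ resid

    e_full = residual_sscp(x)
    x_reduced = np.delete(x, 1, axis=1)  # drop the group column
    h = residual_sscp(x_reduced) - e_full

    ve = n - rank
    df1 = p
    df2 = ve - p + 1
    if statistic == "wilks":
        lam = np.linalg.det(e_full) / np.linalg.det(e_full + h)
        f = ((1.0 - lam) / lam) * (df2 / df1)
    else:  # Pillai's trace; s = 1 for the single-df group hypothesis
        v = np.trace(h @ np.linalg.inv(e_full + h))
        f = (v / (1.0 - v)) * (df2 / df1)
    p_value = float(sps.f.sf(f, df1, df2))
    return float(f), int(df1), int(df2), p_value


def ancova_univariate(design: DesignSpec, state: int = 0):
    """F-test of the group term for one state's probability, adjusting for the
    covariates; df = (1, n - rank).  Returns ``(F, df1, df2, p_value)``."""
    y = design.responses[:, state]
    x = _design_matrix(design)
    n = x.shape[0]
    rank = _check_rank(x)

    def rss(xm):
        beta, *_ = np.linalg.lstsq(xm, y, rcond=None)
        resid = y - xm @ beta
        return float(resid @ resid)

    rss_full = rss(x)
    rss_reduced = rss(np.delete(x, 1, axis=1))
    df2 = n - rank
    f = (rss_reduced - rss_full) / (rss_full / df2)
    return float(f), 1, int(df2), float(sps.f.sf(f, 1, df2))


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def pearson_fisher_ci(r: float, n: int, alpha: float = 0.05):
    """Fisher-z confidence interval for a Pearson correlation."""
    if n <= 3:
        raise ValueError("need n > 3")
    if not (-1.0 < r < 1.0):
        raise ValueError("|r| must be < 1")
    z = np.arctanh(r)
    half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def _rank_residuals(v: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    ranks = sps.rankdata(v)
    if covariates is None or covariates.size == 0:
        return ranks - ranks.mean()
    x = np.column_stack([np.ones(v.shape[0]), covariates])
    beta, *_ = np.linalg.lstsq(x, ranks, rcond=None)
    return ranks - x @ beta


def spearman_partial_bootstrap(x, y, covariates=None, n_boot: int = 1000,
                               seed: int = 0, alpha: float = 0.05):
    """Spearman partial correlation with a percentile-bootstrap CI.

    x and y are rank-transformed, both ranks are residualized on the
    covariates by least squares, and the residuals are Pearson-correlated.
    The p-value uses the t approximation with df = n - 2 - (number of
    covariates); the CI resamples subjects with replacement (default 1000
    replicates).  Returns ``(rho, p, (ci_low, ci_high))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.shape[0]
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov is not None and cov.shape[0] != n:
        cov = cov.T
    n_cov = 0 if cov is None else cov.shape[1]
    if n <= n_cov + 2:
        raise ValueError("too few observations for the covariate count")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input after ranking")

    def partial_rho(xi, yi, ci):
        rx = _rank_residuals(xi, ci)
        ry = _rank_residuals(yi, ci)
        denom = np.linalg.norm(rx) * np.linalg.norm(ry)
        if denom == 0:
            return np.nan
        return float(rx @ ry / denom)

    rho = partial_rho(x, y, cov)
    df = n - 2 - n_cov
    t = rho * np.sqrt(df / max(1e-300, 1 - rho**2))
    p = float(2 * sps.t.sf(abs(t), df))

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[b] = partial_rho(x[idx], y[idx], None if cov is None else cov[idx])
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(rho), p, (float(lo), float(hi))


def paired_t(a, b):
    """Paired two-sided t-test; returns ``(t, df, p)``.

    Identical inputs give (0, n-1, 1).  Zero-variance differences with a
    nonzero mean leave t undefined and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    d = a - b
    df = d.size - 1
    if d.std(ddof=1) == 0:
        if np.allclose(d.mean(), 0.0):
            return 0.0, df, 1.0
        raise ValueError("zero-variance nonzero differences; t undefined")
    t, p = sps.ttest_rel(a, b)
    return float(t), df, float(p)


def state_probability_table(meta: pd.DataFrame, pms_matrix: np.ndarray,
                            covariates=DEFAULT_COVARIATES) -> DesignSpec:
    """Assemble a DesignSpec from a covariate table and per-subject PMS rows.

    Covariates that are constant in this sample (e.g. a single-sex cohort)
    carry no adjustment information and would make the design singular;
    they are dropped.
    """
    cov = meta.loc[:, list(covariates)].to_numpy(dtype=float)
    keep = cov.std(axis=0) > 0
    return DesignSpec(
        group=meta["group"].to_numpy(),
        covariates=cov[:, keep],
        responses=np.asarray(pms_matrix, dtype=float),
    )
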