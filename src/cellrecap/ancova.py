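"""The core statistic: intercept contrasts between regression lines at equal slopes.

For each cell population, the back-transformed mean expression of a tested
gene group (y) is regressed on the cell-cycle signature signal (x), with
individual cells as points. Two populations are compared by the difference
in intercepts of the two lines constrained to a common slope (classical
one-covariate ANCOVA):

    y = a + da * g + b * x + e,   g = 1 for the contrast population, 0 otherwise

so ``da`` is the expression difference extrapolated to zero cell-cycle
activity. Standard errors come from the usual linear-model covariance with
``n_total - 3`` residual degrees of freedom; p-values and confidence
intervals use the t distribution. A quadratic-alternative fit quantifies how
much of the nonlinearly explainable variance the linear model captures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import CellGroupSignal


@dataclass
class RegressionFit:
    """Per-population OLS fit of group signal on cell-cycle signal."""

    population: str
    slope: float
    slope_se: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_se: float
    r_squared: float
    n_cells: int


@dataclass
class InterceptContrast:
    """Intercept difference (contrast minus reference) at a common slope."""

    group_name: str
    contrast_population: str
    reference_population: str
    delta_intercept: float
    se: float
    ci: tuple[float, float]
    p_value: float
    common_slope: float
    n_contrast: int
    n_reference: int

    @property
    def call(self) -> str:
        """Qualitative call from the CI: 'down', 'up' or 'null'."""
        lo, hi = self.ci
        if hi < 0:
            return "down"
        if lo > 0:
            return "up"
        return "null"


@dataclass
class AdequacyReport:
    """Linear-vs-quadratic comparison of the group-on-signature regression."""

    population: str
    r_squared_linear: float
    r_squared_quadratic: float
    quadratic_p: float
    linear_fraction: float
    degenerate: bool


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Least squares with coefficient covariance; returns (beta, cov, r2, df)."""
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError(f"need more than {p} points for a {p}-parameter fit")
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        raise ValueError("degenerate design matrix (constant covariate?)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    cov = (rss / df) * np.linalg.inv(xtx)
    return beta, cov, r2, df


def fit_group_regression(signal: CellGroupSignal, cc_signal: CellGroupSignal,
                         population: str, alpha: float = 0.05) -> RegressionFit:
    """OLS of the group signal on the signature signal within one population."""
    y = signal.in_population(population)
    x = cc_signal.in_population(population)
    if len(y) < 3:
        raise ValueError(f"population {population!r} has {len(y)} cells; need >= 3")
    if np.ptp(x) == 0:
        raise ValueError("cell-cycle signal is constant; slope undefined")
    X = np.column_stack([np.ones_like(x), x])
    beta, cov, r2, df = _ols(X, y)
    tq = stats.t.ppf(1 - alpha / 2, df)
    slope_se = float(np.sqrt(cov[1, 1]))
    return RegressionFit(
        population=population,
        slope=float(beta[1]),
        slope_se=slope_se,
        slope_ci=(float(beta[1] - tq * slope_se), float(beta[1] + tq * slope_se)),
        intercept=float(beta[0]),
        intercept_se=float(np.sqrt(cov[0, 0])),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n_cells=len(y),
    )


def intercept_contrast(signal: CellGroupSignal, cc_signal: CellGroupSignal,
                       contrast_pop: str, reference_pop: str,
                       alpha: float = 0.05,
                       group_name: str | None = None) -> InterceptContrast:
    """Intercept difference between two populations at equal slopes."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    y_c = signal.in_population(contrast_pop)
    y_r = signal.in_population(reference_pop)
    x_c = cc_signal.in_population(contrast_pop)
    x_r = cc_signal.in_population(reference_pop)
    if len(y_c) < 3 or len(y_r) < 3:
        raise ValueError("each population needs >= 3 cells")
    y = np.concatenate([y_r, y_c])
    x = np.concatenate([x_r, x_c])
    g = np.concatenate([np.zeros(len(y_r)), np.ones(len(y_c))])
    if np.ptp(x) == 0:
        raise ValueError("pooled cell-cycle signal is constant; slope undefined")
    X = np.column_stack([np.ones_like(x), g, x])
    beta, cov, _, df = _ols(X, y)
    delta = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    if se == 0:
        p = 0.0 if delta != 0 else 1.0
    else:
        p = float(2 * stats.t.sf(abs(delta) / se, df))
    tq = stats.t.ppf(1 - alpha / 2, df)
    return InterceptContrast(
        group_name=group_name or signal.group_name,
        contrast_population=contrast_pop,
        reference_population=reference_pop,
        delta_intercept=delta,
        se=se,
        ci=(delta - tq * se, delta + tq * se),
        p_value=p,
        common_slope=float(beta[2]),
        n_contrast=len(y_c),
        n_reference=len(y_r),
    )


def adequacy_check(signal: CellGroupSignal, cc_signal: CellGroupSignal,
                   population: str) -> AdequacyReport:
    """How much of the quadratically explainable variance the line captures.

    ``linear_fraction = r2_linear / r2_quadratic``; when either r-squared is
    zero the ratio is reported as 0 with the ``degenerate`` flag set.
    """
    y = signal.in_population(population)
    x = cc_signal.in_population(population)
    if len(y) < 4:
        raise ValueError("adequacy check needs >= 4 cells")
    X1 = np.column_stack([np.ones_like(x), x])
    X2 = np.column_stack([np.ones_like(x), x, x * x])
    _, _, r2_lin, _ = _ols(X1, y)
    beta2, cov2, r2_quad, df2 = _ols(X2, y)
    se_q = float(np.sqrt(cov2[2, 2]))
    if se_q == 0:
        p_quad = 0.0 if beta2[2] != 0 else 1.0
    else:
        p_quad = float(2 * stats.t.sf(abs(beta2[2]) / se_q, df2))
    r2_lin = float(np.clip(r2_lin, 0.0, 1.0))
    r2_quad = float(np.clip(r2_quad, 0.0, 1.0))
    degenerate = r2_quad <= 0.0 or r2_lin <= 0.0
    fraction = 0.0 if degenerate else min(r2_lin / r2_quad, 1.0)
    return AdequacyReport(
        population=population,
        r_squared_linear=r2_lin,
        r_squared_quadratic=r2_quad,
        quadratic_p=p_quad,
        linear_fraction=fraction,
        degenerate=degenerate,
    )
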